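import numpy as np
import pandas as pd
import pytest

from smnmod.gating import GateConfig
from smnmod.simulate import SimulationConfig


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture
def gate() -> GateConfig:
    return GateConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def make_events(
    n_large: int,
    n_small: int,
    genotype: str = "homozygous",
    gate: GateConfig | None = None,
    clone_id: str = "c0001",
    plate_id: str = "plate01",
    trial: int = 1,
) -> pd.DataFrame:
    """Hand-built gated+called event table with exact large/small counts."""
    gate = gate or GateConfig()
    boundary = gate.large_for(genotype)
    tof = [boundary + 50.0] * n_large + [boundary - 50.0] * n_small
    n = n_large + n_small
    return pd.DataFrame(
        {
            "plate_id": [plate_id] * n,
            "well_id": ["A01"] * n,
            "replicate_id": [trial] * n,
            "clone_id": [clone_id] * n,
            "tof_length": tof,
            "gfp_intensity": [
                1000.0 if genotype == "heterozygous" else 5.0
            ] * n,
            "genotype": [genotype] * n,
        }
    )
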