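"""Sorter-event gating: debris removal, GFP genotype calls, % large.

The balancer chromosome carries a pharyngeal GFP marker, so among gated
(non-debris) events GFP-positive animals are heterozygous and
GFP-negative animals are homozygous mutant.  Debris is excluded by a
lower length bound at the L2 boundary (the smallest larvae are
indistinguishable from bacterial debris).  The growth-assay statistic is
the fraction of a genotype's animals whose time-of-flight exceeds a
"large" boundary (adults, L4 and L3 larvae); because homozygotes are
shorter at the same stage the large boundary may be genotype-specific.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import GENOTYPES, SorterEvent, SimulationConfig, events_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "GenotypeCall",
    "FractionLarge",
    "UndefinedFractionError",
    "call_genotype",
    "call_genotypes",
    "apply_debris_gate",
    "fraction_large",
    "estimate_gfp_threshold",
]


class UndefinedFractionError(ValueError):
    """Raised when % large is requested for a genotype with zero events."""


@dataclass
class GateConfig:
    """Thresholds for debris, GFP positivity, and the 'large' boundary.

    ``large_min_length`` may be a single value or a per-genotype mapping
    (homozygotes are shorter at the same stage, so genotype-specific
    boundaries are supported; a shared boundary is equally valid).
    """

    gfp_threshold: float = 100.0
    debris_min_length: float = 140.0
    large_min_length: float | Mapping[str, float] = field(
        default_factory=lambda: {"homozygous": 300.0, "heterozygous": 340.0}
    )

    def __post_init__(self):
        if self.gfp_threshold <= 0 or self.debris_min_length <= 0:
            raise ValueError("thresholds must be > 0")
        for g in GENOTYPES:
            if self.large_for(g) <= 0:
                raise ValueError("large_min_length must be > 0")
            if self.debris_min_length >= self.large_for(g):
                raise ValueError("debris_min_length must be < large_min_length")

    def large_for(self, genotype: str) -> float:
        if isinstance(self.large_min_length, Mapping):
            return float(self.large_min_length[genotype])
        return float(self.large_min_length)

    @classmethod
    def from_simulation(cls, config: SimulationConfig, **kwargs) -> "GateConfig":
        """Derive a gate from the generative model's own parameters.

        The GFP threshold defaults to the midpoint of the two class
        medians on the log scale.
        """
        pos_loc = config.gfp_params["positive"][0]
        neg_loc = config.gfp_params["negative"][0]
        kwargs.setdefault("gfp_threshold", math.exp((pos_loc + neg_loc) / 2.0))
        return cls(**kwargs)


@dataclass(frozen=True)
class GenotypeCall:
    event: SorterEvent
    label: str  # homozygous | heterozygous


def estimate_gfp_threshold(intensities: Sequence[float], n_iter: int = 50) -> float:
    """Data-driven GFP threshold: midpoint of the two class medians.

    A two-means split on log intensity separates the GFP+ and GFP-
    classes; the threshold is the midpoint of the class medians on the
    log scale, mapped back to intensity units.
    """
    x = np.log(np.asarray(intensities, dtype=float))
    if x.size < 2:
        raise ValueError("need at least two events to estimate a threshold")
    lo, hi = x.min(), x.max()
    c = np.array([lo, hi], dtype=float)
    for _ in range(n_iter):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [x[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
    med = [np.median(x[assign == k]) if np.any(assign == k) else c[k] for k in (0, 1)]
    return float(math.exp((med[0] + med[1]) / 2.0))


def call_genotype(event: SorterEvent, gate: GateConfig) -> GenotypeCall:
    """GFP above threshold (strictly) => heterozygous, else homozygous."""
    label = "heterozygous" if event.gfp_intensity > gate.gfp_threshold else "homozygous"
    return GenotypeCall(event=event, label=label)


def _as_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events
    return events_to_frame(list(events))


def call_genotypes(events, gate: GateConfig) -> pd.DataFrame:
    """Vector form: adds a ``genotype`` column to a gated event table."""
    df = _as_frame(events).copy()
    codes = (df["gfp_intensity"].to_numpy() > gate.gfp_threshold).astype(np.int8)
    df["genotype"] = pd.Categorical.from_codes(
        codes, ["homozygous", "heterozygous"]
    )
    return df


def apply_debris_gate(events, gate: GateConfig):
    """Retain events with tof_length >= debris_min_length (closed bound).

    Order is preserved.  Accepts and returns either a list of
    :class:`SorterEvent` or an event DataFrame.
    """
    if isinstance(events, pd.DataFrame):
        kept = events[events["tof_length"] >= gate.debris_min_length]
        if len(events) and not len(kept):
            logger.warning("debris gate removed all %d events", len(events))
        return kept.reset_index(drop=True)
    kept = [e for e in events if e.tof_length >= gate.debris_min_length]
    if events and not kept:
        logger.warning("debris gate removed all %d events", len(events))
    return kept


@dataclass(frozen=True)
class FractionLarge:
    fraction: float
    n_large: int
    n_total: int

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def fraction_large(events, gate: GateConfig, genotype: str) -> FractionLarge:
    """% large for one genotype: P(tof >= large boundary | genotype).

    ``events`` must already be debris-gated and carry a ``genotype``
    column (see :func:`call_genotypes`).  Zero events of the requested
    genotype is an explicit error, never a silent 0/0.
    """
    df = _as_frame(events)
    if "genotype" not in df.columns:
        raise ValueError("events must be genotype-called first (call_genotypes)")
    sub = df[df["genotype"] == genotype]
    n = len(sub)
    if n == 0:
        raise UndefinedFractionError(f"no gated events with genotype {genotype!r}")
    n_large = int((sub["tof_length"] >= gate.large_for(genotype)).sum())
    return FractionLarge(fraction=n_large / n, n_large=n_large, n_total=n)
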