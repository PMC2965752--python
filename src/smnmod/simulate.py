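"""Generative models for every assay input the pipeline consumes.

The central object is a mixed-stage population of *C. elegans* broods
segregating a recessive-lethal mutation kept over a GFP-marked balancer
chromosome.  Heterozygous mothers throw progeny 1:2:1
(homozygous mutant : heterozygous : balancer-homozygous); balancer
homozygotes die as embryos, so hatched larvae are ~1/3 homozygous mutant
and ~2/3 heterozygous.  Homozygotes start out indistinguishable from their
siblings because of maternally loaded gene product; once the maternal
contribution is depleted they grow more slowly, are shorter at the same
stage, and die at an elevated rate.  A flow sorter measures each animal's
length as time-of-flight and its pharyngeal GFP fluorescence, which is the
genotype marker.

All lengths are in arbitrary "sorter units" (time-of-flight is never
calibrated to microns here); stage is a discrete daily Markov advance
through L1..L4 and adult.  RNAi clone effects are planted as per-clone
multipliers on the stage-advance probability and/or the daily death
hazard of the affected genotype, scaled by a knockdown-efficacy factor.

Auxiliary generators produce pharyngeal pump-count tables (overdispersed
counts around a genotype x day x treatment mean rate), Drosophila pupal
fate counts (multinomial early/late/eclosed), and larval NMJ bouton
counts (Poisson counts proportional to muscle area).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ModifierEffect",
    "SimulationConfig",
    "SorterEvent",
    "PumpingTrial",
    "LethalityCounts",
    "BoutonRecord",
    "ScreenDataset",
    "simulate_brood",
    "simulate_screen",
    "simulate_pumping",
    "simulate_lethality",
    "simulate_boutons",
    "events_to_frame",
]

STAGES = ("L1", "L2", "L3", "L4", "adult")
GENOTYPES = ("homozygous", "heterozygous")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ModifierEffect:
    """Planted per-clone modifier effect.

    ``growth_mult`` scales the stage-advance probability and
    ``mortality_mult`` scales the daily death hazard of each genotype in
    ``affected``.  Multipliers of 1 are the identity (no effect); a
    growth_mult < 1 or mortality_mult > 1 is an enhancer-like effect.
    """

    growth_mult: float = 1.0
    mortality_mult: float = 1.0
    affected: tuple[str, ...] = ("homozygous",)

    def validate(self) -> None:
        if self.growth_mult <= 0 or self.mortality_mult <= 0:
            raise ConfigurationError("modifier multipliers must be > 0")
        for g in self.affected:
            if g not in GENOTYPES:
                raise ConfigurationError(f"unknown affected genotype {g!r}")


def _default_stage_length_params() -> dict[str, tuple[float, float]]:
    # location/scale of log-length per stage, arbitrary sorter units
    means = {"L1": 100.0, "L2": 170.0, "L3": 280.0, "L4": 450.0, "adult": 700.0}
    return {s: (math.log(m), 0.12) for s, m in means.items()}


@dataclass
class SimulationConfig:
    """Study conditions for the sorter, pumping, lethality and bouton models.

    Parameters
    ----------
    seed:
        Base seed; every generator also accepts an explicit seed argument.
    n_broods, brood_size:
        Broods pooled per culture well and progeny per brood.  A single
        brood hatches synchronously at day 0; with multiple broods each
        animal's hatch day is drawn from the expanding culture's age
        structure (see ``hatch_spread``), which is what makes screen
        cultures mixed-stage.
    day:
        Assay day (days after the first hatch).  Screen cultures run for
        8 days; plate-format growth assays for 5; pumping assays score
        day 1-4 animals.
    stage_length_params:
        Per-stage (L1..adult) location/scale of log time-of-flight.
    genotype_growth_rate:
        Daily stage-advance probability per genotype.  Homozygotes use
        the heterozygous rate while maternal rescue lasts.
    maternal_depletion_day:
        Age (days post-hatch) after which homozygote deficits begin:
        their own growth rate, length shift, death hazard, and any
        homozygote-directed modifier effect all switch on only for ages
        strictly greater than this.
    mortality_hazard:
        Daily death probability per genotype.  The heterozygous hazard
        applies at every age; the homozygous hazard only after maternal
        depletion.
    gfp_params:
        location/scale of log-GFP for the GFP+ (heterozygous, balancer
        marker) and GFP- (homozygous mutant) classes.
    debris_rate:
        Expected debris events per progeny slot; debris mimics the
        smallest larvae in length and is GFP-negative.
    knockdown_efficacy:
        Fraction in [0, 1] scaling all planted modifier effects toward
        the identity; models incomplete RNAi knockdown (feeding RNAi is
        notably weaker in neurons).
    modifier_effect:
        Mapping clone id -> :class:`ModifierEffect` for planted clones.
    homozygote_length_shift:
        Additive log-length shift for homozygotes past maternal
        depletion (they are shorter at the same stage).
    pumping_*:
        Pump-count model: wild-type mean rate (pumps/min), observation
        window, negative-binomial dispersion, and the per-day rate
        multiplier applied to homozygotes for each day past maternal
        depletion.
    """

    seed: int | None = None
    n_broods: int = 8
    brood_size: int = 40
    day: int = 8
    stage_length_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_stage_length_params
    )
    genotype_growth_rate: dict[str, float] = field(
        default_factory=lambda: {"heterozygous": 0.65, "homozygous": 0.35}
    )
    maternal_depletion_day: int = 2
    mortality_hazard: dict[str, float] = field(
        default_factory=lambda: {"heterozygous": 0.0, "homozygous": 0.3}
    )
    gfp_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "positive": (math.log(1000.0), 0.5),
            "negative": (math.log(5.0), 0.5),
        }
    )
    debris_rate: float = 0.05
    knockdown_efficacy: float = 1.0
    modifier_effect: dict[str, ModifierEffect] = field(default_factory=dict)
    homozygote_length_shift: float = -0.22
    debris_length_params: tuple[float, float] = (math.log(60.0), 0.35)
    hatch_spread: float = 0.3
    pumping_base_rate: float = 250.0
    pumping_window_s: float = 10.0
    pumping_dispersion: float = 30.0
    pumping_day_decline: float = 0.45

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.brood_size < 1 or self.n_broods < 1:
            raise ConfigurationError("brood_size and n_broods must be >= 1")
        if self.day < 1:
            raise ConfigurationError("day must be >= 1")
        if not 0.0 <= self.debris_rate < 1.0:
            raise ConfigurationError("debris_rate must be in [0, 1)")
        if not 0.0 <= self.knockdown_efficacy <= 1.0:
            raise ConfigurationError("knockdown_efficacy must be in [0, 1]")
        for g, r in self.genotype_growth_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"growth rate for {g} outside [0, 1]")
        for g, h in self.mortality_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"mortality hazard for {g} outside [0, 1]")
        for s, (loc, scale) in self.stage_length_params.items():
            if scale <= 0:
                raise ConfigurationError(f"length scale for stage {s} must be > 0")
        for k, (loc, scale) in self.gfp_params.items():
            if scale <= 0:
                raise ConfigurationError(f"GFP scale for class {k} must be > 0")
        if self.pumping_base_rate <= 0 or self.pumping_window_s <= 0:
            raise ConfigurationError("pumping rate and window must be > 0")
        if self.pumping_dispersion <= 0:
            raise ConfigurationError("pumping_dispersion must be > 0")
        for eff in self.modifier_effect.values():
            eff.validate()

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "modifier_effect" in d:
            d["modifier_effect"] = {
                k: v if isinstance(v, ModifierEffect) else ModifierEffect(
                    growth_mult=v.get("growth_mult", 1.0),
                    mortality_mult=v.get("mortality_mult", 1.0),
                    affected=tuple(v.get("affected", ("homozygous",))),
                )
                for k, v in d["modifier_effect"].items()
            }
        if "stage_length_params" in d:
            d["stage_length_params"] = {
                k: tuple(v) for k, v in d["stage_length_params"].items()
            }
        if "gfp_params" in d:
            d["gfp_params"] = {k: tuple(v) for k, v in d["gfp_params"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load a configuration from a JSON or YAML file."""
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class SorterEvent:
    """One sorter measurement: an animal (or debris particle) in a well."""

    plate_id: str
    well_id: str
    replicate_id: int
    clone_id: str
    tof_length: float
    gfp_intensity: float
    true_genotype: str  # homozygous / heterozygous / debris (hidden label)


@dataclass(frozen=True)
class PumpingTrial:
    trial_id: int
    genotype: str
    treatment: str
    day: int
    pump_counts: tuple[int, ...]
    window_s: float = 10.0

    def __post_init__(self):
        if len(self.pump_counts) < 1:
            raise ConfigurationError("a pumping trial needs >= 1 animal")
        if self.window_s <= 0:
            raise ConfigurationError("window_s must be > 0")
        if any(c < 0 for c in self.pump_counts):
            raise ConfigurationError("pump counts must be >= 0")


@dataclass(frozen=True)
class LethalityCounts:
    cross_id: str
    n_early_pupal: int
    n_late_pupal: int
    n_eclosed: int

    def __post_init__(self):
        if min(self.n_early_pupal, self.n_late_pupal, self.n_eclosed) < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.total < 1:
            raise ConfigurationError("total count must be >= 1")

    @property
    def total(self) -> int:
        return self.n_early_pupal + self.n_late_pupal + self.n_eclosed


@dataclass(frozen=True)
class BoutonRecord:
    larva_id: str
    genotype: str
    bouton_count: int
    muscle_area: float
    site: str = "muscle6/7_A2"

    def __post_init__(self):
        if self.bouton_count < 0:
            raise ConfigurationError("bouton_count must be >= 0")
        if self.muscle_area <= 0:
            raise ConfigurationError("muscle_area must be > 0")


EVENT_COLUMNS = [
    "plate_id",
    "well_id",
    "replicate_id",
    "clone_id",
    "tof_length",
    "gfp_intensity",
    "true_genotype",
]


def events_to_frame(events: Sequence[SorterEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in events], columns=EVENT_COLUMNS)


def _effective_multipliers(config: SimulationConfig, clone_id: str):
    """(growth_mult, mort_mult) per genotype, knockdown-efficacy scaled."""
    gm = {g: 1.0 for g in GENOTYPES}
    mm = {g: 1.0 for g in GENOTYPES}
    eff = config.modifier_effect.get(clone_id)
    if eff is not None:
        e = config.knockdown_efficacy
        for g in eff.affected:
            gm[g] = 1.0 + e * (eff.growth_mult - 1.0)
            mm[g] = 1.0 + e * (eff.mortality_mult - 1.0)
    return gm, mm


def _simulate_wells(
    config: SimulationConfig,
    wells: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorized core: simulate sorter events for many wells at once.

    ``wells`` needs columns plate_id, well_id, replicate_id, clone_id and
    the four per-well effective multiplier columns gm_homo, gm_het,
    mm_homo, mm_het.  Every well holds ``n_broods`` broods of
    ``brood_size`` progeny.  Returns an event table (hidden true genotype
    included).
    """
    n_wells = len(wells)
    per_well = config.n_broods * config.brood_size
    n = n_wells * per_well
    well_idx = np.repeat(np.arange(n_wells), per_well)

    # Standing age structure of the expanding culture: each animal's
    # hatch day is drawn with geometric weights (later days contribute
    # more animals as the population grows).  A single brood with no
    # spread hatches synchronously at day 0.
    if config.n_broods == 1 or config.hatch_spread <= 0:
        hatch_day = np.zeros(n, dtype=np.int64)
    else:
        days = np.arange(config.day)
        w = (1.0 + config.hatch_spread) ** days
        probs = w / w.sum()
        hatch_day = rng.choice(days, size=n, p=probs)
    age = config.day - hatch_day  # >= 1

    # Mendelian 1:2:1; balancer homozygotes die as embryos and are dropped.
    u = rng.random(n)
    is_balancer = u >= 0.75
    is_homo = u < 0.25
    keep = ~is_balancer
    well_idx = well_idx[keep]
    age = age[keep]
    is_homo = is_homo[keep]
    n = keep.sum()

    gm = np.where(is_homo, wells["gm_homo"].to_numpy()[well_idx],
                  wells["gm_het"].to_numpy()[well_idx])
    mm = np.where(is_homo, wells["mm_homo"].to_numpy()[well_idx],
                  wells["mm_het"].to_numpy()[well_idx])

    g_het = config.genotype_growth_rate["heterozygous"]
    g_homo = config.genotype_growth_rate["homozygous"]
    h_het = config.mortality_hazard["heterozygous"]
    h_homo = config.mortality_hazard["homozygous"]
    depl = config.maternal_depletion_day

    stage = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    for step in range(1, config.day + 1):
        active = alive & (age >= step)
        depleted = step > depl
        if depleted:
            p_adv = np.where(is_homo, np.clip(g_homo * gm, 0, 1),
                             np.clip(g_het * gm, 0, 1))
            p_die = np.where(is_homo, np.clip(h_homo * mm, 0, 1),
                             np.clip(h_het * mm, 0, 1))
        else:
            # maternal rescue: homozygotes grow like siblings, no extra
            # hazard, and homozygote-directed clone effects are masked.
            p_adv = np.where(is_homo, g_het, np.clip(g_het * gm, 0, 1))
            p_die = np.where(is_homo, 0.0, np.clip(h_het * mm, 0, 1))
        adv = rng.random(n) < p_adv
        stage = np.where(active & adv, np.minimum(stage + 1, len(STAGES) - 1), stage)
        die = rng.random(n) < p_die
        alive &= ~(active & die)

    # measurement of survivors
    surv = alive
    stage_s = stage[surv]
    well_s = well_idx[surv]
    homo_s = is_homo[surv]
    age_s = age[surv]
    locs = np.array([config.stage_length_params[s][0] for s in STAGES])
    scales = np.array([config.stage_length_params[s][1] for s in STAGES])
    log_len = locs[stage_s] + scales[stage_s] * rng.standard_normal(surv.sum())
    log_len = log_len + np.where(
        homo_s & (age_s > depl), config.homozygote_length_shift, 0.0
    )
    tof = np.exp(log_len)
    pos_loc, pos_scale = config.gfp_params["positive"]
    neg_loc, neg_scale = config.gfp_params["negative"]
    log_gfp = np.where(
        homo_s,
        neg_loc + neg_scale * rng.standard_normal(surv.sum()),
        pos_loc + pos_scale * rng.standard_normal(surv.sum()),
    )
    gfp = np.exp(log_gfp)

    # debris: below the L2 boundary, GFP-negative
    n_debris = rng.binomial(per_well, config.debris_rate, size=n_wells)
    d_well = np.repeat(np.arange(n_wells), n_debris)
    d_loc, d_scale = config.debris_length_params
    d_tof = np.exp(d_loc + d_scale * rng.standard_normal(d_well.size))
    d_gfp = np.exp(neg_loc + neg_scale * rng.standard_normal(d_well.size))

    all_well = np.concatenate([well_s, d_well])
    order = np.argsort(all_well, kind="stable")
    aw = all_well[order]

    def _cat(col: str):
        codes, cats = pd.factorize(wells[col])
        return pd.Categorical.from_codes(codes[aw], cats)

    geno_codes = np.concatenate(
        [np.where(homo_s, 0, 1), np.full(d_well.size, 2, dtype=np.int64)]
    )[order]
    out = pd.DataFrame(
        {
            "plate_id": _cat("plate_id"),
            "well_id": _cat("well_id"),
            "replicate_id": wells["replicate_id"].to_numpy()[aw],
            "clone_id": _cat("clone_id"),
            "tof_length": np.concatenate([tof, d_tof])[order],
            "gfp_intensity": np.concatenate([gfp, d_gfp])[order],
            "true_genotype": pd.Categorical.from_codes(
                geno_codes, ["homozygous", "heterozygous", "debris"]
            ),
        }
    )
    return out


def _resolve_rng(config: SimulationConfig, seed) -> np.random.Generator:
    if seed is None:
        seed = config.seed
    return np.random.default_rng(seed)


def simulate_brood(
    config: SimulationConfig,
    clone_id: str = "empty",
    *,
    plate_id: str = "plate1",
    well_id: str = "A01",
    replicate_id: int = 1,
    seed: int | None = None,
) -> list[SorterEvent]:
    """Simulate one culture well (``n_broods`` broods) on one RNAi clone.

    Progeny are drawn 1:2:1 and balancer homozygotes removed before
    hatching; each survivor is advanced day by day to ``config.day``
    with genotype-specific growth and mortality (homozygote deficits and
    homozygote-directed clone effects only past maternal depletion),
    then measured (length from the stage distribution, GFP from the
    genotype class) with debris appended at ``debris_rate``.
    """
    config.validate()
    rng = _resolve_rng(config, seed)
    gm, mm = _effective_multipliers(config, clone_id)
    wells = pd.DataFrame(
        [
            {
                "plate_id": plate_id,
                "well_id": well_id,
                "replicate_id": replicate_id,
                "clone_id": clone_id,
                "gm_homo": gm["homozygous"],
                "gm_het": gm["heterozygous"],
                "mm_homo": mm["homozygous"],
                "mm_het": mm["heterozygous"],
            }
        ]
    )
    df = _simulate_wells(config, wells, rng)
    return [SorterEvent(**row) for row in df.to_dict("records")]


@dataclass
class ScreenDataset:
    """Events grouped by plate/clone/trial plus the plate layout."""

    events: pd.DataFrame
    layout: pd.DataFrame  # plate_id, well_id, clone_id

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.events["replicate_id"].unique().tolist())

    def with_additional_trials(
        self, config: SimulationConfig, n_trials: int, seed: int | None = None
    ) -> "ScreenDataset":
        """Independent retest trials with ids continuing after the last."""
        start = max(self.trial_ids) + 1
        extra = _simulate_trials(config, self.layout, n_trials, start, seed)
        return ScreenDataset(
            events=pd.concat([self.events, extra], ignore_index=True),
            layout=self.layout,
        )


def _well_name(i: int) -> str:
    return f"{'ABCDEFGH'[i // 12]}{i % 12 + 1:02d}"


def _simulate_trials(config, layout, n_trials, first_trial, seed) -> pd.DataFrame:
    rng = _resolve_rng(config, seed)
    frames = []
    for t in range(first_trial, first_trial + n_trials):
        wells = layout.copy()
        wells["replicate_id"] = t
        mults = [
            _effective_multipliers(config, c) for c in wells["clone_id"]
        ]
        wells["gm_homo"] = [m[0]["homozygous"] for m in mults]
        wells["gm_het"] = [m[0]["heterozygous"] for m in mults]
        wells["mm_homo"] = [m[1]["homozygous"] for m in mults]
        wells["mm_het"] = [m[1]["heterozygous"] for m in mults]
        frames.append(_simulate_wells(config, wells, rng))
    return pd.concat(frames, ignore_index=True)


def simulate_screen(
    config: SimulationConfig,
    n_plates: int,
    clones_per_plate: int,
    planted: Mapping[str, ModifierEffect] | None = None,
    n_trials: int = 2,
    *,
    seed: int | None = None,
    first_trial: int = 1,
) -> ScreenDataset:
    """Simulate a 96-well liquid-culture RNAi screen.

    Every plate x clone x trial combination receives an independent
    culture from :func:`simulate_brood`'s model, with the clone's planted
    effect (identity if unplanted).  Clone ids are ``c0001``.. laid out
    row-major across plates.
    """
    config.validate()
    if clones_per_plate > 96:
        raise ConfigurationError("clones_per_plate must be <= 96")
    planted = dict(planted or {})
    for eff in planted.values():
        eff.validate()
    clone_ids = [
        f"c{i + 1:04d}" for i in range(n_plates * clones_per_plate)
    ]
    unknown = set(planted) - set(clone_ids)
    if unknown:
        raise ConfigurationError(
            f"planted clones not on any plate: {sorted(unknown)}"
        )
    layout = pd.DataFrame(
        {
            "plate_id": [
                f"plate{i // clones_per_plate + 1:02d}" for i in range(len(clone_ids))
            ],
            "well_id": [_well_name(i % clones_per_plate) for i in range(len(clone_ids))],
            "clone_id": clone_ids,
        }
    )
    cfg = config.replace(modifier_effect={**config.modifier_effect, **planted})
    events = _simulate_trials(cfg, layout, n_trials, first_trial, seed)
    return ScreenDataset(events=events, layout=layout)


def _homo_rate_multiplier(config: SimulationConfig, day: int) -> float:
    """Pumping-rate decline of homozygotes past maternal depletion."""
    excess = max(0, day - config.maternal_depletion_day)
    return config.pumping_day_decline ** excess


def simulate_pumping(
    config: SimulationConfig,
    genotypes: Sequence[str],
    treatments: Mapping[str, float],
    n_animals: int,
    n_trials: int,
    seed: int | None = None,
    *,
    day: int | None = None,
) -> list[PumpingTrial]:
    """Per-animal pump counts over a fixed observation window.

    Counts are negative-binomial around a mean that follows genotype x
    day x treatment: wild-type and heterozygous animals pump at
    ``pumping_base_rate`` (~250/min); homozygote rates decline
    geometrically for each day past maternal depletion.  ``treatments``
    maps treatment name -> rate multiplier (use 1.0 for the empty-vector
    control); multipliers are scaled by ``knockdown_efficacy``.
    """
    config.validate()
    if n_animals < 1:
        raise ConfigurationError("n_animals must be >= 1")
    for g in genotypes:
        if g not in GENOTYPES and g != "control":
            raise ConfigurationError(f"unknown genotype {g!r}")
    day = config.day if day is None else day
    rng = _resolve_rng(config, seed)
    k = config.pumping_dispersion
    out: list[PumpingTrial] = []
    for trial in range(1, n_trials + 1):
        for g in genotypes:
            for treatment, mult in treatments.items():
                if mult <= 0:
                    raise ConfigurationError("treatment multipliers must be > 0")
                eff = 1.0 + config.knockdown_efficacy * (mult - 1.0)
                rate = config.pumping_base_rate * eff
                if g == "homozygous":
                    rate *= _homo_rate_multiplier(config, day)
                mean_count = rate * config.pumping_window_s / 60.0
                counts = rng.negative_binomial(
                    k, k / (k + mean_count), size=n_animals
                )
                out.append(
                    PumpingTrial(
                        trial_id=trial,
                        genotype=g,
                        treatment=treatment,
                        day=day,
                        pump_counts=tuple(int(c) for c in counts),
                        window_s=config.pumping_window_s,
                    )
                )
    return out


def simulate_lethality(
    p_early: float,
    p_late: float,
    n: int,
    seed: int | None = None,
    *,
    cross_id: str = "cross1",
) -> LethalityCounts:
    """Multinomial pupal fates: early death, late death, or eclosion.

    The reference parameterization for strong ubiquitous SMN knockdown is
    44% early / 56% late pupal lethality.
    """
    if p_early < 0 or p_late < 0 or p_early + p_late > 1 + 1e-12:
        raise ConfigurationError("(p_early, p_late) must lie in the simplex")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    early, late, eclosed = rng.multinomial(
        n, [p_early, p_late, max(0.0, 1.0 - p_early - p_late)]
    )
    return LethalityCounts(cross_id, int(early), int(late), int(eclosed))


def simulate_boutons(
    genotype_means: Mapping[str, float],
    area_params: tuple[float, float],
    n_larvae: int,
    seed: int | None = None,
    *,
    site: str = "muscle6/7_A2",
) -> list[BoutonRecord]:
    """Poisson bouton counts with mean proportional to muscle area.

    ``genotype_means`` gives the expected bouton count at the average
    muscle area; per-larva areas are log-normal with the given
    (location, scale) of log-area, and the count mean scales linearly
    with relative area.
    """
    if n_larvae < 1:
        raise ConfigurationError("n_larvae must be >= 1 per genotype")
    loc, scale = area_params
    if scale < 0:
        raise ConfigurationError("area scale must be >= 0")
    rng = np.random.default_rng(seed)
    mean_area = math.exp(loc + scale**2 / 2.0)
    out: list[BoutonRecord] = []
    for genotype, mean in genotype_means.items():
        if mean <= 0:
            raise ConfigurationError(f"bouton mean for {genotype} must be > 0")
        areas = np.exp(loc + scale * rng.standard_normal(n_larvae))
        counts = rng.poisson(mean * areas / mean_area)
        for i, (a, c) in enumerate(zip(areas, counts), start=1):
            out.append(
                BoutonRecord(
                    larva_id=f"{genotype}_{i:03d}",
                    genotype=genotype,
                    bouton_count=int(c),
                    muscle_area=float(a),
                    site=site,
                )
            )
    return out
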