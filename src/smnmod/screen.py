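"""Genome-wide screen statistic and two-stage hit confirmation.

Each 96-well plate carries one RNAi clone per well; the per-well,
per-genotype statistic is the growth ratio large:small.  Ratios are
standardized within plate x genotype x trial (z-scores over the plate's
usable clones), and a clone flags as a candidate in a trial when its
homozygous-mutant ratio sits more than ``k_homo`` (2.0) standard
deviations from the plate mean while its heterozygous-control ratio
stays within ``k_het`` (0.7) standard deviations — the specificity
filter.  Confirmation is two-stage: a clone must flag in both of the
two primary trials to enter retest, and then flag in at least 40% of
at least four retest trials.  The candidate rule is two-sided; the sign
of the homozygous deviation labels the putative direction afterwards
(ratio deficit = enhancer by default; the convention is a flag because
the plotted ratio's orientation is a reporting choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gating import GateConfig, apply_debris_gate, call_genotypes
from .simulate import GENOTYPES, ScreenDataset

__all__ = [
    "CloneRatio",
    "HitCall",
    "growth_ratio",
    "compute_ratios",
    "plate_zscores",
    "call_candidate",
    "confirm_hits",
    "run_screen",
]

MIN_EVENTS = 20
MIN_USABLE_CLONES = 8


@dataclass(frozen=True)
class CloneRatio:
    """Per-well, per-genotype large:small growth ratio."""

    clone_id: str
    plate_id: str
    trial_id: int
    genotype: str
    ratio: float | None
    n_large: int
    n_small: int
    usable: bool
    reason: str | None = None  # too-few-events | zero-denominator


@dataclass
class HitCall:
    clone_id: str
    direction: str | None  # enhancer | suppressor | None
    primary_flags: tuple[bool, ...]
    retest_flags: tuple[bool, ...]
    z_homo: dict[int, float] = field(default_factory=dict)
    z_het: dict[int, float] = field(default_factory=dict)
    stage: str = "primary"  # primary | retest
    confirmed: bool = False
    pass_fraction: float = 0.0


def growth_ratio(
    events,
    gate: GateConfig,
    genotype: str,
    min_events: int = MIN_EVENTS,
) -> CloneRatio:
    """Growth ratio for one well's events (already gated and
    genotype-called).  Wells with fewer than ``min_events`` events of the
    genotype, or no small animals, are unusable and carry a reason code.
    """
    df = events if isinstance(events, pd.DataFrame) else pd.DataFrame(events)
    sub = df[df["genotype"] == genotype]
    clone = df["clone_id"].iloc[0] if len(df) else "?"
    plate = df["plate_id"].iloc[0] if len(df) else "?"
    trial = int(df["replicate_id"].iloc[0]) if len(df) else -1
    n_large = int((sub["tof_length"] >= gate.large_for(genotype)).sum())
    n_small = int(len(sub) - n_large)
    if len(sub) < min_events:
        return CloneRatio(clone, plate, trial, genotype, None, n_large, n_small,
                          usable=False, reason="too-few-events")
    if n_small == 0:
        return CloneRatio(clone, plate, trial, genotype, None, n_large, n_small,
                          usable=False, reason="zero-denominator")
    return CloneRatio(clone, plate, trial, genotype, n_large / n_small,
                      n_large, n_small, usable=True)


def compute_ratios(
    events: pd.DataFrame, gate: GateConfig, min_events: int = MIN_EVENTS
) -> pd.DataFrame:
    """Vectorized growth ratios for every plate x clone x trial x genotype.

    ``events`` is a raw event table; debris gating and genotype calling
    are applied here.
    """
    gated = apply_debris_gate(events, gate)
    gated = call_genotypes(gated, gate)
    large = np.where(
        gated["genotype"] == "homozygous",
        gated["tof_length"] >= gate.large_for("homozygous"),
        gated["tof_length"] >= gate.large_for("heterozygous"),
    )
    gated = gated.assign(is_large=large)
    g = gated.groupby(
        ["plate_id", "well_id", "clone_id", "replicate_id", "genotype"],
        observed=True,
    )["is_large"].agg(n_large="sum", n_total="count").reset_index()
    g["n_large"] = g["n_large"].astype(int)
    g["n_small"] = g["n_total"] - g["n_large"]
    g["usable"] = (g["n_total"] >= min_events) & (g["n_small"] > 0)
    g["reason"] = np.select(
        [g["n_total"] < min_events, g["n_small"] == 0],
        ["too-few-events", "zero-denominator"],
        default=None,
    )
    g["ratio"] = np.where(g["usable"], g["n_large"] / g["n_small"].replace(0, 1), np.nan)
    g = g.rename(columns={"replicate_id": "trial_id"})
    return g.drop(columns=["n_total"])


class DegeneratePlateError(ValueError):
    """All usable ratios on a plate are identical (SD = 0)."""


def plate_zscores(
    ratios: pd.DataFrame, min_usable: int = MIN_USABLE_CLONES
) -> pd.DataFrame:
    """Standardize ratios within plate x genotype x trial.

    z = (ratio - plate mean) / plate SD over the usable clones of that
    plate/genotype/trial.  Plates with fewer than ``min_usable`` usable
    clones are skipped (z left NaN, ``plate_status`` = 'skipped');
    zero-SD plates are flagged 'degenerate'.
    """
    out = ratios.copy()
    out["z"] = np.nan
    out["plate_status"] = "ok"
    for key, idx in out.groupby(
        ["plate_id", "genotype", "trial_id"], observed=True
    ).groups.items():
        sub = out.loc[idx]
        usable = sub[sub["usable"]]
        if len(usable) < min_usable:
            out.loc[idx, "plate_status"] = "skipped"
            continue
        mu = usable["ratio"].mean()
        sd = usable["ratio"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            out.loc[idx, "plate_status"] = "degenerate"
            continue
        mask = out.loc[idx, "usable"]
        out.loc[idx[mask], "z"] = (out.loc[idx[mask], "ratio"] - mu) / sd
    return out


def call_candidate(
    z_homo: float, z_het: float, k_homo: float = 2.0, k_het: float = 0.7
) -> bool:
    """Candidate iff |z_homo| > k_homo and |z_het| < k_het (both strict:
    'more than' / 'within')."""
    if not (np.isfinite(z_homo) and np.isfinite(z_het)):
        raise ValueError("both z-scores must be finite")
    return bool(abs(z_homo) > k_homo and abs(z_het) < k_het)


def confirm_hits(
    primary_flags: Sequence[bool],
    retest_flags: Sequence[bool],
    min_retests: int = 4,
    min_pass_fraction: float = 0.4,
) -> HitCall:
    """Two-stage confirmation.

    A clone enters retest only if it flagged in *both* of exactly two
    primary trials; it is confirmed if it then flagged in at least
    ``min_pass_fraction`` of at least ``min_retests`` retest trials.
    Fewer retest trials leave it ineligible, never confirmed.
    """
    primary = tuple(bool(f) for f in primary_flags)
    retest = tuple(bool(f) for f in retest_flags)
    if len(primary) != 2:
        raise ValueError("the primary stage is exactly two independent trials")
    call = HitCall(
        clone_id="", direction=None, primary_flags=primary, retest_flags=retest
    )
    if not all(primary):
        return call
    call.stage = "retest"
    if len(retest) < min_retests:
        return call
    call.pass_fraction = sum(retest) / len(retest)
    call.confirmed = call.pass_fraction >= min_pass_fraction
    return call


def run_screen(
    dataset: ScreenDataset | pd.DataFrame,
    gate: GateConfig,
    k_homo: float = 2.0,
    k_het: float = 0.7,
    min_pass_fraction: float = 0.4,
    min_retests: int = 4,
    n_primary: int = 2,
    min_events: int = MIN_EVENTS,
    deficit_is_enhancer: bool = True,
) -> pd.DataFrame:
    """End-to-end hit calling: gate, ratio, standardize, flag, confirm.

    The first ``n_primary`` trial ids are the primary screen; the rest
    are retests.  Returns one row per clone with per-trial z-scores,
    candidate flags, pass fraction, confirmed status, direction, and a
    status of 'untested' for clones with no usable primary data
    (degenerate or skipped plates propagate here).  Ranked with
    confirmed hits first.
    """
    events = dataset.events if isinstance(dataset, ScreenDataset) else dataset
    ratios = compute_ratios(events, gate, min_events=min_events)
    z = plate_zscores(ratios)
    trials = sorted(z["trial_id"].unique())
    if len(trials) < n_primary:
        raise ValueError(f"need at least {n_primary} primary trials")

    def _wide(genotype: str) -> pd.DataFrame:
        sub = z[z["genotype"] == genotype]
        return sub.pivot_table(
            index="clone_id", columns="trial_id", values="z", aggfunc="first",
            observed=True,
        )

    wh, wt = _wide("homozygous"), _wide("heterozygous")
    clones = sorted(set(wh.index) | set(wt.index))
    zh = wh.reindex(index=clones, columns=trials).to_numpy()
    zt = wt.reindex(index=clones, columns=trials).to_numpy()

    both = np.isfinite(zh) & np.isfinite(zt)
    flags = both & (np.abs(zh) > k_homo) & (np.abs(zt) < k_het)
    untested = ~both[:, :n_primary].any(axis=1)
    primary_pass = flags[:, :n_primary].all(axis=1)
    n_retest = len(trials) - n_primary
    if n_retest > 0:
        pass_fraction = flags[:, n_primary:].mean(axis=1)
    else:
        pass_fraction = np.zeros(len(clones))
    pass_fraction = np.where(primary_pass & ~untested, pass_fraction, 0.0)
    confirmed = (
        primary_pass
        & ~untested
        & (n_retest >= min_retests)
        & (pass_fraction >= min_pass_fraction)
    )
    # direction from the sign of the homozygous deviation in flagged trials
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_flag_z = np.nanmean(np.where(flags, zh, np.nan), axis=1)
    with np.errstate(invalid="ignore"):
        deficit = mean_flag_z < 0
    any_flag = flags.any(axis=1)
    direction = np.where(
        any_flag,
        np.where(deficit == deficit_is_enhancer, "enhancer", "suppressor"),
        None,
    )
    table = pd.DataFrame({
        "clone_id": clones,
        "status": np.where(untested, "untested", "tested"),
        "confirmed": confirmed & ~untested,
        "direction": direction,
        "pass_fraction": pass_fraction,
    })
    for j, t in enumerate(trials):
        table[f"z_homo_t{t}"] = zh[:, j]
        table[f"z_het_t{t}"] = zt[:, j]
        table[f"flag_t{t}"] = flags[:, j]
    return table.sort_values(
        ["confirmed", "pass_fraction", "clone_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
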