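"""Monte-Carlo calibration of the pipeline under its own generator.

These routines run the full pipeline (simulate -> gate -> statistic) on
null or planted-effect data and measure operating characteristics: the
screen's per-trial candidate rate and confirmed-hit rate under the null,
detection of planted strong enhancers, recovery of planted pumping
effects, genotype-call accuracy, and empirical type-I error of the three
decision procedures.  They are used by the acceptance checks and are
importable for ad-hoc power analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fly import bouton_anova
from .gating import GateConfig, apply_debris_gate, call_genotypes
from .growth import GrowthSummary, classify_modifier, compare_growth
from .pumping import compare_pumping
from .screen import run_screen
from .simulate import (
    ModifierEffect,
    SimulationConfig,
    simulate_boutons,
    simulate_pumping,
    simulate_screen,
)

__all__ = [
    "STRONG_ENHANCER",
    "analytic_candidate_rate",
    "null_screen_calibration",
    "planted_enhancer_power",
    "genotype_call_accuracy",
    "pumping_multiplier_recovery",
    "classify_modifier_type1",
    "compare_pumping_type1",
    "bouton_anova_type1",
]

# near-complete post-depletion growth arrest of homozygotes; a strong
# mortality effect instead empties the well below the event minimum and
# makes the clone untestable rather than hit-positive
STRONG_ENHANCER = ModifierEffect(growth_mult=0.1, affected=("homozygous",))


def analytic_candidate_rate(k_homo: float = 2.0, k_het: float = 0.7) -> float:
    """P(candidate per trial) if both z-scores were independent standard
    normals: P(|Z| > k_homo) * P(|Z| < k_het)."""
    return float(2 * sps.norm.sf(k_homo) * (2 * sps.norm.cdf(k_het) - 1))


def _seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_screen_calibration(
    config: SimulationConfig | None = None,
    gate: GateConfig | None = None,
    n_plates: int = 16,
    clones_per_plate: int = 96,
    n_trials: int = 6,
    seed: int | None = None,
) -> dict:
    """One full null screen (no planted effects): per-trial candidate rate
    and confirmed-hit rate, with the analytic normal-composition rate for
    comparison."""
    config = config or SimulationConfig()
    gate = gate or GateConfig()
    ds = simulate_screen(config, n_plates, clones_per_plate, {}, n_trials,
                         seed=seed)
    table = run_screen(ds, gate)
    flag_cols = [c for c in table.columns if c.startswith("flag_")]
    flags = table[flag_cols].to_numpy(dtype=bool)
    n_clones = len(table)
    return {
        "candidate_rate": float(flags.mean()),
        "analytic_rate": analytic_candidate_rate(),
        "confirmed_rate": float(table["confirmed"].mean()),
        "n_confirmed": int(table["confirmed"].sum()),
        "n_clones": n_clones,
        "n_clone_trials": int(flags.size),
    }


def planted_enhancer_power(
    n_replicates: int = 200,
    config: SimulationConfig | None = None,
    gate: GateConfig | None = None,
    effect: ModifierEffect = STRONG_ENHANCER,
    n_plates: int = 16,
    clones_per_plate: int = 96,
    n_planted: int = 4,
    n_trials: int = 6,
    seed: int | None = None,
) -> dict:
    """Detection of planted strong enhancers across screen replicates.

    Plants ``n_planted`` copies of ``effect`` on distinct plates of a
    1,536-clone screen and reruns the full pipeline per replicate.
    Reports the fraction of replicates in which *all* planted clones are
    confirmed, the per-clone confirmation rate, and the per-trial
    candidate rate of planted clones.
    """
    config = config or SimulationConfig()
    gate = gate or GateConfig()
    stride = n_plates // n_planted
    planted_ids = [
        f"c{i * stride * clones_per_plate + 1:04d}" for i in range(n_planted)
    ]
    planted = {cid: effect for cid in planted_ids}
    all_confirmed = 0
    clone_confirmed = 0
    cand_flags = 0
    cand_total = 0
    for s in _seeds(seed, n_replicates):
        ds = simulate_screen(config, n_plates, clones_per_plate, planted,
                             n_trials, seed=s)
        table = run_screen(ds, gate).set_index("clone_id")
        sub = table.loc[planted_ids]
        all_confirmed += int(sub["confirmed"].all())
        clone_confirmed += int(sub["confirmed"].sum())
        flag_cols = [c for c in table.columns if c.startswith("flag_")]
        f = sub[flag_cols].to_numpy(dtype=bool)
        cand_flags += int(f.sum())
        cand_total += int(f.size)
    return {
        "all_planted_confirmed_fraction": all_confirmed / n_replicates,
        "per_clone_confirmation_rate": clone_confirmed / (n_planted * n_replicates),
        "planted_candidate_rate_per_trial": cand_flags / cand_total,
        "n_replicates": n_replicates,
    }


def genotype_call_accuracy(
    config: SimulationConfig | None = None,
    gate: GateConfig | None = None,
    n_events: int = 100_000,
    seed: int | None = None,
) -> dict:
    """GFP genotype-call accuracy against the simulation's hidden labels
    (debris-gated events only)."""
    config = config or SimulationConfig()
    gate = gate or GateConfig()
    n_wells = max(1, n_events // (config.n_broods * config.brood_size))
    ds = simulate_screen(config, 1, min(96, n_wells), {}, n_trials=
                         max(1, n_wells // 96 + 1), seed=seed)
    ev = apply_debris_gate(ds.events, gate)
    ev = call_genotypes(ev, gate)
    truth = ev["true_genotype"].astype(str)
    mask = truth.isin(["homozygous", "heterozygous"])
    called = ev.loc[mask, "genotype"].astype(str)
    acc = float((called.to_numpy() == truth[mask].to_numpy()).mean())
    return {"accuracy": acc, "n_events": int(mask.sum())}


def pumping_multiplier_recovery(
    multiplier: float = 0.5,
    n_trials: int = 100,
    n_animals: int = 20,
    day: int = 3,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Recover a planted pumping-rate multiplier with the percent-change
    estimator: mean per-trial percent change vs the configured value."""
    config = config or SimulationConfig()
    trials = simulate_pumping(
        config, ["homozygous"], {"empty": 1.0, "candidate": multiplier},
        n_animals, n_trials, seed=seed, day=day,
    )
    treated = [t for t in trials if t.treatment == "candidate"]
    control = [t for t in trials if t.treatment == "empty"]
    pc, p, test = compare_pumping(treated, control)
    return {
        "mean_percent_change": pc.mean_percent,
        "expected_percent": 100.0 * multiplier,
        "n_trials": n_trials,
        "p_value": p,
        "test_used": test,
    }


def classify_modifier_type1(
    n_replicates: int = 1000,
    n_trials: int = 6,
    config: SimulationConfig | None = None,
    gate: GateConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Empirical false-positive rate of the enhancer/suppressor call under
    the null generator (treated and control cultures identical).

    Each replicate simulates ``n_trials`` independent cultures per arm,
    computes per-trial % large for both genotypes, runs the
    Mann-Whitney growth comparisons and classifies.  A false positive is
    any enhancer or suppressor call.
    """
    config = config or SimulationConfig()
    gate = gate or GateConfig()
    wells_per_rep = 2 * n_trials  # treated + control arms
    n_wells = n_replicates * wells_per_rep
    # one bulk simulation: each well is an independent identical culture
    n_trials_sim = -(-n_wells // 96)
    ds = simulate_screen(config, 1, 96, {}, n_trials=n_trials_sim, seed=seed)
    ev = apply_debris_gate(ds.events, gate)
    ev = call_genotypes(ev, gate)
    large = np.where(
        ev["genotype"] == "homozygous",
        ev["tof_length"] >= gate.large_for("homozygous"),
        ev["tof_length"] >= gate.large_for("heterozygous"),
    )
    ev = ev.assign(is_large=large)
    frac = (
        ev.groupby(["replicate_id", "well_id", "genotype"], observed=True)[
            "is_large"
        ]
        .mean()
        .reset_index()
        .pivot_table(index=["replicate_id", "well_id"], columns="genotype",
                     values="is_large", observed=True)
        .to_numpy()
    )
    frac = frac[: n_replicates * wells_per_rep]
    frac = frac.reshape(n_replicates, 2, n_trials, 2)  # rep x arm x trial x geno
    false_pos = 0
    for r in range(n_replicates):
        calls = {}
        for gi, geno in enumerate(["homozygous", "heterozygous"]):
            treated = GrowthSummary(geno, "candidate", tuple(frac[r, 0, :, gi]))
            control = GrowthSummary(geno, "empty", tuple(frac[r, 1, :, gi]))
            calls[geno] = compare_growth(treated, control)
        cls = classify_modifier(calls["homozygous"], calls["heterozygous"], alpha)
        false_pos += cls in ("enhancer", "suppressor")
    return {"rate": false_pos / n_replicates, "n_replicates": n_replicates}


def compare_pumping_type1(
    n_replicates: int = 1000,
    n_trials: int = 4,
    n_animals: int = 20,
    config: SimulationConfig | None = None,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Empirical false-positive rate of the percent-change test when the
    treatment multiplier is exactly 1 (null)."""
    config = config or SimulationConfig()
    false_pos = 0
    for s in _seeds(seed, n_replicates):
        trials = simulate_pumping(
            config, ["homozygous"], {"empty": 1.0, "candidate": 1.0},
            n_animals, n_trials, seed=s, day=3,
        )
        treated = [t for t in trials if t.treatment == "candidate"]
        control = [t for t in trials if t.treatment == "empty"]
        _, p, _ = compare_pumping(treated, control)
        false_pos += p <= alpha
    return {"rate": false_pos / n_replicates, "n_replicates": n_replicates}


def bouton_anova_type1(
    n_replicates: int = 1000,
    mean: float = 60.0,
    n_larvae: int = 12,
    n_groups: int = 3,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Empirical ANOVA rejection rate when all genotype means are equal."""
    false_pos = 0
    means = {f"g{i}": mean for i in range(n_groups)}
    for s in _seeds(seed, n_replicates):
        records = simulate_boutons(means, (0.0, 0.15), n_larvae, seed=s)
        groups: dict[str, list[float]] = {g: [] for g in means}
        for r in records:
            groups[r.genotype].append(r.bouton_count / r.muscle_area)
        res = bouton_anova(groups)
        false_pos += res.p_value <= alpha
    return {"rate": false_pos / n_replicates, "n_replicates": n_replicates}
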