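"""Pharyngeal-pumping statistics: rates, percent change vs control,
data-driven test selection, and trial aggregation.

Pumping is scored as grinder movements in a fixed (default 10 s)
observation window, reported as pumps per minute.  Because absolute
rates drift day to day (food thickness, temperature), the effect
statistic is the per-trial percent change: 100 x treated / control mean
rate within each trial, so an enhancer scores below 100% and a
suppressor above 100%.  Significance is assessed on the per-trial
percent changes against 100% by default (pooling animal-level rates
across arms is available as an alternative), with the test chosen by a
sample-screening rule: a t-test when both samples look normal
(Shapiro-Wilk) and variances are comparable, otherwise the rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .growth import mann_whitney_u, sem
from .simulate import PumpingTrial

logger = logging.getLogger(__name__)

__all__ = [
    "PumpSummary",
    "PercentChange",
    "pumps_per_minute",
    "percent_change",
    "select_test",
    "compare_pumping",
    "summarize_pumping",
]

VARIANCE_RATIO_MAX = 4.0


def pumps_per_minute(count: int, window_s: float) -> float:
    """Convert a pump count over a window to pumps/min."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 60.0 / window_s


def percent_change(treated_mean_rate: float, control_mean_rate: float) -> float:
    """100 x treated / control: enhancers < 100, suppressors > 100."""
    if control_mean_rate <= 0:
        raise ValueError("control mean rate must be > 0")
    return 100.0 * treated_mean_rate / control_mean_rate


@dataclass
class PumpSummary:
    """Pooled pumping rates for one genotype/treatment arm.

    The pooled mean is the average over all animals in all trials (each
    animal weighted once), alongside per-trial means.
    """

    genotype: str
    treatment: str
    trial_means: dict[int, float]
    pooled_mean: float
    sem: float
    n_animals: int


@dataclass
class PercentChange:
    per_trial: dict[int, float]
    mean_percent: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self):
        vals = list(self.per_trial.values())
        self.mean_percent = float(np.mean(vals))
        self.sem = sem(vals)

    @property
    def n_trials(self) -> int:
        return len(self.per_trial)


def _trial_rates(trials: Sequence[PumpingTrial]) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    for t in trials:
        rates = np.array([pumps_per_minute(c, t.window_s) for c in t.pump_counts])
        if t.trial_id in out:
            out[t.trial_id] = np.concatenate([out[t.trial_id], rates])
        else:
            out[t.trial_id] = rates
    return out


def summarize_pumping(trials: Sequence[PumpingTrial]) -> PumpSummary:
    by_trial = _trial_rates(trials)
    all_rates = np.concatenate(list(by_trial.values()))
    return PumpSummary(
        genotype=trials[0].genotype,
        treatment=trials[0].treatment,
        trial_means={k: float(v.mean()) for k, v in by_trial.items()},
        pooled_mean=float(all_rates.mean()),
        sem=sem(all_rates),
        n_animals=int(all_rates.size),
    )


def _looks_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:  # constant sample: Shapiro undefined, clearly non-normal fit
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def select_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float] | None = None,
    alpha_normality: float = 0.05,
) -> str:
    """Choose between ``t_test`` and ``mann_whitney`` from the samples.

    The parametric test is used only when every sample passes a
    Shapiro-Wilk normality screen at ``alpha_normality`` and (for two
    samples) the variance ratio is below 4; anything else falls to the
    rank test.  Samples smaller than three force the rank test with a
    warning.  For a single sample (testing percent changes against a
    constant) only the normality screen applies.
    """
    a = np.asarray(sample_a, dtype=float)
    samples = [a]
    if sample_b is not None:
        samples.append(np.asarray(sample_b, dtype=float))
    if any(s.size < 3 for s in samples):
        logger.warning("sample with n < 3: forcing the rank test")
        return "mann_whitney"
    if not all(_looks_normal(s, alpha_normality) for s in samples):
        return "mann_whitney"
    if sample_b is not None:
        v = [s.var(ddof=1) for s in samples]
        if min(v) == 0 or max(v) / min(v) >= VARIANCE_RATIO_MAX:
            return "mann_whitney"
    return "t_test"


def compare_pumping(
    trials_treated: Sequence[PumpingTrial],
    trials_control: Sequence[PumpingTrial],
    alpha_normality: float = 0.05,
    method: str = "per_trial",
):
    """Treated-vs-control pumping comparison.

    Trials are paired by ``trial_id`` (same day/arena); unmatched ids
    are an error.  The default ``per_trial`` method computes one percent
    change per paired trial and tests those against 100% (one-sample t
    or Wilcoxon signed-rank per :func:`select_test`); ``pooled`` tests
    animal-level rates between arms (two-sample t or Mann-Whitney).

    Returns (PercentChange, p_value, test_used).
    """
    tr = _trial_rates(trials_treated)
    ct = _trial_rates(trials_control)
    unmatched = set(tr) ^ set(ct)
    if unmatched:
        raise ValueError(f"unpaired trial ids: {sorted(unmatched)}")
    per_trial = {
        tid: percent_change(tr[tid].mean(), ct[tid].mean()) for tid in sorted(tr)
    }
    pc = PercentChange(per_trial=per_trial)
    if pc.n_trials < 3:
        logger.warning("only %d paired trials: low power", pc.n_trials)
    if method == "per_trial":
        diffs = np.array(list(per_trial.values())) - 100.0
        choice = select_test(diffs + 100.0, None, alpha_normality)
        if np.allclose(diffs, 0):
            return pc, 1.0, "t_test" if choice == "t_test" else "wilcoxon"
        if choice == "t_test":
            p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
            return pc, p, "t_test"
        p = float(stats.wilcoxon(diffs, zero_method="wilcox").pvalue)
        return pc, p, "wilcoxon"
    if method == "pooled":
        a = np.concatenate(list(tr.values()))
        b = np.concatenate(list(ct.values()))
        choice = select_test(a, b, alpha_normality)
        if choice == "t_test":
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            return pc, p, "t_test"
        res = mann_whitney_u(a, b, mode="auto")
        return pc, res.p_value, "mann_whitney"
    raise ValueError(f"unknown method {method!r}")
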