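"""Growth-assay statistics: % large summaries, exact Mann-Whitney U,
chi-square contingency tests, and enhancer/suppressor classification.

The experimental unit for growth comparisons is the independent trial:
each culture yields one fraction-large per genotype, three to six trials
per condition, and treated-vs-control significance is a two-tailed
Mann-Whitney U test on the per-trial fractions at alpha 0.05.  For such
small samples the exact null distribution of U is enumerated over all
label assignments (ties included); larger samples use the tie-corrected
normal approximation.  Mutant-allele comparisons of categorical outcomes
(large vs small counts) use the Pearson chi-square test instead.

A candidate gene is called an enhancer when it significantly decreases
the homozygous mutant's % large while leaving the heterozygous control
unchanged; a suppressor when the homozygous change is a significant
increase; any significant heterozygous change makes the effect
nonspecific (the mutant phenotype is no longer the target).

No multiple-testing correction is applied across candidate-gene tables;
``ComparisonResult.multiple_testing_corrected`` records this caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthSummary",
    "ComparisonResult",
    "MannWhitneyResult",
    "Chi2Result",
    "mann_whitney_u",
    "compare_growth",
    "classify_modifier",
    "chi_square_2xk",
    "compare_mean_length",
    "sem",
]

EXACT_MAX_N = 12  # total sample size at/below which auto mode enumerates


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample SD / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


@dataclass
class GrowthSummary:
    """Per-condition % large across independent trials."""

    genotype: str
    treatment: str
    trial_fractions: tuple[float, ...]
    mean_pct_large: float = field(init=False)
    sem_pct: float = field(init=False)

    def __post_init__(self):
        if len(self.trial_fractions) < 1:
            raise ValueError("need at least one trial")
        pct = [100.0 * f for f in self.trial_fractions]
        self.mean_pct_large = float(np.mean(pct))
        self.sem_pct = sem(pct)

    @property
    def n_trials(self) -> int:
        return len(self.trial_fractions)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # exact | approximate


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float


@dataclass
class ComparisonResult:
    statistic: float
    test_used: str  # mann_whitney | chi_square | t_test | wilcoxon
    p_value: float
    direction: str  # decrease | increase | none
    mean_a: float | None = None
    mean_b: float | None = None
    classification: str | None = None
    multiple_testing_corrected: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def _u_less(a: np.ndarray, b: np.ndarray) -> float:
    """Number of pairs with a < b, plus half the tied pairs."""
    less = (a[:, None] < b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(less) + 0.5 * float(ties)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Enumerate all C(n_a+n_b, n_a) label assignments of the combined
    multiset; the two-sided p is the fraction whose U is at least as far
    from the null mean n_a*n_b/2 as the observed U."""
    c = np.concatenate([a, b])
    n, n_a = c.size, a.size
    mu = n_a * (n - n_a) / 2.0
    score = (c[:, None] < c[None, :]) + 0.5 * (c[:, None] == c[None, :])
    row_tot = score.sum(axis=1)
    obs_dev = abs(u_obs - mu)
    hits = 0
    total = comb(n, n_a)
    idx = np.arange(n)
    for a_idx in combinations(idx, n_a):
        a_idx = np.asarray(a_idx)
        # U(A) = sum over i in A of score over B = row totals minus in-A part
        u = row_tot[a_idx].sum() - score[np.ix_(a_idx, a_idx)].sum()
        if abs(u - mu) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    mode: str = "auto",
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    The reported statistic is the classical U = min(U_a, U_b) where
    U_a counts pairs with a < b (half credit for ties).  In ``exact``
    mode (or ``auto`` with n_a+n_b <= 12) the two-sided p comes from
    full enumeration of label assignments, which handles ties without
    approximation; otherwise the tie-corrected normal approximation is
    used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "approximate", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    u_less = _u_less(a, b)
    u_stat = min(u_less, a.size * b.size - u_less)
    use_exact = mode == "exact" or (mode == "auto" and a.size + b.size <= EXACT_MAX_N)
    if use_exact:
        combined = np.concatenate([a, b])
        if np.unique(combined).size == combined.size:
            # no ties: the exact null is symmetric, so twice the smaller
            # tail equals the |U - mean|-extremity enumeration
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return MannWhitneyResult(u=u_stat, p_value=float(min(1.0, res.pvalue)),
                                     method="exact")
        p = _exact_two_sided_p(a, b, u_less)
        return MannWhitneyResult(u=u_stat, p_value=min(1.0, p), method="exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=u_stat, p_value=float(min(1.0, res.pvalue)),
                             method="approximate")


def _direction(mean_a: float, mean_b: float) -> str:
    if np.isclose(mean_a, mean_b):
        return "none"
    return "decrease" if mean_a < mean_b else "increase"


def compare_growth(
    treated: GrowthSummary, control: GrowthSummary, mode: str = "auto"
) -> ComparisonResult:
    """Mann-Whitney on per-trial % large, treated vs empty-vector control.

    Both summaries must describe the same genotype with at least three
    independent trials each.  Direction is the sign of the difference of
    trial means (treated minus control).
    """
    if treated.genotype != control.genotype:
        raise ValueError(
            f"genotype mismatch: {treated.genotype!r} vs {control.genotype!r}"
        )
    if treated.n_trials < 3 or control.n_trials < 3:
        raise ValueError("growth comparisons need >= 3 trials per condition")
    res = mann_whitney_u(treated.trial_fractions, control.trial_fractions, mode=mode)
    return ComparisonResult(
        statistic=res.u,
        test_used="mann_whitney",
        p_value=res.p_value,
        direction=_direction(treated.mean_pct_large, control.mean_pct_large),
        mean_a=treated.mean_pct_large,
        mean_b=control.mean_pct_large,
    )


def classify_modifier(
    homo: ComparisonResult, het: ComparisonResult, alpha: float = 0.05
) -> str:
    """Enhancer / suppressor / nonspecific / none.

    enhancer: homozygous % large significantly decreased AND the
    heterozygous control unchanged; suppressor: significant homozygous
    increase with the heterozygous control unchanged; nonspecific: any
    significant heterozygous change (whatever the homozygous result);
    none otherwise.
    """
    if het.significant(alpha):
        return "nonspecific"
    if homo.significant(alpha) and homo.direction == "decrease":
        return "enhancer"
    if homo.significant(alpha) and homo.direction == "increase":
        return "suppressor"
    return "none"


def chi_square_2xk(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> Chi2Result:
    """Pearson chi-square for a 2 x k contingency table, no continuity
    correction; df = k - 1.  Zero expected cells are an error (pool
    categories first)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("counts_a and counts_b must be equal-length, k >= 2")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    table = np.vstack([a, b])
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; pool sparse categories before testing"
        )
    chi2 = float(((table - expected) ** 2 / expected).sum())
    k = a.size
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return Chi2Result(chi2=chi2, df=k - 1, p_value=p)


def compare_mean_length(events_a, events_b) -> ComparisonResult:
    """Two-sided test on raw time-of-flight lengths of two groups.

    The test (pooled-variance t vs Mann-Whitney) is chosen by the same
    sample-screening rule used for pumping rates; groups smaller than
    three fall back to the exact Mann-Whitney path.
    """
    from .pumping import select_test

    def _lengths(ev):
        if isinstance(ev, pd.DataFrame):
            return ev["tof_length"].to_numpy(dtype=float)
        arr = np.asarray(
            [e.tof_length if hasattr(e, "tof_length") else e for e in ev], dtype=float
        )
        return arr

    a, b = _lengths(events_a), _lengths(events_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 events per group")
    choice = select_test(a, b)
    if choice == "t_test":
        t, p = stats.ttest_ind(a, b, equal_var=True)
        stat, test = float(t), "t_test"
    else:
        res = mann_whitney_u(a, b, mode="auto")
        stat, p, test = res.u, res.p_value, "mann_whitney"
    return ComparisonResult(
        statistic=stat,
        test_used=test,
        p_value=float(min(1.0, p)),
        direction=_direction(float(a.mean()), float(b.mean())),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
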