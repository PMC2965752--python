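"""Drosophila readouts: pupal-lethality chi-square and NMJ bouton ANOVA.

Ubiquitous SMN knockdown in flies causes pupal death; modifiers shift
the balance between early (white pupae) and late (black pupae) death,
compared to control crosses by Pearson chi-square on the 2x2 table of
stage-of-death counts (a dead-vs-eclosed categorization is available).

NMJ severity is quantified as synaptic bouton counts normalized to
muscle area: each larva's count is divided by its muscle area expressed
relative to the wild-type mean area, giving boutons per wild-type-
equivalent area.  Genotypes are compared by one-way ANOVA with all
pairwise contrasts, Bonferroni-adjusted by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .growth import Chi2Result, chi_square_2xk, sem
from .simulate import BoutonRecord, LethalityCounts

__all__ = [
    "LethalityComparison",
    "BoutonSummary",
    "AnovaResult",
    "lethality_chi_square",
    "normalize_bouton_density",
    "bouton_anova",
    "summarize_boutons",
]


@dataclass(frozen=True)
class LethalityComparison:
    experimental: LethalityCounts
    control: LethalityCounts
    categories: str
    chi2: float
    df: int
    p_value: float


def lethality_chi_square(
    exp: LethalityCounts,
    ctrl: LethalityCounts,
    categories: str = "early_vs_late",
) -> LethalityComparison:
    """Pearson chi-square on pupal fates, experimental vs control cross.

    ``early_vs_late`` (default) compares stage of death among dead
    pupae; ``dead_vs_eclosed`` compares overall survival.
    """
    if categories == "early_vs_late":
        a = (exp.n_early_pupal, exp.n_late_pupal)
        b = (ctrl.n_early_pupal, ctrl.n_late_pupal)
    elif categories == "dead_vs_eclosed":
        a = (exp.n_early_pupal + exp.n_late_pupal, exp.n_eclosed)
        b = (ctrl.n_early_pupal + ctrl.n_late_pupal, ctrl.n_eclosed)
    else:
        raise ValueError(f"unknown categorization {categories!r}")
    if sum(a) == 0 or sum(b) == 0:
        raise ValueError("a row of the selected categorization is all zero")
    res: Chi2Result = chi_square_2xk(a, b)
    return LethalityComparison(
        experimental=exp,
        control=ctrl,
        categories=categories,
        chi2=res.chi2,
        df=res.df,
        p_value=res.p_value,
    )


def normalize_bouton_density(record: BoutonRecord, wt_mean_area: float) -> float:
    """Boutons per wild-type-equivalent muscle area:
    count / (area / wt_mean_area)."""
    if wt_mean_area <= 0:
        raise ValueError("wt_mean_area must be > 0")
    if record.muscle_area <= 0:
        raise ValueError("muscle_area must be > 0")
    return record.bouton_count / (record.muscle_area / wt_mean_area)


@dataclass
class BoutonSummary:
    genotype: str
    densities: tuple[float, ...]
    mean: float
    sem: float
    n_larvae: int


def summarize_boutons(
    records: Sequence[BoutonRecord], wt_genotype: str
) -> dict[str, BoutonSummary]:
    """Area-normalized density summaries per genotype.

    The wild-type mean muscle area (from ``wt_genotype`` records) is the
    normalization reference for every genotype.
    """
    wt_areas = [r.muscle_area for r in records if r.genotype == wt_genotype]
    if not wt_areas:
        raise ValueError(f"no records for reference genotype {wt_genotype!r}")
    wt_mean_area = float(np.mean(wt_areas))
    grouped: dict[str, list[float]] = {}
    for r in records:
        grouped.setdefault(r.genotype, []).append(
            normalize_bouton_density(r, wt_mean_area)
        )
    return {
        g: BoutonSummary(
            genotype=g,
            densities=tuple(v),
            mean=float(np.mean(v)),
            sem=sem(v),
            n_larvae=len(v),
        )
        for g, v in grouped.items()
    }


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    # (group_a, group_b) -> (t, raw p, adjusted p)
    pairwise: dict[tuple[str, str], tuple[float, float, float]]

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        return [k for k, (_, _, p) in self.pairwise.items() if p <= alpha]


def bouton_anova(
    groups: Mapping[str, Sequence[float]], adjustment: str = "bonferroni"
) -> AnovaResult:
    """One-way ANOVA across genotype density groups with all pairwise
    pooled-variance t contrasts, family-wise adjusted (Bonferroni by
    default; ``none`` disables adjustment)."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 observations per group")
    if all(a.var(ddof=1) == 0 for a in arrays):
        if len({a.mean() for a in arrays}) > 1:
            raise ValueError("zero within-group variance with distinct means")
        # identical constant groups: no evidence of any difference
        pairs = {
            (names[i], names[j]): (0.0, 1.0, 1.0)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
        return AnovaResult(f_statistic=0.0, p_value=1.0, pairwise=pairs)
    f, p = stats.f_oneway(*arrays)
    m = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
                t_ij, p_ij = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            else:
                t_ij, p_ij = stats.ttest_ind(a, b, equal_var=True)
            adj = p_ij if adjustment == "none" else min(1.0, float(p_ij) * m)
            pairwise[(names[i], names[j])] = (float(t_ij), float(p_ij), float(adj))
    return AnovaResult(f_statistic=float(f), p_value=float(p), pairwise=pairwise)
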