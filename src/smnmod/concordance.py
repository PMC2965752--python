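"""Cross-species modifier polarity and concordance logic.

A modifier observation is a (perturbation, effect) pair: the
perturbation direction (loss of function, RNAi knockdown — treated as
lof-direction — or over-expression) and the effect on the SMN
loss-of-function phenotype (enhance or suppress).  Combining the two
gives the gene's polarity: a gene whose *loss* enhances the phenotype is
protective (its normal activity buffers SMN loss), as is a gene whose
*over-expression* suppresses; the mirror combinations are detrimental.
Unknown perturbations, complex interactions, and undetermined effects
block the inference.

For a true cross-species modifier the polarity should be conserved: an
enhancer gene should enhance in both species.  The verdict is
``concordant`` when both species' polarities are defined and equal,
``discordant`` when both are defined and differ, else ``unclear``; the
rule is symmetric in species order.

Ortholog pairing is abstracted as reciprocal best hits over a supplied
similarity matrix (higher score = more similar); BLAST itself is out of
scope.  Transcriptions of the published worm growth/pumping outcomes
and the cross-species summary table ship as TSV fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ModifierAnnotation",
    "ConcordanceVerdict",
    "infer_polarity",
    "concordance",
    "summarize_annotations",
    "count_cross_species_modifiers",
    "reciprocal_best_hits",
    "load_table_modifiers",
    "load_table_outcomes",
]

PERTURBATIONS = ("lof", "oe", "rnai", "unknown")
EFFECTS = ("enhance", "suppress", "complex", "none", "not_determined")
SPECIES = ("worm", "fly")
ASSAYS = ("growth", "pumping", "lethality", "nmj")


@dataclass(frozen=True)
class ModifierAnnotation:
    gene_id: str
    species: str  # worm | fly
    assay: str  # growth | pumping | lethality | nmj
    perturbation: str  # lof | oe | rnai | unknown
    effect: str  # enhance | suppress | complex | none | not_determined

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if self.effect not in EFFECTS and self.effect != "unknown":
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass(frozen=True)
class ConcordanceVerdict:
    gene_worm: str
    gene_fly: str
    polarity_worm: str  # protective | detrimental | unclear
    polarity_fly: str
    verdict: str  # concordant | discordant | unclear


def infer_polarity(perturbation: str, effect: str) -> str:
    """Polarity of a modifier from perturbation direction and effect.

    RNAi is canonicalized to lof-direction.  (lof, enhance) and
    (oe, suppress) are protective; (lof, suppress) and (oe, enhance)
    are detrimental; anything else (unknown perturbation, complex /
    absent / undetermined effect) is unclear.
    """
    pert = "lof" if perturbation == "rnai" else perturbation
    if pert not in ("lof", "oe") or effect not in ("enhance", "suppress"):
        return "unclear"
    if pert == "lof":
        return "protective" if effect == "enhance" else "detrimental"
    return "detrimental" if effect == "enhance" else "protective"


def concordance(
    worm: ModifierAnnotation, fly: ModifierAnnotation
) -> ConcordanceVerdict:
    """Cross-species verdict for one orthologous gene pair."""
    annotations = {a.species: a for a in (worm, fly)}
    if set(annotations) != {"worm", "fly"}:
        raise ValueError("need one worm and one fly annotation")
    w, f = annotations["worm"], annotations["fly"]
    pw = infer_polarity(w.perturbation, w.effect)
    pf = infer_polarity(f.perturbation, f.effect)
    if pw == "unclear" or pf == "unclear":
        verdict = "unclear"
    elif pw == pf:
        verdict = "concordant"
    else:
        verdict = "discordant"
    return ConcordanceVerdict(
        gene_worm=w.gene_id,
        gene_fly=f.gene_id,
        polarity_worm=pw,
        polarity_fly=pf,
        verdict=verdict,
    )


ANNOTATION_COLUMNS = [
    "gene_worm",
    "gene_fly",
    "assay",
    "worm_perturbation",
    "worm_effect",
    "fly_perturbation",
    "fly_effect",
]


def summarize_annotations(annotations: pd.DataFrame):
    """Verdicts and summary counts for a table of annotation pairs.

    ``annotations`` has one row per gene per assay with the columns
    ``ANNOTATION_COLUMNS`` (an ``origin`` column, if present, is carried
    through).  Returns ``(verdicts, counts)`` where ``verdicts`` adds
    polarity and verdict columns, and ``counts`` holds: the number of
    genes with a defined worm modifier polarity or effect in >= 1 assay,
    the number of clearly concordant genes (overall and per assay), and
    the number of discordant gene/assay rows.
    """
    df = annotations.copy()
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing annotation columns: {missing}")
    if df.duplicated(subset=["gene_worm", "assay"]).any():
        dupes = df[df.duplicated(subset=["gene_worm", "assay"], keep=False)]
        raise ValueError(
            f"duplicate gene/assay rows: {sorted(set(dupes['gene_worm']))}"
        )
    verdicts = []
    for _, row in df.iterrows():
        v = concordance(
            ModifierAnnotation(row["gene_worm"], "worm", row["assay"],
                               row["worm_perturbation"], row["worm_effect"]),
            ModifierAnnotation(row["gene_fly"], "fly", row["assay"],
                               row["fly_perturbation"], row["fly_effect"]),
        )
        verdicts.append(
            {"polarity_worm": v.polarity_worm, "polarity_fly": v.polarity_fly,
             "verdict": v.verdict}
        )
    vcols = pd.DataFrame(
        verdicts, columns=["polarity_worm", "polarity_fly", "verdict"]
    )
    out = pd.concat([df.reset_index(drop=True), vcols], axis=1)
    modifying = out[out["worm_effect"].isin(["enhance", "suppress", "complex"])]
    concordant = out[out["verdict"] == "concordant"]
    counts = {
        "n_genes": int(out["gene_worm"].nunique()),
        "n_worm_modifier_genes": int(modifying["gene_worm"].nunique()),
        "n_concordant_genes": int(concordant["gene_worm"].nunique()),
        "n_discordant_rows": int((out["verdict"] == "discordant").sum()),
    }
    for assay in out["assay"].unique():
        sub = out[out["assay"] == assay]
        counts[f"n_concordant_{assay}"] = int(
            (sub["verdict"] == "concordant").sum()
        )
    return out, counts


def count_cross_species_modifiers(
    outcomes: pd.DataFrame, origin: str = "fly_screen"
) -> int:
    """Genes from ``origin`` with a significant effect in >= 1 worm assay.

    ``outcomes`` is a per-gene, per-assay, per-arm table of worm assay
    results (see :func:`load_table_outcomes`) with boolean
    ``significant`` and string ``origin`` columns.
    """
    sub = outcomes[(outcomes["origin"] == origin) & outcomes["significant"]]
    return int(sub["gene_worm"].nunique())


def reciprocal_best_hits(similarity: pd.DataFrame) -> list[tuple[str, str]]:
    """Ortholog pairs by reciprocal best hit on a gene x gene score table.

    Rows are one species' genes, columns the other's; higher scores mean
    more similar.  A pair (a, b) is emitted iff b is a's unique best hit
    and a is b's unique best hit; a tied best hit yields no pair for the
    tied gene.  The result is a partial matching.
    """
    if similarity.size == 0:
        return []
    m = similarity.to_numpy(dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("similarity scores must be finite")
    pairs = []
    row_max = m.max(axis=1)
    col_max = m.max(axis=0)
    for i, a in enumerate(similarity.index):
        best_j = np.flatnonzero(m[i] == row_max[i])
        if best_j.size != 1:
            continue  # tie: no call for this gene
        j = best_j[0]
        best_i = np.flatnonzero(m[:, j] == col_max[j])
        if best_i.size != 1 or best_i[0] != i:
            continue
        pairs.append((str(a), str(similarity.columns[j])))
    return pairs


def _load_tsv(name: str) -> pd.DataFrame:
    with resources.files("smnmod.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table_modifiers() -> pd.DataFrame:
    """Published cross-species modifier summary (perturbation/effect codes
    per gene per worm assay, with the fly observation alongside)."""
    return _load_tsv("cross_species_modifiers.tsv")


def load_table_outcomes() -> pd.DataFrame:
    """Published worm growth and pumping outcomes (per gene, per assay,
    per genotype arm: value, SEM, significance flag, direction)."""
    df = _load_tsv("worm_assay_outcomes.tsv")
    df["significant"] = df["significant"].astype(bool)
    return df
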