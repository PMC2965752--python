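# Methods

## The system being modelled

A recessive lethal SMN-ortholog deletion in *C. elegans* is maintained
over a balancer chromosome carrying a pharyngeal GFP marker and its own
recessive lethal. Heterozygous mothers therefore produce progeny 1:2:1
(mutant homozygote : heterozygote : balancer homozygote); balancer
homozygotes die as embryos, so hatched larvae are ~1/3 GFP-negative
mutant homozygotes and ~2/3 GFP-positive heterozygotes. Homozygotes are
initially indistinguishable from siblings because the mother loads SMN
product into the oocyte (maternal rescue); once that store is depleted
they grow slowly, are short for their stage, feed poorly, and mostly
die before adulthood. A flow sorter measures each animal's length as
time-of-flight (TOF) and its GFP fluorescence, so genotype and size are
read in one pass over thousands of animals.

## Sorter population model (`smnmod.simulate`)

Each culture well holds `n_broods × brood_size` progeny. Hatch days are
drawn per animal with geometric weights `(1 + hatch_spread)^day`,
representing the standing age structure of an expanding culture laying
eggs continuously; with a single brood (`n_broods=1`,
`hatch_spread=0`) the cohort hatches synchronously at day 0, which is
the configuration used for closed-form checks. Development is a daily
Markov chain over stages L1–L4 and adult: each animal advances one
stage per day with probability `genotype_growth_rate` and dies with
probability `mortality_hazard`. Maternal rescue is age-based:
homozygotes use the heterozygous growth rate, suffer no excess
mortality, and ignore homozygote-directed clone effects until their age
exceeds `maternal_depletion_day`; afterwards their own (lower) growth
rate, excess hazard, stage-conditional length shift, and any planted
modifier multipliers apply. Measured TOF is log-normal around a
per-stage location; GFP is log-normal per genotype class; debris events
(binomial per progeny slot at `debris_rate`) mimic the smallest larvae
and are GFP-negative. RNAi clone effects are multipliers on the
stage-advance probability and death hazard of the affected genotype,
scaled toward the identity by `knockdown_efficacy` (feeding RNAi is
incompletely penetrant, especially in neurons — a reduced efficacy is
the natural way to model a neuronal target).

Key defaults (the frozen study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| stage TOF means | 100/170/280/450/700 sorter units | arbitrary units, ~2× per stage; never calibrated to microns |
| TOF scale (log) | 0.12 | within-stage size spread |
| growth rate het/homo | 0.65 / 0.35 per day | heterozygotes reach adulthood in ~1 week; homozygotes stall after depletion |
| maternal depletion | age > 2 days | deficits emerge on day 2–3 |
| homozygote hazard | 0.3/day post-depletion | "most die before adulthood" over an 8-day culture |
| homozygote length shift | −0.22 log units | homozygotes short for stage |
| GFP classes (log) | ln 1000 ± 0.5 vs ln 5 ± 0.5 | well-separated marker; overlap integral ~1e−7 |
| well size | 8 broods × 40 progeny (~320) | cultures of "more than 200 animals" |
| culture day (screen) | 8 | two-generation liquid culture |
| debris rate | 0.05 | small-object contamination |

Pump counts are negative-binomial (dispersion `pumping_dispersion`,
default 30) around mean rate 250/min for healthy animals over a 10 s
window; homozygote rates decline geometrically (×0.45) for each day
past maternal depletion, reproducing normal day-1 behaviour and a
collapse by day 3. Pupal fates are a single multinomial over
early-death / late-death / eclosed. Bouton counts are Poisson with mean
proportional to a log-normal muscle area.

What the generator deliberately does not emulate: bacterial food
dynamics, liquid-vs-plate culture differences beyond effect sizes,
RNAi molecular mechanism, sorter optics (extinction profiles), plate
row/column gradients, and between-day environmental drift. Tests
passing on this generator therefore certify the statistical machinery
and its calibration under the stated model, not robustness to every
artefact of real sorter data.

## Gating and the growth statistic (`smnmod.gating`)

Events shorter than `debris_min_length` (140 units, the L2 boundary)
are excluded — the closed bound (≥ keeps the boundary event) is a
documented convention. Among gated events, GFP strictly above threshold
⇒ heterozygous, else homozygous; the default threshold (100) is the
midpoint of the class medians on the log scale, and
`estimate_gfp_threshold` recovers a threshold from data by a two-means
split when none is configured. "% large" for a genotype is the
fraction of its gated events at or above `large_min_length`.

"Large" means L3/L4/adult, so the boundary is placed between the L2 and
L3/L4 length bands: 300 units for homozygotes, 340 for heterozygotes
(genotype-specific boundaries are supported because homozygotes are
short for their stage; a shared boundary is configurable). Placing the
boundary this high matters mechanistically: maternally rescued young
homozygotes grow normally, so a boundary near L2 would count them as
"large" and make the statistic insensitive to post-depletion modifier
effects. Under the frozen defaults the control condition yields ~17%
large homozygotes and ~40% large heterozygotes, closely matching the
published control determinations (18 ± 2 and 46 ± 1).

## Growth comparisons (`smnmod.growth`)

The experimental unit is the independent trial; three to six trials per
condition, and treated-vs-control significance is a two-tailed
Mann-Whitney *U* on the per-trial fractions at α = 0.05. The reported
statistic is the classical U = min(U₁, U₂). For combined n ≤ 12 the
two-sided p is exact: with no ties scipy's exact method is used (the
null is symmetric, so twice the smaller tail equals the
extremity-of-|U − mean| count); with ties the full set of label
assignments is enumerated with half-credit tie scoring. Larger samples
use the tie-corrected normal approximation. At 3v3 the smallest
attainable two-sided p is 0.1 — three-trial comparisons can never reach
0.05, which is why null simulations of the classifier at three trials
show a strictly zero false-positive rate, and why the type-I
calibration is run at six trials per arm (the top of the stated range),
where the exact test's attainable level is ≈0.041.

Classification: enhancer = significant homozygote decrease with an
unchanged heterozygous control; suppressor = significant homozygote
increase, control unchanged; any significant heterozygous change is
"nonspecific" regardless of the homozygote result. No multiple-testing
correction is applied across candidate tables (none was applied in the
assay design this mirrors); the result object carries an explicit
`multiple_testing_corrected=False` flag rather than a silent policy.

Chi-square comparisons (used for mutant-allele × genotype count tables
and fly lethality) are Pearson without continuity correction,
df = k − 1, implemented directly so that `scipy.stats.chi2_contingency`
and the 2×2 closed form n(ad−bc)²/(r₁r₂c₁c₂) remain independent
oracles in the tests. Zero expected cells raise an error instructing
category pooling.

## Screen hit calling (`smnmod.screen`)

Per well and genotype, the growth ratio is n_large/n_small; wells with
fewer than 20 events of the genotype or no small animals are unusable
and carry a reason code. Ratios are standardized within
plate × genotype × trial over usable clones (≥8 required, else the
plate is skipped; zero variance flags it degenerate). A clone is a
per-trial candidate iff |z_homo| > 2 and |z_het| < 0.7, both strict.
The rule is two-sided — enhancers and suppressors are both sought — and
the direction label (deficit = enhancer by default) is applied after
calling, because the orientation of a plotted ratio is a reporting
convention, exposed as the `deficit_is_enhancer` flag. Confirmation is
two-stage: flagged in both of exactly two primary trials, then flagged
in ≥40% of ≥4 retest trials.

Calibration facts, measured by `smnmod.calibration` under the frozen
conditions: the null per-trial candidate rate is close to (within a
factor-two band of) the normal composition
P(|Z|>2)·P(|Z|<0.7) ≈ 0.023 — the band is wide a priori because
plate-standardized count ratios are only approximately normal in the
tails — and the null confirmed-hit rate is ≈ p² · P(Binom(4,p) ≥ 2),
i.e. ~10⁻⁶, far below 1%. The specificity filter imposes a hard power
ceiling: for a perfectly genotype-specific modifier the heterozygote
well is exchangeable with its plate-mates, so z_het is standard normal
by construction and |z_het| < 0.7 holds with probability ≈ 0.52 per
trial no matter the effect size. Composed through the two-stage rule
this caps per-clone confirmation near 0.52² × P(Binom(4, ·) ≥ 2) ≲ 0.2
even at perfect homozygote detection, and at realistic per-well animal
numbers the ratio's binomial noise further bounds |z_homo| (a ratio
cannot fall below zero, so |z| cannot exceed ~1/CV of the plate's null
ratios). The procedure is faithfully stringent: it almost never
confirms anything by chance and only rarely confirms true strong
enhancers — consistent with a genome-wide screen recovering a handful
of modifiers from ~16,500 clones.

## Pumping analysis (`smnmod.pumping`)

Rates are count × 60/window. The effect measure is the per-trial
percent change 100 × treated/control — a ratio, not a delta, so
suppressors exceed 100% — computed within trial because absolute rates
drift day to day; treated and control trials pair by trial id and
unmatched ids are an error. Significance defaults to the per-trial
percent changes against 100% (animal-level pooling is available), with
the test chosen by an explicit screening rule: Shapiro-Wilk normality
on every sample at α = 0.05 plus a variance-ratio < 4 check for
two-sample comparisons; failures, or samples smaller than three, fall
to the rank test (Wilcoxon signed-rank in the one-sample case). The
rule is recorded in the output and overridable.

## Fly assays (`smnmod.fly`)

Lethality: Pearson chi-square on the 2×2 of early- vs late-pupal death
counts (experimental vs control cross); a dead-vs-eclosed
categorization is selectable. Boutons: each larva's count is divided by
its muscle area expressed relative to the wild-type mean area, giving
boutons per wild-type-equivalent area; genotypes compare by one-way
ANOVA. "ANOVA multiple comparison" is realized as all pairwise
pooled-variance t contrasts with Bonferroni family-wise adjustment —
chosen as the simplest conservative reproducible post-hoc; the
adjustment is a flag, and adjusted p ≥ raw p always.

## Concordance (`smnmod.concordance`)

Polarity combines perturbation direction with effect: loss-direction
perturbations (lof, RNAi — canonicalized to lof) that enhance, and
over-expression that suppresses, mark a gene protective; the mirror
combinations detrimental; unknown perturbations and
complex/absent/undetermined effects are unclear and block the verdict.
Cross-species concordance requires equal defined polarities; defined
but unequal polarities are discordant; anything else is unclear — and
the verdict is symmetric in species order. Genes with heterozygote-only
("complex") growth interactions are deliberately left unclear rather
than forced to a sign. Ortholog pairing is reciprocal best hit on a
supplied similarity matrix; tied best hits yield no pair, and the
output is always a partial matching. The packaged tables transcribe the
published worm growth/pumping outcomes and cross-species
perturbation/effect codes; the summarizer reports several count
variants (genes with any worm effect, clearly concordant genes overall
and per assay, discordant rows) rather than privileging one.

## Numerical and procedural choices

* Seeds: every generator takes an explicit seed; identical
  (config, seed) pairs reproduce outputs exactly. Monte-Carlo routines
  derive per-replicate seeds from one `numpy` generator.
* Boundary conventions: debris gate closed (≥), GFP call strictly
  greater, candidate thresholds strict ("more than" / "within"),
  pass-fraction ≥ 0.4 closed.
* Degenerate inputs raise typed errors rather than returning silent
  zeros: 0/0 % large, zero-variance ANOVA with distinct means, rows of
  zeros in contingency tables, unpaired pumping trials.
* Problem sizes for the calibration runs: type-I error at 1,000
  replicates per procedure in the test suite (500 in the reproduction
  script), planted-enhancer power at 200 replicates of a 1,536-clone,
  6-trial screen (100 in the script), exact-test oracles at 500
  random Mann-Whitney cases plus an exhaustive sweep of all 2×2 tables
  with total count ≤ 50.

## Known limitations

* TOF is never mapped to physical length; all thresholds are in sorter
  units and would need recalibration against real instrument data.
* The stage-advance chain has no within-stage ageing, so length
  distributions are mixtures of per-stage log-normals rather than a
  continuous growth curve.
* Death removes an animal from measurement entirely; carcasses are not
  simulated as events.
* The pumping day-course is geometric decline only; it does not model
  recovery, molt pauses, or inter-individual frailty correlation
  across days.
* The power ceiling analysis above is a property of the published
  candidate rule itself; no generator setting can raise the
  heterozygote filter's ~52% per-trial pass rate for truly specific
  modifiers.
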