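# Methods

`mirmint` re-implements, as a tested library, an integrative miRNA–mRNA
analysis of atrial tissue across three clinical stages — patients without
atrial fibrillation (nonAF), with paroxysmal AF (parAF) and with persistent
AF (persAF). The pipeline combines per-feature differential expression,
a target-database voting rule, anti-correlation pair discovery, and a set
of permutation and Kolmogorov–Smirnov tests that together ask whether
differentially expressed miRNAs exert a detectable repressive effect on the
mRNA signature.

## Differential expression

Counts are normalised to counts per million (CPM) using the raw column sum
as library size, and variance-stabilised as
`log2((count + c) / (libsize + 2c) * 1e6)` with pseudo-count `c = 0.5`.
For each feature an ordinary-least-squares model

    log2CPM ~ 1 + I(parAF) + I(persAF) + age + gender

is fit, and the three pairwise contrasts (persAF−nonAF, parAF−nonAF,
persAF−parAF) are reported with t-based p-values (df = n − 5) and
Benjamini–Hochberg FDR computed within each contrast across features.
Design notes:

* No empirical-Bayes variance moderation or precision weights are applied.
  Plain OLS keeps the estimator transparent; its calibration (uniform null
  p-values) and parameter recovery are verified directly on synthetic
  cohorts in the test suite.
* FDR is computed per contrast, not pooled, mirroring the per-comparison
  FDR columns of the reference tables. Whether a pooled family would
  change the selection is an open sensitivity question.
* No between-sample normalisation beyond CPM (no TMM). Under strongly
  asymmetric composition this shifts all log-fold-changes by a common
  offset (see Limitations); the contrast identity
  `log2FC(persAF−nonAF) = log2FC(parAF−nonAF) + log2FC(persAF−parAF)`
  holds exactly regardless, by linearity.

Selection rules, with defaults matching the reference analysis:
a feature is *DE* if FDR < 0.05 (strict) in ≥ 1 contrast; the *top-DE*
selection additionally requires |log2FC| > 1 in a contrast that is itself
significant, and average log2-CPM (AveExpr) > 1. The "CPM > 1" expression
cut-off is interpreted on the AveExpr scale, following the reference
table's column definition. A feature's stage profile is *ordinal* when
both incremental contrasts (nonAF→parAF, parAF→persAF) share a sign
beyond a tolerance (default 0, i.e. strict sign agreement).

## Target-database voting

Six evidence sources are modelled: four in-silico prediction databases
with per-source score thresholds (miRDB score ≥ 75; TargetScan total
context score ≥ −0.30; DIANA-microT score ≥ 0.85; RNA22 score ≥ 0.02 with
binding free energy ≤ −18 kcal/mol) and two experimentally validated
databases (miRTarBase, DIANA-TarBase) used without score filtering.
A pair is *predicted* iff supported by ≥ 2 prediction databases, or by
1 prediction database plus ≥ 1 validated database. Two deliberate choices:

* Validated-only support does **not** qualify a pair. The rule is applied
  literally; it is counter-intuitive and therefore asserted explicitly in
  the tests.
* The TargetScan comparison is applied as printed (`score ≥ −0.30`).
  Because more-negative context scores indicate *stronger* predicted
  repression, this direction keeps the weaker predictions; the flipped
  comparison is available behind `ThresholdConfig.targetscan_keep_weaker
  = False`. The default follows the printed rule.

Duplicate records from one source count once; adding evidence can only
grow the predicted set (monotonicity, property-tested).

## Correlation network

Pearson correlations are computed between each DE miRNA and every mRNA on
log2-CPM across all samples pooled, without covariate adjustment (the
reference procedure is plain correlation; adjustment is a sensitivity
question). Two-sided p-values come from the t transform of r; BH FDR is
taken across the whole DE-miRNA × mRNA grid as a single family.
Zero-variance profiles produce records with undefined r that are excluded
from the FDR family but never dropped silently. Significant pairs are
r < −0.4 (negative set) or r > +0.4 (positive set) at FDR < 0.05, all
strict inequalities. *Interactions* are the intersection of the negative
set with the predicted pair set.

## Enrichment statistics

**Pair enrichment.** Whether predicted pairs are over-represented among
the selected (anti-correlated) pairs is tested by resampling the selected
set, with `enrichment = observed / mean(null)` and the +1-corrected
permutation p-value `p = (1 + #{null ≥ obs}) / (n_perm + 1)`
(n_perm = 1000 by default). Two null schemes are implemented because the
original permutation construction is not published:

* `stratified` (default): per miRNA, its number of selected mRNAs is
  redrawn uniformly from that miRNA's tested mRNAs. This preserves
  per-miRNA selection counts — the dominant confounder, since predicted
  target counts vary strongly between miRNAs.
* `pooled`: the total selected count is redrawn from the whole grid.

Under either scheme the null overlap is exactly a (sum of) hypergeometric
draw(s), which is how the Monte-Carlo null is realised — mathematically
identical to explicit resampling and much faster. Both schemes are checked
against exhaustive subset enumeration on small universes, and they agree
in expectation on exchangeable grids.

**KS target shift.** Per top-DE miRNA, a one-sided two-sample
Kolmogorov–Smirnov test compares the correlation coefficients of its
predicted targets against non-predicted mRNAs, with the alternative that
predicted targets are shifted toward more negative r. mRNAs with mean
CPM ≤ 3 are excluded first, since a repressive effect is only detectable
for adequately expressed genes. The statistic is
`D+ = sup_t (F_pred(t) − F_non(t))`. The p-value is exact — integer
lattice-path counting over the pooled order statistics — when the combined
group size is ≤ 25 and there are no cross-group ties, and otherwise uses
Smirnov's one-sided tail with Hodges' continuity correction. Both branches
agree with an independent reference implementation to 1e-10.

**Gene-set regulation.** For each gene set, the observed score is the
number of distinct DE miRNAs with ≥ 1 predicted target inside the set
(the alternative score, total predicted-target hits, is available via
`score="total_hits"`); the null redraws equally many miRNAs uniformly from
all miRNAs. BH is applied across sets. The summary `overall_factor` is the
number of sets with p < α over the count expected at α — e.g. 32
significant of 270 sets at α = 0.05 gives 32/13.5 ≈ 2.37, i.e. "2.4-fold
over chance". This reading of the overall factor is an interpretation and
is labelled as such in the output.

**Over-representation.** A self-contained upper-tail hypergeometric test
(conditioning on a user-supplied background universe) stands in for web
gene-set services; it makes no attempt to emulate their bespoke
multiple-testing procedures beyond BH.

Permutation streams are derived from `(seed, test label, unit id)`, so
per-set and per-strategy results are reproducible independent of
evaluation order.

## Synthetic cohorts

The generator (`mirmint.synthetic`) emulates the reference study design:
22 + 22 + 20 patients across nonAF/parAF/persAF, with ages uniform on
[50, 80] years and gender Bernoulli(0.5). Each feature has a latent
per-sample log2 abundance with a uniform baseline on [2, 10] log2-CPM,
small random age and gender coefficients (SD 0.01 /year and 0.1 log2
units, so covariate correction is exercised), and N(0, `latent_sd`²)
biological noise (default SD 0.8 log2 units). Planted group effects move
ordinal features by `effect_log2fc` (default 1) per stage; non-ordinal
features get a transient up-then-back pattern. Default fractions: 12% of
miRNAs and 20% of mRNAs DE, 79% of planted effects ordinal — matching the
proportions of the reference cohort at the package's desk-scale universe
of 120 miRNAs × 800 mRNAs.

Planted repression: 150 couplings draw their regulators from the
planted-DE miRNAs and their targets from distinct non-DE mRNAs; a target's
latent mean decreases by `coupling_k` (default 1) per unit of its
regulator's *centred latent* (count-noise-free) log2 expression, keeping
the sign of the planted correlation analytically known. Counts are
negative-binomial with mean `libsize · 2^latent / 1e6` (library sizes
uniform on [1e6, 3e6]) and dispersion 0.2 (`var = μ + 0.2 μ²`).

Evidence databases emit each planted pair per source with probability
`db_sensitivity` (default 0.8) and unplanted decoys at per-source rate
`db_decoy_rate` (default 0.01), with scores drawn to pass the reference
thresholds. Gene sets (270 by default, sizes 10–40) over-sample planted
target mRNAs with weight `set_enrichment` (default 3) in a 12% subset of
enriched sets, recorded in the ground truth.

What the generator does *not* emulate — and hence what passing tests do
not show about real tissue data: correlated co-expression modules beyond
the planted couplings, many-to-one miRNA targeting of a single mRNA (each
synthetic target has exactly one regulator, so multi-miRNA target genes
arise only from the worked-example tables), sponging or other positive
predicted-target correlations, compositionally realistic library
structure, count outliers, or batch effects.

## Calibration design

Under a fully null cohort (no effects, no coupling) the reference
selection rule (r < −0.4 at grid-wide FDR < 0.05) correctly returns an
essentially empty pair set, which would make the enrichment p degenerate.
The calibration suite therefore selects a fixed-size set of the K most
negative pairs (K = 150, fixed a priori); under the null this selection is
independent of the databases, so it exercises the identical permutation
machinery at a non-degenerate size. Observed behaviour across seeds:
rejection rate ≈ 5% at α = 0.05 and mean enrichment ≈ 1. For the same
reason, the null type-I property of the DE stage is asserted on raw
p-values (≈ 5% below 0.05, uniform by a KS check) — under a complete null
BH flags a near-zero *fraction* of features, which is also asserted.

## Problem sizes

Simulation-based tests run at 60 miRNAs × 300 mRNAs (40 seeds for
calibration, 20 for each recovery property), chosen so the whole suite
completes in well under a minute while keeping every selection step
populated. The acceptance script runs the full pipeline once at the
default 120 × 800 scale with 1000 permutations.

## Known limitations

* CPM normalisation without a trimmed-mean correction transfers
  composition shifts into a common log-fold-change offset when planted
  effects are strongly asymmetric; the effect-recovery tests quantify this
  (estimates remain well inside the Monte-Carlo 95% recovery interval).
* The OLS t-test is approximate for low-count features whose log2-CPM is
  markedly non-normal; the null-uniformity test bounds the practical
  impact at the simulated depths.
* The exact KS branch assumes no cross-group ties; tied inputs fall back
  to the asymptotic formula.
* Identifiers are opaque strings; no nomenclature validation or cross-
  release mapping is attempted.
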