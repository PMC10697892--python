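# mirmint

Integrative miRNA–mRNA analysis of atrial fibrillation (AF) tissue:
differential expression across disease stages, target-database voting,
anti-correlation pair discovery, and permutation/Kolmogorov–Smirnov
enrichment statistics — with a synthetic cohort generator that plants
known miRNA→mRNA repression for end-to-end validation.

## The problem

Atrial fibrillation is accompanied by structural remodelling of the
atrium, and miRNAs are candidate post-transcriptional regulators of that
process. Given miRNA and mRNA counts from the same patients across three
stages — no AF (`nonAF`), paroxysmal AF (`parAF`) and persistent AF
(`persAF`) — the question is whether differentially expressed (DE) miRNAs
measurably repress the mRNA signature, and which miRNA–mRNA interactions
drive it. `mirmint` is aimed at computational biologists who want that
analysis as a reusable, tested pipeline rather than a one-off script.

## The method

1. **Differential expression.** Per feature, OLS on log2-CPM
   (pseudo-count 0.5) with group indicators plus age and gender; the three
   contrasts parAF−nonAF, persAF−nonAF, persAF−parAF get t-based p-values
   and per-contrast Benjamini–Hochberg FDR. DE: FDR < 0.05 in ≥1 contrast;
   top-DE additionally |log2FC| > 1 in a significant contrast and
   AveExpr > 1. Stage profiles with sign-consistent incremental changes
   are classified *ordinal*.
2. **Predicted pairs.** Per-source score thresholds (miRDB ≥ 75,
   TargetScan context ≥ −0.30, DIANA-microT ≥ 0.85, RNA22 ≥ 0.02 with
   free energy ≤ −18), then the voting rule: ≥2 prediction databases, or
   1 prediction database + ≥1 validated database (miRTarBase,
   DIANA-TarBase).
3. **Interactions.** Pearson r of each DE miRNA against all mRNAs on
   log2-CPM; pairs with r < −0.4 at grid-wide FDR < 0.05 intersected with
   the predicted set.
4. **Inference.** Permutation enrichment of predicted pairs among the
   anti-correlated pairs (stratified-by-miRNA null, 1000×, +1-corrected
   p); per-miRNA one-sided KS tests comparing correlation distributions
   of predicted vs non-predicted targets (mRNAs with CPM > 3); a gene-set
   regulation permutation test with an overall "fold over chance" factor;
   and a hypergeometric over-representation test for interaction targets.

See `docs/methods.md` for model details, null constructions and
limitations.

## Worked example

A self-contained run simulates a cohort with planted repression (150
couplings, repression strength 1 log2 unit, database sensitivity 0.8) and
analyses it at the reference thresholds:

```python
from mirmint import AnalysisConfig, SimConfig, run_pipeline, report_summary

cfg = AnalysisConfig()
cfg.seed = 7
cfg.sim = SimConfig(seed=7)
summary = run_pipeline(cfg, outdir="runs/demo")
print(report_summary(summary))
```

Abridged output:

```
Stage counts
------------
                 samples: 64
               de_mirnas: 14
         predicted_pairs: 262
          negative_pairs: 520
            interactions: 140

Ordinal trend
-------------
11 of 14 DE miRNAs (79%) follow an ordinal stage trend

Pair enrichment
---------------
negative: observed 140 vs expected 7.6 -> enrichment 18.31 (p=0.000999, 1000x stratified)
positive: observed 1 vs expected 6.3 -> enrichment 0.16 (p=0.999, 1000x stratified)

Ground-truth recovery
---------------------
     planted_pair_recall: 0.993
         de_mirna_recall: 0.929
```

Reading: of the 64 simulated patients, 14 miRNAs come out DE and 79% of
them follow the ordinal nonAF→parAF→persAF trend; the 140 interactions
(anti-correlated ∧ predicted) are 18-fold more frequent than the
permutation null expects (p at the 1000-permutation floor), and 99% of
the planted couplings that entered the tested grid are recovered —
whereas positively correlated pairs show no predicted-target enrichment,
as they should not under a repression-only generator.

The same pipeline runs from files
(`mirmint run --config cfg.yaml --outdir out`), and each stage is
available as a subcommand (`simulate`, `de`, `targets`, `correlate`,
`enrich`, `report`) over the intermediate TSV/CSV/GMT/JSON files.

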