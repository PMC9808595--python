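# pbscreen

Analysis toolkit for **piggyBac gain-of-function insertional-mutagenesis
screens** and the downstream **multi-gene survival signature** they feed.
It is aimed at groups running transposon activation screens in cultured
tumor cells (here: cisplatin selection of an osteosarcoma mutant library)
who then ask whether the enriched genes carry prognostic information in an
expression + disease-free-survival (DFS) cohort.

The package covers the full path from raw splinkerette junction reads to a
validated risk model, with a synthetic-data generator that produces every
input with known ground truth, so each stage is verifiable at desk scale.

## What it computes

**Screen arm.** piggyBac integrates at TTAA tetranucleotides. Junction
reads carry a PB5′/PB3′ inverted-terminal-repeat (ITR) tag at their 5′ end;
`pbscreen.trim` recognizes the tag (anchored Hamming match), removes tag and
read-through adapter, and emits genomic flanks. `pbscreen.sites` aligns the
flanks (exact unique-hit search on the toy reference, or `import_sam` for
external aligner output), snaps each junction to its TTAA start, aggregates
strand-aware insertion sites with per-library read support, and builds the
gene × library count matrix. `pbscreen.enrichment` tests each gene's read
proportion in a selected library against the unselected control with a
two-sided Fisher exact test, applies Benjamini–Hochberg FDR, classifies
genes at the volcano thresholds (log₂FC > 1, −log₁₀ adj-p > 2), and
intersects the up-calls across selection doses.

**Survival arm.** `pbscreen.survival` implements the product-limit
(Kaplan–Meier) estimator Ŝ(t) = Π_{tᵢ≤t}(1 − dᵢ/nᵢ), the two-group log-rank
test, and a multivariate Cox proportional-hazards fit maximizing the Efron
tie-corrected partial likelihood by Newton–Raphson, reporting β, SE, hazard
ratios exp(β) with 95% CIs, the log partial likelihood and
AIC = −2·logPL + 2k. The per-sample risk score Σ_g β_g x_g dichotomizes the
cohort at its median; time-dependent cumulative/dynamic ROC with
inverse-probability-of-censoring weights evaluates prediction at a horizon;
a five-group stratification counts how many signature genes sit at/above
their cohort median. `pbscreen.dge` adds a limma-style moderated-t test
(empirical-Bayes variance shrinkage), and `pbscreen.pathway` provides
hypergeometric over-representation against user-supplied GMT gene sets and
hub scoring (degree or Maximal Clique Centrality, MCC(v) = Σ_{C∋v}(|C|−1)!)
on a user-supplied interaction network.

`pbscreen.pipeline.run_pipeline` chains everything from one JSON config with
a single seed, writing per-stage TSVs, a checksum manifest, and a report.

## Worked example

```bash
python examples/04_survival_signature.py
```

prints (95-sample simulated cohort, signature coefficients planted):

```
multivariate Cox fit (planted beta in parentheses):
   ZNF720: beta = +0.592 (+0.419), HR = 1.81 [1.43, 2.28]
    REEP3: beta = +0.008 (+0.122), HR = 1.01 [0.84, 1.21]
    CNNM2: beta = +0.228 (+0.139), HR = 1.26 [1.02, 1.55]
   CGREF1: beta = +0.325 (+0.291), HR = 1.38 [1.11, 1.73]
  logPL = -194.5985, AIC = 397.1971

risk-score high vs low: log-rank p = 4.87e-05; 3-year cumulative/dynamic AUC = 0.806
```

Each fitted coefficient lands near its planted value (a 95-sample cohort
leaves real sampling noise — the acceptance suite shows ±0.05 recovery of
the mean at n=500 over 20 seeds); the high-risk half of the cohort relapses
significantly earlier, and the risk score discriminates 3-year relapse well
above chance. `examples/01–03` walk the screen arm (simulation, read
trimming + site calling, enrichment + overlap), `05` covers DGE/ORA/hubs,
and `06` runs the whole pipeline; each prints its numbers with a line on
what they mean. The same stages are available from a shell via the thin
`pbscreen` CLI (`pbscreen run --config cfg.json --out run/`, `pbscreen trim`,
`pbscreen callsites`, `pbscreen survival`, ...).

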