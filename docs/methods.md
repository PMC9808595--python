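# Methods

## The screen model

The generator emulates a piggyBac activation screen in cultured tumor
cells. A clone is a cell lineage carrying 1–3 transposon insertions, each
at a TTAA tetranucleotide start (piggyBac's invariant target motif) with a
random orientation; clonal cell counts follow log-normal(0, 1) scaled by
`abundance_scale` (default 20) and rounded to ≥1, reproducing the
clonal-expansion skew a pooled library develops. An insertion is
**activating** when its orientation matches the gene strand and the TTAA
start lies inside the gene span `[start, end)` — the promoter + splice-donor
cargo then reads into the gene. No upstream-promoter window is modeled
(window = 0 bp): intragenic activation is the clean, testable case, and a
window would only relabel a handful of near-boundary insertions. The TTAA
target-site duplication is likewise not written into the sequence; a site
is a point annotation at the TTAA start, because site *calling*, not
integration biochemistry, is what the pipeline must get right.

Selection is binomial thinning: each cell survives a dose with probability
`base_survival[dose]`, multiplied by `resistance_boost` (clipped at 1) if
its clone has an activating insertion in a designated resistance gene;
clones thinned to zero cells disappear. Defaults: doses 0/5/10 µg·mL⁻¹ with
base survival 1.0 / 0.01 / 0.01 and boost 10. Both selected doses share the
0.01 floor; the two arms are independent stochastic realizations of the
same stringency rather than a dose–response curve — modeling monotone
dose–response would change the floor the enrichment statistics are
computed against without exercising any additional code path.

### Why 150 genes, 300 kb, 5000 clones

These free parameters were fixed by a power computation, not by trial.
Two quantities control whether a resistance gene can be re-discovered:

* **Compositional dilution.** Let f be the fraction of clones carrying an
  activating insertion. After selection the library's average survival is
  base·(1 − f + boost·f), and a resistance gene's fold change is roughly
  (boost + 1)/2 divided by that mixture factor. With few genes (f ≈ 0.2)
  the mixture term reaches ~3 and log₂FC compresses toward the volcano
  threshold regardless of boost; at 150 genes in 300 kb, f ≈ 0.09, the
  mixture is ~1.8, and the expected log₂FC is ≈ 1.6 with floor
  log₂(1/1.8) ≈ −0.86 — so a depleted gene can never legitimately cross the
  −1 "down" threshold.
* **Clonal dropout.** A gene's enrichment rides on its sense-orientation
  clones. With the log-normal abundance skew, a gene represented by few
  clones can be dominated by one large antisense clone that dies under
  selection. 5000 clones give ≈ 20 sense clones per resistance gene, which
  averages the skew out; 300-clone screens (the test fixtures) are
  deliberately underpowered and exercise bookkeeping only.

Junction reads are 2×125 bp: read 1 is `[ITR tag][genomic flank]`, with the
adapter read through (then padding) when the sheared fragment (60–300 bp) is
shorter than the read; read pairs per insertion and side are
Poisson(depth × abundance). The flank always begins at the TTAA start, so an
error-free read round-trips to the exact insertion coordinate. Flanks
truncated below 20 bp by a genome end are not emitted — they could only ever
be rejected downstream. No sequencing-error, PCR-bias or chimera model is
included: the suite verifies *exact* recovery under clean input, and any
error model would only dilute that statement.

## Read processing choices

Tag detection is anchored at the read start, Hamming distance ≤ 2 (real
splinkerette chemistry puts the ITR primer at the 5′ end; indels buy
nothing). Config validation requires the two tags to differ at
≥ 2·max_mismatches + 1 positions — the bound that actually makes a
double-match impossible. Adapter removal takes the earliest exact match,
then the earliest 1-mismatch match (found via pigeonhole on the two adapter
halves), then an exact adapter *prefix* flush against the read end down to
a single base — the standard read-through treatment; without it, a fragment
whose adapter was clipped by the read boundary keeps 1–4 adapter bases and
fails exact-match alignment. None of these steps can touch the ITR-adjacent
end of the flank, so the junction coordinate is never affected.

The internal aligner is an exact-substring unique-hit search over a seeded
20-mer index. This is intentional: on a ≤ 1 Mb synthetic reference it is
exact, fast and dependency-free, and real-genome alignments enter through
`import_sam` (primary mapped records, 1-based POS converted to 0-based,
FLAG 0x10 → minus strand). Junction coordinate: `pos0` for a plus-strand
alignment, `pos0 + matched_len − 1` for minus; the PB3 side flips the
inferred transposon orientation. Snapping tolerance is ±2 bp around TTAA
starts to absorb end artifacts. Gene assignment counts a site for every
gene span containing it and ignores orientation (orientation is kept on the
record; an activating-only filter is a caller-side choice). PCR
deduplication is off by default — reads, not fragments, are the support
unit here.

## Enrichment statistics

Each gene is tested with a two-sided Fisher exact test on
`[count_screen, size_screen − count_screen; count_ctrl, size_ctrl − count_ctrl]`,
where sizes are total mapped junction reads. Fisher was chosen because the
comparison is one library against one library — there are no replicates, so
a dispersion-based (negative-binomial) test has nothing to estimate, and
the exact test is parameter-free and reproducible. log₂FC is computed on
CPM with a 0.5 pseudocount so zero-count genes stay finite. The BH family
is the union of genes with a read in either library, per comparison arm.
Thresholds default to log₂FC > 1 and −log₁₀(adj p) > 2 ("up"; mirrored for
"down") with strict inequalities.

## Survival machinery

* **KM/median:** product-limit estimator; the median is the earliest event
  time with Ŝ ≤ 0.5, `None` when never reached. Median-split ties go to
  "high" everywhere (matching the high/low naming convention); the choice
  is a flagged default, not a hidden rule.
* **Log-rank:** (Σ(O−E))²/ΣV with hypergeometric variance per event time;
  no events → statistic 0, p 1.
* **Cox:** Newton–Raphson with step-halving on the Efron-corrected partial
  likelihood (year-resolution DFS times guarantee ties; Breslow users will
  see small differences at tied times). Risk-set sums are suffix cumulative
  sums over time-sorted samples, so one evaluation is O(n·p²). Convergence:
  max |score| < 1e-7 or 50 iterations, with a plateau break at machine
  precision; SEs from the inverse observed information. A coefficient
  exceeding |β| > 15 at "convergence" is reported as a monotone-likelihood
  (perfect separation) error naming the covariate, because the score tends
  to zero as β → ∞ and Newton would otherwise return an absurd finite
  estimate with a huge SE. An optional L2 penalty (`ridge`) provides the
  penalized mode; reported logPL/AIC stay unpenalized. AIC is the exact
  identity −2·logPL + 2k.
* **Time-dependent ROC:** cumulative-case / dynamic-control AUC at a
  horizon (default 3 years — a clinically conventional DFS landmark; the
  estimator and horizon are configurable because neither is canonical),
  with case weights 1/Ĝ(Tᵢ⁻) from the KM estimate of the censoring
  distribution; control-side weights cancel in the ratio. Uncensored data
  reduce it to the plain concordance fraction; it agrees with
  scikit-survival's Uno-type estimator to machine precision in the tests.
* **Five-group stratification:** label by the count of signature genes at
  or above their cohort median (4 → `Four_genes_high` … 0 → `Low_group`).

## Cohort generator

Expression is Normal(0, 1.5²) per gene on the log2 scale — 1.5 is a
realistic cross-sample spread for prognostically variable genes and makes
the Cox information per sample large enough that coefficient recovery at
n=500 has SE ≈ 0.04 per coefficient. Event times are exponential with rate
h₀·exp(βᵀx), h₀ = 0.12 y⁻¹ (median ≈ 6 y at the null); censoring is
independent Uniform(0, b) with b calibrated by bisection so the expected
censored fraction matches `censor_frac` (default 0.4, in the range of
pediatric DFS cohorts); `censor_frac = 1` censors everyone at their
would-be event time. What this generator does **not** emulate: gene–gene
correlation, batch structure, non-proportional hazards, or the unknown
normalization of any real cohort — so passing tests certify the machinery
and its calibration, not transferability of any specific coefficient to
real data.

## DGE, ORA, hubs

The moderated two-group test is implemented directly (OLS per gene,
method-of-moments fit of the variance prior on log s², squeezing
s̃² = (d₀s₀² + d·s²)/(d₀ + d), t on d₀ + d df capped at the pooled residual
df; when the observed spread of log s² is within chi-square noise, d₀ = ∞
and the shared variance is the arithmetic mean). Implementing it in-package
keeps the d₀ → ∞ and d₀ → 0 limits available as exact oracles; the test
suite additionally checks full agreement with the R reference
implementation on both variance regimes. No voom-style mean–variance
weighting: the inputs here are already log-scale expression values at toy
scale.

ORA is the hypergeometric upper tail P(X ≥ k) over a universe defined as
all genes in the supplied expression matrix (not the genome): terms are
intersected with the universe first and empty intersections skipped.
Annotations and interaction networks are user-supplied files (GMT, edge
list) because database-version-dependent term content is explicitly not
reproducible; the bundled demo sets and networks are synthetic stand-ins
built around canonical bone-formation genes. MCC enumerates maximal cliques
(Bron–Kerbosch via networkx) and sums (|C|−1)! per node, with isolated
nodes scoring 0 and gene-id tie-breaks; both degree and MCC are offered
since hub definitions differ between studies.

## Pipeline and determinism

One JSON config drives every stage; unknown keys are rejected with their
dotted path. All randomness flows from a single seed through
`SeedSequence`-derived sub-seeds, so a rerun is bit-identical (the manifest
records SHA-256 checksums of every artifact and the test suite re-verifies
them). Stage failures halt with the stage named, keeping partial outputs.

## Problem sizes used by the test and acceptance suites

Round-trip and bookkeeping tests run 8–40-gene genomes with 25–300 clones;
the screen-power check runs the default 150-gene / 5000-clone scale once;
Cox reference agreement uses 50 random cohorts (n = 60–150, p = 1–4);
coefficient recovery uses 20 cohorts at n = 500; the log-rank permutation
oracle uses 10⁴ permutations at n = 20; Fisher/ORA/MCC oracles sweep all
small configurations exhaustively (margins ≤ 12, universes ≤ 25, graphs
≤ 11 nodes) plus randomized larger cases. These sizes were chosen so each
suite finishes in seconds while leaving every statistical claim at ≥ 3–4σ
margins.

## Known limitations

* The exact-match aligner does not model mismatches, indels or multi-mapping
  rescue; real-genome work must route through `import_sam`.
* Fisher on single libraries treats reads as independent draws; clonal
  correlation within a library makes the p-values optimistic. The
  enrichment *ranking* and the planted-gene recovery statements are what
  the tests certify.
* Passenger ("hitchhiker") genes sharing a clone with an activating
  insertion can be genuinely enriched; the screen cannot distinguish them
  from drivers, only the overlap across doses and external cohorts can.
* The moderated test assumes equal group variances per gene (the classic
  two-group design); no array weights, trends or robust variants.
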