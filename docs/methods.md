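# Methods

This note documents the models, defaults and design choices behind the
pipeline, and what the synthetic generators do and do not emulate.

## Cohort model (synthetic data)

Counts for gene *g* in sample *j* are negative binomial with mean
μ_gj = p_g(t_j)·s_j and variance μ + φμ², where p_g(t) is the gene's
relative-abundance proportion in tissue class t, s_j the library size, and φ
a dispersion shared across genes (per-gene dispersion variation is out of
scope for the generator because the DE stage estimates exactly this
mean–dispersion form). Baseline log2 relative expression is N(5, 2²) per
gene. Two planted programs structure the tissues: liver-program genes sit
`planted_logfc` log2 units higher in adjacent liver (AL) than in colon
tumors (CC), colon-program genes the reverse. Metastasis classes (LM1–LM3)
have log-means `(1−w)·CC + w·AL` with mixture weight w — the mixture is in
log space because log2 fold change is the effect scale the DE stage
thresholds on. With w = 0 the LM groups are distributionally identical to
CC, which is what the null-calibration tests exploit.

Defaults mirror the cohort structure the pipeline targets: 50 samples
(9 CC, 25 LM1, 7 LM2, 3 LM3, 6 AL) from 9 patients with 8+ matched CC/LM1
pairs, 2000 genes, 40-gene programs, w = 0.8, planted logFC = 6 (so the
realized LM-vs-CC effect is w·6 = 4.8, just above the |logFC| > 4 call
threshold — recovery is a genuine test, not a giveaway), φ = 0.1 and library
sizes log-uniform on [10⁶, 2×10⁷]. φ and the library-size range are
conventional bulk RNA-seq values, not measured ones; library sizes vary per
sample specifically so the normalization step has observable work to do.

All randomness derives from one `numpy.random.SeedSequence`; substreams for
means, library sizes and counts are spawned deterministically, so a config
plus seed reproduces outputs byte for byte.

What the generator does **not** emulate: read-level structure, isoforms,
batch effects, per-gene dispersion trends, correlated genes within programs,
or tumor purity. Passing recovery tests therefore demonstrates the
statistical machinery is correct under its stated model, not that the
pipeline is robust to every artifact of real cohorts.

## Differential expression

* **Normalization** — trimmed mean of M-values (TMM): reference sample by
  the 75th count-fraction quantile closest to the mean; 30 % two-sided trim
  on M, 5 % on A; inverse-asymptotic-variance weighting; factors rescaled to
  geometric mean 1. Verified against edgeR's `calcNormFactors` on a frozen
  toy matrix to 1e-6.
* **Dispersion** — per-gene method of moments on normalized counts pooled
  over groups with ≥ 2 samples, clipped at 0, then shrunk toward the
  across-gene median with weight 0.3. The shrinkage weight trades per-gene
  noise (n is small) against bias; 0.3 keeps planted-dispersion recovery
  within [0.1, 0.3] at φ = 0.2 while sending the Poisson case to ~0.
* **Test** — Wald statistic on log2 normalized group means with
  delta-method standard errors, Var(mean) = (m·κ + φm²)/n with κ the mean
  library rescaling factor, and a pseudo-count of 0.5 per group mean so zero
  counts give finite logFC (0.5 is far below the resolution of the
  |logFC| > 4 threshold). The statistic is referred to a Student t with
  n_A + n_B − 2 df by default: with 8-vs-8 groups the estimated-dispersion
  Wald z is anti-conservative in the extreme tail, and the t reference is
  what keeps the global-null raw-p rate inside 0.05 ± 0.02 and BH at 0.01
  at zero discoveries. An asymptotic-normal variant and a "consensus" mode
  (per-gene max of both p-values, i.e. significant only under both variants)
  are available via `method=`.
* **Calls** — strict inequalities throughout (|logFC| strictly greater than
  the cutoff, p strictly below). Presets: `paper` (BH-adjusted p < 0.01),
  `public1` (raw p < 1e-3), `public2` (raw p < 0.01), all with |logFC| > 4.
* **Embedding** — top-2000-variable-gene log2-CPM (pseudo-count 1,
  TMM-effective library sizes), gene-centered, projected on the leading
  principal axes; each axis's sign is fixed by making its largest-magnitude
  gene loading positive.

The low-expression filter keeps genes with count > 10 in at least
⌈0.10·n_samples⌉ samples, computed on whatever matrix is passed in (not on
any per-contrast subset).

## Signature derivation

Gene identity is the upper-cased symbol. The core signature is the exact
intersection of the up-sets of all provided contrasts (matched, unmatched,
externals), down-sets symmetrically; provenance records every input so that
alternative intersection semantics are a configuration change, not a code
change. Tissue classification reads the enrichment column of a
Protein-Atlas-style table; "liver-enriched" means liver appears among the
enriched tissues — the numeric levels are informational and no expression
cutoff is applied. The pipeline's default derived signature is up-only
(`call_de` still reports down genes). Over-representation is a one-sided
hypergeometric upper tail per pathway with BH across pathways.

The packaged 22-gene colon-to-liver signature table and the synthetic
reference-universe file (21 of the 22 genes; SLC13A5 deliberately absent,
emulating a signature gene unannotated in a perturbation database) are the
worked-example fixtures for query validation and tissue classification.

## Pathway clustering

Feature space per pathway: log2-CPM of the pathway's expressed genes,
standardized per gene — without standardization a single high-variance gene
dominates the Euclidean metric. K-means uses k-means++ initialization,
squared Euclidean distance, a 100-iteration cap, and per-replica seeds
spawned from the master seed.

The gap statistic follows the original uniform-reference variant: B = 50
reference draws uniform over each feature's observed range,
gap(k) = mean_B log W_ref − log W, s_k = sd_B·√(1+1/B), choosing the
smallest k with gap(k) ≥ gap(k+1) − s_{k+1} (k_max if none). Uniform
per-feature ranges make the choice invariant to feature-wise affine
rescaling, which is asserted in tests. Degenerate all-identical data returns
k = 1.

Stability at fixed k runs 500 independent replicas; the reference partition
is the replica with the lowest within-cluster dispersion (the best local
optimum seen), and "conserved composition" is read strictly as partition
identity up to label permutation, implemented by canonical relabeling in
order of first appearance. A relaxed mode (adjusted Rand ≥ 0.99) exists
behind a flag for noisier data. A pathway is stable at a conservation
fraction ≥ 0.95. Consensus blocks: per stable pathway each cluster is named
by the majority tissue class of its members (ties to the lexicographically
smallest class, flagged); samples then vote across stable pathways and the
report keeps the full tally plus a "votes/total" string.

Clustering operates on samples, not genes — the consensus question ("which
block does this metastasis sample join?") is a sample-level question.

## Connectivity screen

The score is the classic weighted-KS enrichment with uniform hit weights:
rank profile genes descending (ties broken by gene id and flagged when they
involve query genes), walk the ranking adding 1/n_hit at query genes and
−1/(N−n_hit) elsewhere, take the signed maximum deviation; with both up and
down sets the combined score is (ES_up − ES_down)/2, up-only queries use
ES_up directly, and the result is scaled ×100. Query genes at the very top
give exactly +100, at the very bottom −100. Queries are validated to 10–150
genes after dropping genes absent from the reference.

The per-context scores are aggregated into a "global" score as the plain
mean across contexts (the reference's own summary statistic is not
reproducible from a local matrix, so the package's global is defined — and
labeled — as a mean). Hits must score strictly below the cutoff (default
−95) in **every** required context. Class summaries count hit mechanisms
inside a score band (default [−100, −50], inclusive).

## Organoid pharmacology

RS uses the three-factor product (count × diameter × viability) at both
timepoints; a two-factor variant without viability is available via
`use_viability=False`. Orientation is baseline over 72 h, so growth
inhibition gives RS > 1. Viability entered above 1 is treated as a percent
and normalized; use one convention per comparison (the ratio is invariant
when both timepoints use the same convention). A zero 72-h product (no
surviving organoids) returns an infinite RS with an explicit flag rather
than raising. Sensitivity classification is control-relative with a
configurable margin (default 0.2): treated RS must exceed control RS by more
than 20 % — the margin is a package convention, reported in output, since no
universal cutoff exists for this assay.

Bliss synergy: excess = observed inhibition − (y_a + y_b − y_a·y_b) over
combination cells only (margins excluded, matching the usual
synergy-calculator convention; inclusion is a flag), score = 100 × mean
excess, classified < −10 antagonistic / −10..10 additive (boundaries
inclusive) / > 10 synergistic. The organoid simulator caps single-agent
inhibition at 0.45 so that planted excess up to 0.2 plus noise stays inside
[0, 1] and is not clipped into bias; margins are generated noise-free so the
planted excess is identifiable from combination cells.

## Pipeline and problem sizes

`run_pipeline` chains the stages on synthetic data, standing in the two
"external" cohorts with additional simulated cohorts tested at the public
presets. The default test and demonstration sizes (2000 genes, 8-vs-8
groups, 10–50 seed replicates, 500 clustering replicas on ≤ 30-sample
pathway matrices) were chosen so the whole suite runs in well under a minute
per stage on one core while leaving every recovery test with a real failure
mode (effects near thresholds, stability on genuinely ambiguous data).

## Known limitations

* The NB test is a two-group Wald test; GLM designs, covariates and exact
  replication of any specific DE package's internals are non-goals.
* The connectivity score emulates the family of rank-based signature
  matching scores; it is not numerically comparable to any live service's
  proprietary summary statistic.
* Stability's strict partition-identity reading is conservative on large
  sample sets; use the Rand-relaxed mode when near-identical partitions
  should count as conserved.
* No dose–response curve fitting (4PL) — margins enter the Bliss model as
  measured.
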