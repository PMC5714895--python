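# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, the synthetic generating process used
for testing, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design and data model

The pipeline assumes a replicated factorial design: G genotypes observed
at S totally ordered developmental stages with R replicates each
(default emulated design: 4 genotypes forming two mutant / non-mutant
pairs × 5 stages × 3 replicates = 60 libraries). The universal data
currency is a genes × samples matrix tagged with its scale (raw counts,
normalized counts, FPKM, or log2).

**Normalization.** Size factors use the median-of-ratios estimator: the
per-gene reference is the geometric mean across samples over genes with
all-positive counts, and each sample's factor is the median (in linear
space) of its count/reference ratios. FPKM is
`count · 1e9 / (gene_length_bp · raw_column_sum)`; the raw per-sample
column sum is the per-million denominator, so FPKM is invariant to
sequencing depth but — deliberately — not recomputed from normalized
counts: normalized counts feed the DE test, FPKM feeds clustering.
Replicates are averaged arithmetically into one column per
(genotype, stage) condition.

## Differential expression

Two contrast families are enumerated from the design: *stage-wise*
(mutant vs. its partnered non-mutant at the same stage; 2 pairs × 5
stages = 10 contrasts) and *between-stage* (adjacent stages within one
genotype; 4 genotypes × 4 steps = 16 contrasts).

The internal test is a pooled two-sample t-test on
log2(normalized count + 1), with Benjamini–Hochberg adjustment applied
per contrast and the DE gate `padj < 0.01 ∧ |log2FC| > 1`. Design notes:

* **Pooled rather than Welch.** With triplicate groups the
  Welch–Satterthwaite degrees of freedom collapse toward 2, which places
  a floor of roughly 3×10⁻⁴ on attainable p-values even for t ≈ 17 —
  large fold changes then become undetectable at a BH-0.01 gate purely
  because of the df estimate. With equal group sizes the pooled test
  keeps df = n_a + n_b − 2 = 4 and calibrates correctly; the null
  false-positive fraction is verified by simulation.
* **Pseudocount 1 on the normalized-count scale** bounds log2FC for
  zero-count genes; genes with zero counts in both groups get p = 1 and
  log2FC = 0.
* **Per-contrast BH** matches the per-comparison usage of count-model DE
  tools; the union over contrasts then defines the clustering input and
  the DE-TF regulator set.
* This is *not* a negative-binomial GLM and has less power than
  dispersion-sharing count models at n = 3. Users with externally
  computed DE tables can load them via `import_de_tables` (columns
  `contrast_label, gene_id, log2fc, pvalue[, padj]`); the DE gate is
  re-applied and a missing padj column is recomputed by BH.

## Co-expression modules

Clustering input: replicate-averaged log2(FPKM + 1) profiles of the
DE-gene union, z-scored per gene (constant genes map to all-zero
profiles). The z-scoring makes modules capture profile *shape*; raw FPKM
would cluster by magnitude. Both the transform and the option to skip it
are exposed in `ClusteringConfig.input_transform`.

k-means uses k-means++ seeding with best-of-`n_restarts` selection
(default 25 restarts, 300 Lloyd iterations). K is scanned over a grid
(default 20–100 in steps of 5, matching the intended full-data scale;
tests use grids proportionate to their planted module counts) and chosen
by minimum BIC, ties to the smaller K.

**BIC formula.** We use the spherical-Gaussian *mixture* BIC in the
X-means formulation:

    ln L = Σ_i n_i ln(n_i/n) − (n d / 2) ln(2π σ̂²) − d (n − K) / 2
    σ̂²  = WSS / (d (n − K))
    BIC  = −2 ln L + p ln n,   p = (K − 1) + K d + 1

with n genes, d conditions, cluster sizes n_i, total within-cluster sum
of squares WSS. The cluster-proportion term Σ n_i ln(n_i/n) is essential
at this problem scale: a likelihood-only spherical BIC (penalty K·d·ln n
alone) leaves the per-split penalty within noise of the likelihood gain
obtainable by splitting a genuine module of ~50 genes over ~20
conditions, and model selection then drifts upward. The mixture form adds
≈ 2·n_c·ln 2 per even split of an n_c-gene cluster and selects the
planted K stably (verified over 50 seeded simulations in the acceptance
suite). A fixed K can be forced via `fixed_k`.

Module mean profiles are arithmetic means of member-gene rows of the
transformed matrix, and are re-validated against the stored assignment.

## Edge scoring (module networks)

Candidate edges are all (regulator, module) pairs, where regulators are
the DE transcription factors and targets are module mean profiles,
stacked into one matrix over the (genotype, stage) conditions. At
full study scale (1245 DE TFs, 60 modules) this is 1305 rows × 20 columns and
74,700 candidate pairs. Constant regulator rows are dropped with a
warning. TF→TF edges are not scored (configurable only by restacking);
a TF may be scored against the module it belongs to — that relation is
additionally represented by an undirected membership edge.

The five engines, and their defaults (all hyperparameter values below
are this package's implementation defaults, fixed and documented here):

* **Mutual information** (shared by ARACNE and CLR): plug-in estimator on
  a B×B discretization, default B = ⌈√n⌉ equal-width bins; an
  equal-frequency (rank) option makes MI invariant to monotone per-row
  transforms. Under independence the plug-in estimator has positive bias
  ≈ (B−1)²/(2n) nats — substantial at small n — but both consumers are
  insensitive to this shared offset (ARACNE compares MI values,
  CLR standardizes against per-row backgrounds).
* **ARACNE**: all-pairs MI, then data-processing-inequality pruning: for
  every triplet the weakest edge is removed when
  `MI_ij < min(MI_ik, MI_jk) · (1 − ε)`, all comparisons against the
  original matrix (pruning order irrelevant). Default ε = 0.1, the
  tolerance recommended for the original ARACNE tool; with only ~20
  conditions, exact comparisons (ε = 0) prune genuine edges on estimator
  noise. Pruned pairs score 0.
* **CLR**: z_i(j) = max(0, (MI_ij − mean_i)/sd_i) over row i's off-diagonal
  MI background; score = √(z_i(j)² + z_j(i)²); zero-variance backgrounds
  contribute 0.
* **Random-forest importance** (GENIE3-style): per module, a
  `RandomForestRegressor` (default 1000 trees, √p features per split) of
  the module profile on all regulator profiles; scores are
  variance-reduction importances normalized to sum 1 per target.
* **Stability selection with LARS** (TIGRESS-style): per module, repeat
  (default 200×): subsample half the conditions, multiply each regulator
  column by an independent Uniform(0.2, 1) weight, run least-angle
  regression for 5 steps; the score is each regulator's selection
  frequency. The deliberate reweighting means even a perfect driver is
  selected in only a fraction of resamples — scores are comparable within
  a run, not probabilities of relevance.
* **Shrinkage partial correlation**: correlation matrix shrunk toward the
  identity with the analytic Schäfer–Strimmer intensity
  λ* = Σ Var̂(r_ij) / Σ r_ij² (clipped to [0, 1]); partial correlations
  from the inverse, scores |pcor|. λ can be fixed; λ = 0 requires a
  well-conditioned matrix.

Scores are min-max rank-normalized per method so retention cutoffs are
comparable across methods.

## Consensus, classification, and network assembly

Each method retains its top-scoring pairs (default: top 1% of the
candidate universe; ties broken by score, then regulator and module ID,
so retention is deterministic). An edge's support is the number of
retaining methods; the stringent network keeps 5-of-5 edges, the extended
one ≥ 4-of-5. Raising `min_support` can only shrink the network.

Every TF in the network gains one undirected membership edge to the
module it was clustered into (none if it was not clustered). Directed
edges are then colored by the regulating TF's DE pattern, first match in
this precedence order:

* **black** — between-stage DE in every mutant *and* every non-mutant
  genotype (stage-driven regulation unaffected by the mutations);
* **green** — between-stage DE in all non-mutants but no mutant
  (regulation lost in mutants);
* **blue** — between-stage DE in no non-mutant but ≥ 1 mutant
  (regulation gained in mutants);
* **red** — stage-wise DE in the focal mutant pair at ≥ 1 stage
  (stage-specific mutation effect); the focal pair defaults to the
  design's first mutant pair and is configurable;
* **grey** — none of the above.

The first three rules are mutually exclusive; the precedence order
resolves the black-and-red overlap deterministically. Classification is
total: every edge receives exactly one color.

`network_summary` reports edge/TF/module counts, per-category tallies and
the exact retained fraction of the candidate universe. Networks export
losslessly as TSV edge lists and as GraphML (a multigraph, since a TF may
carry both a regulatory and a membership edge to the same module).

## Enrichment and reference-network validation

Per-module GO over-representation uses the one-sided hypergeometric tail
P(X ≥ k) (equivalent to one-sided Fisher), testing every (module, term)
pair with at least one annotated member, with BH applied jointly across
all tests (a single FDR gate over the full results table; the per-module
alternative is a one-line change in user code). The default background
universe is all annotated genes; `de_genes` restricts it to the clustered
genes for conditional enrichment. Annotations are used as provided — no
GO-graph ancestor propagation.

Validation counts predicted edges recovered in an external (regulator,
target) edge list through a many-to-many ortholog map: a predicted
(TF, module) edge yields a TF→gene overlap for each module member whose
ortholog pair hits a reference edge, and one TF→module overlap if any
member matches. Because many-to-many maps make "one overlap" ambiguous,
matched pairs are reported both in source-gene and in reference-gene
space, and a strict first-ortholog mode is available. Multiple reference
edge lists merge by set union with per-source bookkeeping.

## Synthetic data: what it emulates, and what it does not

`simulate_dataset` generates the full study design with planted ground
truth (module memberships, TF→module edges, per-contrast true-DE sets,
one GO term per module). The generating model, on the log2 latent scale:

* Module stage-trends are free per-stage profiles (i.i.d. normal values,
  centered, scaled to peak amplitude `effect_sd` = 2.8 log2). Free
  profiles rather than low-order polynomials: over 5 stages, random
  cubic coefficients collapse onto one or two effective shape dimensions
  and cannot yield 10 mutually distinguishable trends. Trends are
  redrawn until pairwise |Pearson r| ≤ 0.75 and each trend steps ≥ 2.5
  log2 between some adjacent stages.
* A fraction (default 0.4) of modules is perturbed: a constant ±3 log2
  shift in one designated mutant genotype at every stage. Stage-wise
  true-DE sets are therefore *exactly* the perturbed-module member
  genes — an invariant the test suite asserts.
* Member genes: log2 mean = baseline N(8, 0.8) + amplitude
  U(0.9, 1.1) × module latent profile.
* Regulator TFs track their module's base trend (not the mutant shift)
  with unit coupling plus small per-stage jitter (σ = 0.25) shared across
  genotypes — so regulators are between-stage DE but never spuriously
  stage-wise DE. Bystander TFs follow independent random trends,
  decorrelated (|r| ≤ 0.75) from every module trend: without this
  identifiability condition, chance 5-point-trend correlations of ~0.95
  make bystanders statistically indistinguishable from planted
  regulators at 20 conditions, and no method could recover the planted
  edge set even in principle.
* Counts are negative-binomial via the gamma–Poisson mixture
  (var = μ + 0.1·μ² by default), with per-library factors U(0.7, 1.3).

The amplitude, baseline, shift and step defaults are set so that the
planted signal is detectable by the pipeline's own DE test: a pooled t at
n = 3 under dispersion 0.1 (log2-scale σ ≈ 0.46) needs roughly a 2.3+
log2 change to clear a BH-0.01 gate.

Deliberately **not** emulated: batch effects, library-preparation biases,
gene-length–expression coupling, overlapping module membership,
nonlinear or time-lagged regulation, TF→TF regulation, and count
outliers. Passing tests on this generator therefore demonstrate that the
pipeline recovers planted linear-coupling structure under NB noise at the
study's design size — not that it would attain the same operating
characteristics on real tissue RNA-seq.

## Evaluation protocol (tests and acceptance script)

Planted-truth evaluation maps each predicted module to the planted module
with the largest member overlap, then scores edges in that mapped space.
Recall is counted over *all* planted edges (a regulator missed by the DE
filter counts as a miss); the candidate-universe-restricted recall is
reported alongside. Precision/recall floors are asserted for the
4-of-5-support network with per-method retention set to 4× the planted
edge count (lists deep enough that a 4-of-5 intersection can cover the
planted network); the community-beats-best-single comparison uses the
5-of-5 network against each single method's precision at the same
retention cutoff. Engine settings in evaluation are 200 trees and 100
resamples (defaults remain 1000/200); simulation counts are 50 runs for
K-recovery, 10 for network metrics, 5 for DE calibration — sizes chosen
to keep the whole suite in the low minutes on one CPU.

## Known limitations

* The DE test trades power for simplicity; real studies at n = 3 should
  import count-model DE tables through `import_de_tables`.
* With ~20 conditions, MI estimates are coarse (5 bins) and ARACNE's DPI
  pruning is the noisiest stage; it is consistently the weakest-ranking
  engine on planted data and the 4-of-5 consensus exists partly to absorb
  that.
* The BIC argmin depends on the chosen variant; the formula above is a
  documented package choice, and a fixed K can always be forced.
* Per-method retention before voting is the least constrained choice in
  the consensus stage; it is exposed prominently (`per_method_top`) and
  logged in every run manifest.
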