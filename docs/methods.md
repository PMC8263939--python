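# Methods

This note documents the models, conventions and design choices behind
`degnet`, in the order the pipeline runs them.

## Study design and data model

A *study* is a set of datasets, each assigned a role (`test` or
`validation`) and containing samples labeled `normal`, `primary` or
`metastatic`. Three two-group comparison classes are defined: MvsN
(metastatic − normal), PvsN (primary − normal) and MvsP (metastatic −
primary); logFC is always the first-listed group mean minus the second
on the log2 scale. Test datasets determine which genes replicate;
validation datasets only confirm or veto them. A dataset may lack a
group (e.g. a tumor/normal-only cohort), in which case only the
available classes are analyzed.

## Preprocessing cascade (microarray-style matrices)

Fixed order: absent-call filter → quantile normalization → median-SD
variance filter → highest-IQR probe collapse. Each stage emits a
`FilterReport` for auditability.

- **Absent filter.** A feature counts absent in a group when its number
  of `A` calls there exceeds `max_absent` (default 2). Default removal
  requires this in *every* group (`all_groups`); the stricter
  `any_group` reading is available because the underlying rule is
  genuinely ambiguous. Detection calls are optional; without them the
  stage is skipped with a warning.
- **Quantile normalization.** Column k-th order statistics are replaced
  by the across-column mean of k-th order statistics. Ties within a
  column receive the mean of their tied targets (standard
  stabilization). The map is idempotent up to float noise on
  tie-free data.
- **Variance filter.** Features with across-sample SD strictly greater
  than the median SD survive. "Strictly greater" is pinned so the
  median-tied mass is removed deterministically; an all-tied (constant)
  matrix removes everything, with a warning.
- **Probe collapse.** For each gene the mapped probe with the largest
  IQR is kept; probes mapping to several genes compete for each of
  them; IQR ties break toward the lexicographically smallest probe ID.
  SD uses the unbiased (ddof = 1) estimator and quartiles the
  linear-interpolation convention throughout — these had to be pinned
  for bit-reproducibility.

RNA-seq-style matrices take `prepare_precomputed` instead: all-zero
rows are dropped and linear-scale input becomes log2(x + 1); the +1
offset keeps zeros at zero and is configurable. Count-model
normalization (size factors, dispersion shrinkage) is deliberately out
of scope — the pipeline accepts pre-normalized matrices.

## Outlier detection (Number-SD)

Sample agreement is 1 − Pearson r over genes. For each sample the mean
off-diagonal statistic is standardized against its group (unbiased SD);
scores below −2 (strict) are outliers. Two sign conventions exist
because the standardization can be done on mean correlations or mean
distances: the default `correlation` convention makes aberrant samples
score negative, which is the only reading consistent with a "< −2"
flagging rule; `distance` flips the sign (and the detector then flags
scores above +2). Removal is per group and single-pass by default
(`max_iterations=1`); iterating until no flags remain is available.
Groups smaller than 3 are never tested. When all samples are mutually
equidistant the SD vanishes and all scores are defined as 0 (detected
with a 1e-12 tolerance, since correlations of identical columns carry
float jitter). PCA embeddings and average-linkage dendrograms on 1 − r
are provided for visual QC only; no automated decision uses them.

## Moderated differential expression

Gene-wise pooled two-sample variances s²_g (d = n₁ + n₂ − 2 df) are
shrunk toward a prior fitted by moment-matching the scaled-F marginal
on the log scale: with e_g = log s²_g − ψ(d/2) + log(d/2),

    E[e] = log s₀² − ψ(d₀/2) + log(d₀/2),   Var[e] = ψ′(d/2) + ψ′(d₀/2),

so ψ′(d₀/2) = Var̂[e] − ψ′(d/2), inverted by monotone bisection of the
trigamma function (ψ′ is strictly decreasing; 200 bisection steps in
geometric mean, deterministic). A non-positive excess variance yields
d₀ = ∞ (full shrinkage, normal reference); `prior_df=0` disables
moderation and reproduces the ordinary pooled t exactly. Zero-variance
genes are excluded from the fit; a gene with zero moderated variance
gets p = 0 (nonzero logFC) or 1, with a warning. The implementation
agrees with the reference R implementation of this estimator to ~1e-14
on shared fixtures (cross-checked in the test suite via Rscript).

BH adjustment is the standard step-up (delegated to statsmodels and
cross-checked against a naive O(m²) oracle). DEG calls are strict:
|logFC| > 0.5 *and* adjusted p < 0.05. The plain moderated variant is
used throughout (no trend or robust fitting).

## Meta-integration

- **Class intersection:** a gene survives only if called in *every*
  test analysis of the class *with the same direction*; discordant
  directions exclude it.
- **Final-DEG screen:** the union of the class intersections is kept
  unless a validation analysis of a matching class measures the gene at
  |logFC| ≥ 0.2 with the *opposite* direction. Cells below 0.2 and
  unmeasured genes never penalize — this mirrors how blank cells in a
  direction table leave an otherwise concordant row intact. The 0.2
  figure doubles as the direction-table reporting cutoff and is
  configurable; an `allow_one_discordant` mode tolerates a single
  opposing cell.
- **Core genes:** the validated MvsP intersection by default; a
  user-supplied list overrides it verbatim (the definition of the core
  set is a scientific choice the caller may want to pin). An empty core
  set is an error since the proximity score is undefined.
- **Concordance classes:** per gene and class, non-blank cells are
  `uniform` (no disagreement), `one_discordant` (exactly one cell
  against a strict majority of ≥ 2) or `heterogeneous` (anything else,
  including even splits).

No effect sizes are pooled and no heterogeneity statistics are
computed: integration is by membership and sign only.

## Core-network extraction

Edge weights are interaction confidence scores in (0,1] (STRING-style
combined scores divided by 1000 on load; self-loops dropped, duplicate
pairs collapsed keeping the maximum). The graph induced by the final
DEGs is reduced to its giant component (size ties break toward the
component with the lexicographically smallest node). The unsigned TOM
uses the standard form with the +1/−a_ij denominator; TOM of an
isolated pair equals its edge weight, and TOM of a unit-weight clique
is 1 off-diagonal.

Shortest paths run over D = 1 − TOM. Because D is a *complete* matrix
(every pair has finite distance ≤ 1), two defensible readings exist:
`complete` (default) treats every off-diagonal entry as a traversable
step, so SP ≤ 1 everywhere; `edges_only` restricts traversal to the
original interaction edges. Both are implemented; neither is asserted
to be "the" published behavior.

D_j sums include the i = j term (contributing 0) with the global C/NC
divisors — the formula as printed, not a leave-one-out variant.
Retention is strictly positive D_j (a node scoring exactly 0 is no
closer to the cores than the average node and is dropped); core nodes
are always retained. Descriptives use unweighted hop distances for
diameter and mean distance (a path of 9 nodes is diameter 8), density
on the full graph, transitivity on the giant component, and weighted
(1 − w) distances only for betweenness.

## Synthetic-data generator

The generator emulates the structure of the multi-cohort design so that
every stage has a recoverable planted signal. Defaults are the study
conditions used by the tests: 2000 genes, 3 test + 2 validation
datasets, 15 samples per group, within-group SD 0.5 (log2), effect
size 1.0, 5% planted DEGs per class, one planted outlier per dataset at
decorrelation strength 0.9, 10% absent calls, probe multiplicity
{1: 0.6, 2: 0.3, 3: 0.1} with a 2% chance of a probe mapping to a
second gene.

- **Baselines** are skewed on the log2 scale (3 + Gamma(4, 1)),
  mimicking microarray intensity distributions so quantile
  normalization has realistic work to do.
- **Planted DEGs** form three disjoint blocks, one designated per
  class, each of size round(de_fraction · n_genes), with group-mean
  offsets of exactly ±effect_size in the designated class, consistent
  across datasets. Because M−N = (M−P) + (P−N), designated genes can
  carry incidental effects in other classes; the ground-truth offset
  table records the full truth. A configurable fraction of the MvsN
  block follows a monotone normal < primary < metastatic trend
  (intermediate step effect/2); an optional discordant fraction flips a
  gene's direction in one dataset to exercise the direction-consistency
  logic.
- **Outliers** are convex mixtures of the clean mean profile with an
  independent random profile at strength λ — the downstream statistic
  is correlation-based, so decorrelation, not mean shift, is the right
  corruption.
- **Detection calls** are absent with probability 2·rate·(1 − u) where
  u is the cell's global intensity percentile: the configured rate on
  average, enriched at low intensity.
- **PPI** is a planted partition: a high-weight clique over the cores
  plus `module_size` proximal neighbors (weights U(0.7, 0.95); clique ⇒
  module connectivity guaranteed), an Erdős–Rényi background layer
  among the remaining nodes at `p_background` with weights
  U(0.15, 0.4), and module↔background coupling at
  `coupling_factor · p_background` (default 0.2). The coupling must be
  sparser than the background's own wiring: if the module couples at
  the full background rate, the dense clique becomes the global center
  of the network and essentially every node touching it scores D_j > 0,
  destroying the planted contrast between proximal and background
  nodes. `module_size` counts the proximal (non-core) members. PPI
  defaults (205 nodes, 12 cores, 27 proximal, background density
  ~2.6%) echo the scale of a STRING subnetwork around a small core set.
- **Determinism.** Every dataset draws from its own RNG stream derived
  from the master seed by fixed offsets; adding datasets never perturbs
  earlier ones, and identical configs give bit-identical output.
  Ground truth is written to separate files that no pipeline stage
  reads.

What the generator does *not* emulate: platform/batch effects between
datasets, probe-level cross-hybridization structure, count noise and
library-size variation for RNA-seq, correlated gene modules in the
expression matrices, and degree-heterogeneous (scale-free) PPI
backgrounds. Passing recovery tests therefore demonstrate correctness
of the inference chain under idealized replication, not robustness to
real cross-platform artifacts.

## Problem sizes and tolerances

The test and acceptance workloads are sized for seconds-scale runs
while keeping estimates stable: DE recovery uses 2000 genes × 10/group
over 20 seeds (null calibration over 100 seeds), outlier recovery
15-sample groups × 2000 genes over 100 seeds, module recovery 60-node
networks over 20 seeds, and the end-to-end run uses the generator
defaults above. Oracle comparisons use 1e-10–1e-12 absolute
tolerances (vectorized vs. naive implementations of identical
formulas); recovery criteria use rates (sensitivity ≥ 0.9, FDR ≤ 0.1,
detection ≥ 95%, false flags ≤ 10%) chosen as what the planted effect
sizes support with margin.

## Known limitations

- The moderated test covers two-group designs only (no paired or
  multi-factor models, no count-based testing).
- The final-DEG screen is a veto rule, not an evidence synthesis; weak
  but consistent validation support is not rewarded.
- The complete-mode SP matrix saturates at 1, so D_j contrasts are
  compressed on sparse graphs; the edges-only mode trades this for
  sensitivity to single-edge bottlenecks.
- Network descriptives on DEG-induced subgraphs depend strongly on the
  DEG cutoffs upstream; they are reported for description, not tested
  against any external reference.
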