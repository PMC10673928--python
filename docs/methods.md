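# Methods

## Data model and ingestion

A dataset is a proteins × voxels matrix of label-free quantification (LFQ)
intensities over a rectangular grid of square LCM voxels. Protein tables
are read in the MaxQuant `proteinGroups` dialect ("LFQ intensity <sample>"
columns; rows flagged Reverse / Potential contaminant / Only identified by
site are removed), the DIA-NN protein-matrix dialect (one column per run),
or a generic TSV. A raw LFQ value of 0 and an absent cell are both recorded
as missing — MaxQuant emits 0 for "not quantified", and treating it as a
real intensity would corrupt every downstream statistic. Observed
intensities are log2-transformed and the per-voxel median of observed
values is subtracted; columns with no observed value stay missing with a
warning. Voxel exclusion masks (empty voxels, annotated haemorrhage) are
user-supplied voxel-id lists applied before the "observed in ≥ 9 voxels"
protein filter, because such annotations are manual and not derivable from
the quantification alone. Grid coordinates are 0-based (row, col),
row-major; every map export states "row 0 = top, col 0 = left" in its
header so orientation is never ambiguous.

The fixed processing order is: flag filtering → exclusion-mask column drop
→ log2 + median centring → minimum-voxel filtering. Each step is a pure
function on the matrix, so the order is testable.

## Spatially variable proteins: Moran's *I*

Contiguity follows the Queen's case: two voxels are neighbours iff they
share an edge or a vertex, with binary weights (w ∈ {0,1}, not
row-standardised). For values x over n voxels,

I = (n / W) · Σᵢⱼ wᵢⱼ (xᵢ − x̄)(xⱼ − x̄) / Σᵢ (xᵢ − x̄)²,  W = Σᵢⱼ wᵢⱼ.

I ≈ +1 for spatially clustered fields, ≈ −1 for dispersed (checkerboard)
fields, and has expectation −1/(n−1) under random arrangement.
Significance uses random spatial permutation (default 999) with the
upper-tail pseudo-*p* convention p = (1 + b)/(1 + n_perm), where b counts
permutations with I* ≥ I_obs; positive autocorrelation is the screening
target, and the +1 correction keeps p ≥ 1/(n_perm+1). q-values are
Benjamini–Hochberg over all tested proteins.

Missing-value policy: each protein is tested on the subgraph induced by its
observed voxels; observed voxels left without any observed neighbour are
dropped (n_used records the drop), and proteins with fewer than 9 usable
voxels or zero variance are reported as untested with a reason rather than
failing the batch. Per-protein RNG streams derive from
`default_rng([master_seed, protein_index])`, so results are reproducible
and independent of iteration order.

## Spatially-unaware clustering

Voxel–voxel distances are pairwise-complete Euclidean with rescaling,
d = √(P/P_valid · Σ_valid (aₖ−bₖ)²), the convention of standard `dist`
implementations on matrices with missing values; a voxel pair with no
jointly observed protein is an error rather than a silent zero.
Average-linkage (UPGMA) hierarchical clustering of that matrix is followed
by a top-down dynamic tree cut: a static cut at the configured height
(default 100, appropriate for matrices with thousands of proteins), then
branches smaller than `min_cluster_size` (default 3) are absorbed into the
sibling with the smallest mean cophenetic distance until all clusters meet
the minimum. With `min_cluster_size=1` this reduces exactly to the static
cut. The hybrid tree-cut variant needs the primary data matrix and
additional parameters, so the simpler tree variant is used, with all knobs
in the configuration. Cluster labels are 1..K by decreasing size (ties by
first leaf index), since any other label↔region mapping would be
figure-specific.

For 2-D visualisation only: proteins observed in < 70 % of voxels are
removed, remaining gaps are imputed per voxel by draws from
Normal(μ − 1.8σ, (0.3σ)²) with (μ, σ) the observed column moments — the
usual proteomics stand-in for left-censored, below-detection values — and a
neighbour embedding maps voxels to the plane. The embedding backend is
pluggable (UMAP when `umap-learn` is installed, deterministic 2-component
PCA otherwise); no statistic depends on the coordinates, so tests use the
deterministic backend.

## Spatially-aware clustering: affinity network fusion

Two views over the same voxels:

* proteomic — Spearman rank correlation ρ between voxel profiles
  (average ranks for ties, pairwise-complete over proteins, ≥ 3 jointly
  observed required), distance D = 1 − ρ, computed on the top 25 % of
  proteins by observed-value variance (deterministic lexicographic
  tie-break), or on an explicit annotation list (e.g. core matrisome) for
  the restricted analysis;
* spatial — Euclidean distance between voxel centres in grid units
  (adjacent = 1, diagonal = √2).

Each distance matrix becomes an affinity with a locally-scaled Gaussian
kernel A_ij = exp(−D²_ij/(σᵢσⱼ)), σᵢ = mean distance from i to its k
nearest neighbours, k = max(10, n/10); local scaling keeps the two views'
affinities on a comparable footing without manual bandwidths. Fusion is a
one-step diffusion: each view's affinity is row-normalised into a
transition matrix P_v and k-NN-sparsified into a local kernel S_v, and the
fused network is Σ_v w_v · S_v P̄ S_vᵀ with P̄ the mean of all views' full
transition matrices and equal weights by default, symmetrised. Diffusing
over the mean network (rather than over the *other* views only) is a
deliberate choice: for any row-stochastic S, S·(J/n)·Sᵀ is exactly uniform,
so a strictly cross-view update lets one uninformative view erase the
other view's structure, whereas the mean-network update degrades
gracefully and reduces to S P Sᵀ for a single view. If every view is
block-diagonal with the same blocks, the fusion is too.

The cluster number is the maximal eigengap of the symmetric-normalised
Laplacian spectrum (ascending), searched over k ∈ [2, 15] — wide enough for
the 6–9 cluster regimes typical of tissue sections; a disconnected
affinity graph short-circuits to its component count. Final labels come
from normalised spectral clustering (k smallest Laplacian eigenvectors,
row-normalised, k-means with 50 seeded restarts), deterministic given the
seed. In the annotation-restricted analysis, voxels observing none of the
listed proteins are dropped from the views and reported with label 0.

## Markers, volcano, overrepresentation

Markers are per-(protein, cluster) one-vs-rest two-sample Wilcoxon
rank-sum tests, two-sided: exact when the pooled sample is ≤ 25 without
ties, tie- and continuity-corrected normal approximation otherwise, BH
jointly over all protein × cluster tests. A protein is a *marker* of a
cluster when q ≤ 1 % **and** its cluster-minus-rest median difference is
positive: although the test is two-sided, a region's functional readout
comes from its up-regulated proteins, and each down-regulated protein is
some other cluster's marker. Pairwise cluster comparisons use Welch's
unequal-variance t-test (the safe default when the variance structure is
unknown) with log2 fold-change = mean difference on the already-log2 data,
BH at 5 % and a ±2-fold-change flag.

Overrepresentation is a one-sided hypergeometric tail per (cluster, gene
set): with background N (all detected, gene-mapped proteins), set size K
(after intersection with the background), query n (cluster markers in the
background) and overlap k, p = P[X ≥ k]. Gene symbols are the first entry
of the (semicolon-separated) gene-name field, uppercased; unmapped proteins
drop out of the background. BH runs within each cluster's family of sets
(the per-cluster display convention), with a global family available in
configuration.

## Feature distances and aggregate maps

Point features (vessel centres) are supplied as a (row, col) coordinate
table — fractional coordinates allowed; image segmentation is out of
scope. Each voxel gets the minimum Euclidean distance from its centre to
any feature, in grid units and µm (× voxel side). Protein–distance
association uses Spearman correlation (robust to the nonlinear decay
shapes of diffusion gradients), two-sided p, BH across proteins, with the
same ≥ 9-voxel guard as the Moran screen. Aggregate set-abundance maps
(sum or mean over a protein set per voxel) use observed values only, and a
voxel observing none of the set is missing, matching the per-protein map
convention that undetected is grey, not zero.

## Synthetic data: what it emulates and what it does not

Defaults (the package's study conditions): a 16 × 16 grid partitioned into
3 Queen-contiguous regions grown by seeded multi-source flooding; 300
proteins = 100 region markers (+1.5 log2 units inside their region, spread
across regions), 50 smooth fields (Gaussian-smoothed white noise, length
scale 2 voxels, rescaled to unit sd, amplitude 0.5), 20 vessel-gradient
proteins (2·exp(−d/3) of the distance d to the nearest of 3 random point
features — blood-borne proteins form gradients around every vessel at
once), 130 nulls; per-protein log-normal baselines (log2 mean 25, sd 2),
observation noise sd 0.5 log2 units. Field amplitude sits at the noise
level because in the emulated tissue the dominant spatial signal is
regional composition, not smooth drift; gradient decay of 3 voxels keeps
vessel gradients visible across roughly a 9-voxel span, the scale of the
high-resolution vessel maps this mimics.

Missingness is left-censored (MNAR): P(missing | v) = logistic(α − βv) on
the log2 value v with slope β = 0.8; α is anchored as
logit(rate) + β·median(v) with rate = 0.2, so β = 0 reduces exactly to a
flat 20 % missing rate. An `empty_fraction` of voxels (default 0) is set
all-missing and excluded, emulating grid cells with no tissue. Raw
intensities 2^v are written in MaxQuant layout (missing = 0, empty flag
columns) for round-trip testing of the ingest path.

Not emulated: peptide-level quantification, between-run normalisation
artefacts, spatially correlated missingness, cell-type mixtures within a
voxel, and identification FDR. Passing recovery tests therefore show that
the statistics detect the planted structure classes under realistic
censoring and noise — not that they would resolve every feature of real
tissue data.

## Validation measurements and problem sizes

`topomaps.evaluation` (driven by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) computes: Moran oracle agreement on 100 random
6 × 6 fields (tolerance 1e-12 against a literal double loop); null
calibration on 2000 i.i.d. Gaussian fields over a 10 × 10 grid with 199
permutations (fraction of p ≤ 0.05 in [0.035, 0.065], the ±3σ binomial
band around 0.05); the permutation mean of I versus −1/(n−1) within 3
Monte-Carlo SEs; the hand-derivable worked statistics (I = −1/3 on the
split 2 × 2 grid, I = 1/3 on the 1 × 4 gradient, exact Wilcoxon 2/252,
hypergeometric 5/210, BH step-up [0.01..0.04] → 0.04); the recovery suite
on the default conditions over 5 seeds (≥ 90 % of smooth fields at
q ≤ 0.05, ≤ 7 % of nulls, ANF ARI ≥ 0.9 per seed against the planted
regions, ≥ 80 % of markers at 1 % FDR, ≥ 90 % of gradient proteins above
the 95th percentile of non-gradient |ρ| pooled over seeds — with 20
gradients among 300 proteins the all-protein percentile would be
unreachable by construction); eigengap recovery of k ∈ 2..8 on noiseless
block-diagonal affinities; and imputation moments over 10⁴ draws within 3
MC SEs. These sizes keep the whole validation run under a minute on one
CPU while leaving all rates far from their thresholds.

## Known limitations

* The dynamic tree cut implements the top-down tree variant only; results
  at a given height are not comparable to the hybrid variant.
* One-step, two-view ANF with equal weights; no iterative refinement or
  view-weight learning.
* The permutation universe for Moran's I is each protein's observed voxel
  subset, which is conservative for proteins whose missingness is itself
  spatial.
* Analytic (normal-approximation) Moran inference, local indicators
  (LISA) and Geary's C are out of scope, as are raw-spectrum processing
  and identification-level FDR.
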