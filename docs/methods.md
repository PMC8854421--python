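# Methods

This document records the statistical model behind each component of
`nfcnkit`, the rationale for fixed parameters, what the synthetic generator
does and does not cover, and the numerical choices that affect results.

## 1. Synthetic data generator (`nfcnkit.synthetic`)

### Count model

Counts are negative binomial: gene baselines are drawn log-normally, cell
library-size factors log-normally, and per-cell-type programs multiply the
mean of their member genes. Cell types are drawn with fixed proportions
(myeloidA 0.19, myeloidB 0.21, tumor 0.12, other 0.08, effector T 0.275,
exhausted T 0.125). A categorical batch covariate multiplies gene means so
that covariate regression has something real to remove.

The planted biology mirrors a suppressive myeloid→T-cell axis:

- **ligand / induction** programs are elevated in myeloidA cells,
- **receptor / activation** programs are elevated in exhausted T cells,
- each cell type additionally carries a marker program (`markers_<type>`),
- the ground-truth connected pairs are the full bipartite set of
  strongly-responding myeloidA senders × exhausted-T receivers, recorded in
  `GroundTruth.connected_pairs`.

Program strength is graded within a type (an "exhaustion gradient"), so
eligibility thresholds have a meaningful continuum to cut.

### Spatial model

Spots sit on an 18×18 grid at 200 µm pitch with 4–12 cells per spot. A
contiguous mesenchymal-like region covering 25% of spots is grown by random
breadth-first expansion; tumor and exhausted-T cells are preferentially
placed inside it. Spot counts are exact sums of their member cells' counts,
so single-cell and spot data are consistent by construction.

### Copy-number events

`plant_cnv` multiplies tumor-cell counts on chromosome 7 by 2^{+0.5} and on
chromosome 10 by 2^{-0.5}, with stochastic rounding so counts stay integers
and the expectation is exact. Non-tumor cells are bitwise untouched.

### Correlated-programs generator

`generate_correlated_spatial_programs` builds a spot grid in which two
80-gene programs have an **exact** sample correlation ρ at the level of the
latent program activities (achieved by orthonormalizing the latent draws
before mixing). After counts are formed and CP10K-normalized, the observed
program-score correlation is attenuated below ρ because depth normalization
couples genes compositionally on an 80-gene panel. This attenuation is a
property of the measurement pipeline, not a generator bug, and it is exactly
what the denoising benchmark (Section 5) is designed to overcome; the
generator was deliberately left unchanged.

### Scope and limitations

The generator covers what the estimators need and no more: there is no
ambient RNA, no doublets, no spatial platform noise beyond Poisson-level
count noise, no cell segmentation errors, and cell-type proportions are
fixed rather than hierarchical across samples. Conclusions about robustness
to those artifacts cannot be drawn from this package's benchmarks.

## 2. Preprocessing (`nfcnkit.preprocess`)

- **Normalization**: counts per 10,000 (CP10K) then log1p. The test suite
  checks conservation: `expm1` of every cell column sums back to 10,000
  within 1e-6.
- **Highly variable genes**: dispersion vs mean with a lowess trend;
  genes are ranked by residual dispersion.
- **Covariate regression + scaling**: per-gene OLS on the supplied covariate
  frame (categoricals are one-hot encoded), residuals z-scored. With only
  constant covariates this reduces exactly to z-scoring.
- **PCA dimensionality**: Horn's parallel analysis — keep components whose
  eigenvalue exceeds the 95th percentile of eigenvalues from permuted data.
- **Clustering**: shared-nearest-neighbor graph with Jaccard edge weights,
  partitioned by Leiden. Resolution is a user parameter; on well-separated
  blobs the planted partition is recovered exactly at low resolution.
- **Program enrichment** (`svd_enrichment`): the first right singular vector
  of the scaled submatrix of program genes, sign-oriented so that it
  correlates positively with mean program expression, then min–max
  normalized to [0, 1]. Requires at least two present member genes; missing
  genes raise an error naming the gene.
- **Quantile filter**: two-sided, keeps the central `q` mass (default 95%).

## 3. The NFCN algorithm (`nfcnkit.nfcn`)

For each side (sender, receiver):

1. **Expression score** `n_exp`: mean scaled expression of the side's
   expression program (ligand genes for senders, receptor genes for
   receivers), min–max normalized. Min–max normalization of a constant
   vector is undefined and raises an error rather than guessing.
2. **Effect score** `n_eff`: `svd_enrichment` of the side's effect program
   (induction genes for senders, activation genes for receivers).
3. **Trajectory density** `f_hat`: a kernel density estimate over the
   trajectory positions, Gaussian or Cauchy kernel, with the bandwidth
   restricted to 0.3 < h < 0.7. Bandwidths outside this range are rejected:
   below 0.3 the density is too spiky to robustify anything, above 0.7 it
   flattens and the central-quantile step loses meaning.
4. **Robustification**: the central 95% (two-sided quantile) of the density
   defines the inlier set. **Only the fitting of thresholds uses inliers**;
   every cell remains normalized and remains eligible for pairing. The
   filter robustifies scale estimation, it does not drop cells.
5. **Eligibility**: within each side, cells at or above the 70th percentile
   of both `n_exp` and `n_eff` (percentiles computed over inliers). On the
   receiver side the candidate pool is *all* T cells; the joint 70th
   percentile cut is what isolates the exhausted subpopulation. Restricting
   the pool to exhausted cells beforehand would double-count the selection
   and, in practice, collapse recall.
6. **Pairing**: every eligible sender × every eligible receiver;
   `pair_score = n_exp^send · n_eff^send · n_exp^recv · n_eff^recv`.
7. **Connected flag**: the top 1% of pairs by score (`ceil`, stable lexsort
   tie-break) are flagged connected.
8. **Spatial proximity filter** (optional, needs a grid and cell-type
   signatures): each signature is localized at the enrichment-weighted
   centroid of its top-5 scoring spots; connected pairs whose sender and
   receiver centroids are more than 150 µm apart are marked `excluded`,
   others `retained`. At the default 200 µm pitch, 150 µm is less than one
   spot spacing, so the filter effectively demands same-spot colocation of
   the two centroids — a deliberately conservative reading. The
   connected-pair density map (Section 4) is therefore computed from **all**
   connected pairs regardless of retained/excluded status: the density map
   is the spatial evidence, the centroid filter is downstream pruning.
9. **Score matrix** (`nfcn_score`): mean pair score between each
   sender-label/receiver-label combination, weighted by pair count and
   normalized to a maximum of 1. With an empty pair table and a label list,
   the result is an all-zero matrix over those labels (not an error).

## 4. Spatial statistics (`nfcnkit.spatial`)

- **Surfaces**: Gaussian-kernel weighted averages over spot coordinates,
  bandwidth controlled by a squared-distance threshold.
- **Moran's I**: queen (default) or rook contiguity on the grid;
  significance by permutation of values over spots, one-sided in the
  direction requested. The statistic matches the explicit double-sum
  definition to 1e-12 (verified against a brute-force oracle).
- **Distance profiles**: spots are binned by distance to the nearest
  top-decile spot of a reference signature; the target signature is
  rank-normalized and averaged per bin.
- **Connected-pair density**: each connected pair contributes, at every
  spot, the product of its sender-label and receiver-label signature
  enrichments; contributions are summed over pairs and min–max normalized.
  This is a co-enrichment reading of pair colocalization suited to spot
  arrays that lack single-cell resolution.
- **Autoencoder denoiser**: a dense numpy autoencoder trained full-batch
  with Adam. It is bitwise deterministic for a fixed `random_state` — no
  framework nondeterminism, no minibatch order effects.
- **Bayesian correlation**: a bivariate-t likelihood with a flat prior on
  the correlation, sampled by random-walk Metropolis; reported as posterior
  mean and central credible interval, with the seeded sample path exposed.

## 5. Denoising benchmark

For seeds 1–10 of the correlated-programs generator (planted latent
correlation ρ = 0.6): the raw pipeline computes the Pearson correlation of
the two programs' `svd_enrichment` scores after CP10K and scaling; the
denoised pipeline first passes log-normalized expression through the
autoencoder and then estimates the correlation with the Bayesian posterior
mean. The denoised estimate was closer to the planted ρ in 8 of 10 seeds.
The raw estimate's bias comes from the compositional attenuation described
in Section 1; the benchmark measures recovery from that attenuation plus
count noise.

## 6. Copy-number inference (`nfcnkit.cnv`)

1. **Reference cells**: 400 cells sampled (seeded) from a user predicate
   (typically T cells). Requests larger than the eligible pool return the
   whole pool with a warning; an empty pool is an error.
2. **Relative expression**: log-normalized expression minus the
   reference-cell mean per gene, clamped to ±2.6. The clamp bound is
   enforced throughout: no downstream value can exceed it because the
   moving average is contractive.
3. **Moving average**: 100-gene windows ordered by genomic position,
   **never spanning chromosome boundaries**; windows shrink at chromosome
   edges rather than padding. Gene input order does not matter — genes are
   sorted by annotation position internally.
4. **Recentering**: per-cell median subtraction, so a diploid cell's profile
   centers at zero even when overall expression shifts.

On the synthetic study, tumor vs reference t-statistics are roughly +20 for
the chromosome 7 gain and −28 for the chromosome 10 loss (seed 1 acceptance
run), with the maximum absolute profile value ≈ 1.32, well inside the clamp.

## 7. Determinism

Every stochastic stage takes an explicit seed (`SyntheticConfig.seed`,
`random_state`, `seed` arguments) and is bitwise reproducible: generator
counts, spot grids, NFCN pair tables, autoencoder weights, and Bayesian
posterior samples are all asserted equal across repeat runs in the test
suite. No stage reads global random state.

## 8. Known limitations

- The spatial proximity filter's conservatism at coarse pitch (Section 3,
  step 8) means `retained` can be empty on 200 µm grids; consumers should
  use the density map plus Moran's I for spatial evidence at that
  resolution.
- `nfcn_score` label axes are the sorted string labels supplied; numeric
  cluster IDs are stringified.
- The CNV module infers relative, smoothed expression shifts; it does not
  call integer copy numbers or breakpoints.
- The Bayesian correlation sampler is a simple random-walk Metropolis and
  is not tuned for very small samples. The autoencoder denoiser requires at
  least 50 observations and rejects smaller inputs.
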