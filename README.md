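# nfcnkit

Tools for studying suppressive myeloid–T-cell communication in tumor
microenvironments from single-cell and spot-based spatial transcriptomics.
The centerpiece is the **Nearest Functionally Connected Neighbor (NFCN)**
algorithm, which pairs individual ligand-producing cells with the individual
receiver cells most likely to be responding to them — for example,
IL-10-releasing CD163+/HMOX1+ myeloid cells and the exhausted CD8 T cells
they induce.

## Scientific idea

A ligand/receptor interaction leaves two footprints in expression data:

1. **Expression evidence** — the sender expresses the ligand and the genes
   that induce it; the receiver expresses the receptor and the downstream
   activation program.
2. **Effect evidence** — across cells, the induction and activation programs
   co-vary as coherent modules, which we summarize with the first right
   singular vector of each program's scaled-expression submatrix.

NFCN places every candidate sender and receiver on a shared trajectory. Each
side's cells get a min–max-normalized expression score and an enrichment
score; a kernel density estimate over the trajectory robustifies the scores,
and the central 95% of the density is used when fitting so that stray cells
do not distort the scale. Cells above the 70th percentile on both axes of
their side are eligible, every eligible sender is paired with every eligible
receiver, and the pair score is the product of the four normalized scores.
The top 1% of pairs are flagged as *connected*. When a spatial spot grid is
available, each cell type's signature is localized to a weighted centroid of
its top-scoring spots, and pairs whose sender and receiver centroids lie more
than 150 µm apart are marked excluded.

Supporting modules cover the rest of a typical analysis:

- `nfcnkit.synthetic` — a negative-binomial generator that plants the whole
  biology (ligand/induction/receptor/activation programs, cell-type marker
  programs, a contiguous mesenchymal-like tissue region, chromosome 7 gain /
  chromosome 10 loss in tumor cells) with a recorded ground truth.
- `nfcnkit.preprocess` — depth normalization to CP10K, highly variable gene
  selection, covariate regression + scaling, PCA dimensionality chosen by
  Horn's parallel analysis, shared-nearest-neighbor Leiden clustering, SVD
  program enrichment, and a two-sided quantile filter.
- `nfcnkit.spatial` — smoothed expression surfaces, tissue-state coordinates,
  a deterministic autoencoder denoiser, Bayesian correlation of program
  scores, Moran's I with permutation testing, and distance profiles between
  cell-state signatures.
- `nfcnkit.cnv` — copy-number inference from expression: reference-cell
  selection, clipped relative expression, a 100-gene moving average within
  chromosomes, and median recentering.

## Worked example

Simulate a study with a planted myeloid→T-cell interaction, recover it, and
check its spatial footprint:

```python
import warnings
import pandas as pd
from scipy.stats import spearmanr
from nfcnkit import (LigandReceptorSpec, NFCN, SyntheticConfig,
                     connected_pair_density, distance_profile,
                     generate_immune_counts, generate_spatial_spots,
                     lognormalize, morans_i, pair_precision_recall,
                     regress_and_scale)

# 1. Simulate counts plus a spatial spot grid.
cfg = SyntheticConfig(seed=1)
counts, truth = generate_immune_counts(cfg)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    grid = generate_spatial_spots(cfg, counts, truth)

# 2. Normalize and regress out the batch covariate.
lognorm = lognormalize(counts)
covariates = pd.DataFrame({"batch": pd.Categorical(truth.batches)})
scaled = regress_and_scale(lognorm, covariates)

# 3. Describe the interaction axis and run NFCN.
programs = truth.program_gene_members
spec = LigandReceptorSpec(
    ligand_genes=programs["ligand"],
    induction_genes=programs["induction"],
    receptor_genes=programs["receptor"],
    activation_genes=programs["activation"],
    target_cell_labels=frozenset({"Teff", "Texh"}))
model = NFCN(spec, random_state=1).fit(scaled, truth.cell_labels)

precision, recall = pair_precision_recall(model.pairs_, truth.connected_pairs)
print(f"connected pairs flagged: {len(model.pairs_.connected)}")
print(f"precision vs planted interactions: {precision:.3f}")
print(f"recall vs planted interactions:    {recall:.3f}")
print(f"highest-scoring sender/receiver:   {model.score_matrix_.argmax()}")

# 4. Spatial evidence: do connected pairs cluster, and do exhausted
#    T cells sit closer to tumor-dense spots?
signatures = {t: programs[f"markers_{t}"]
              for t in ("myeloidA", "myeloidB", "Teff", "Texh",
                        "tumor", "other")}
density = connected_pair_density(model.pairs_, grid, signatures)
i_obs, p = morans_i(density, grid, n_perm=999, seed=1)
print(f"pair-density Moran's I: {i_obs:.3f}  (permutation p = {p:.3f})")

profile = distance_profile(grid, programs["markers_Texh"],
                           programs["markers_tumor"])
sub = profile.dropna()
rho = spearmanr(sub["bin_center"], sub["mean_distance_um"]).statistic
print(f"exhaustion-vs-tumor-distance Spearman rho: {rho:.3f}")
```

Output (exact, reproducible):

```
connected pairs flagged: 2104
precision vs planted interactions: 1.000
recall vs planted interactions:    0.986
highest-scoring sender/receiver:   ('myeloidA', 'Texh')
pair-density Moran's I: 0.296  (permutation p = 0.001)
exhaustion-vs-tumor-distance Spearman rho: -0.626
```

The algorithm recovers the planted myeloidA→exhausted-T-cell axis with
perfect precision and 98.6% recall, the spots where connected pairs
concentrate are strongly spatially autocorrelated, and exhausted-T-cell
signal decreases with distance from tumor-dense spots — all consistent with
the planted biology.

A note on the spatial proximity filter: at the default spot pitch of 200 µm,
the 150 µm cutoff between signature centroids is stricter than one spot
spacing, so it acts as a same-spot colocation requirement and is very
conservative; see `docs/methods.md`.

## Reproduction

```
pip install --no-build-isolation -e .
python -m pytest -o addopts= -p no:cacheprovider -q tests/   # full suite
python scripts/acceptance.py --seed 1 --out results.json     # headline metrics
```

The acceptance script prints and writes JSON with median pair
precision/recall over five simulated studies, the top-scoring
sender/receiver hit rate, Moran's I and its permutation p-value for the
connected-pair density map, the exhaustion-distance trend, tumor-vs-reference
t-statistics for the planted chromosome 7 gain and chromosome 10 loss, the
CNV clamp bound check, the denoising win rate, and the normalization
mass-conservation error. All randomness derives from `--seed`.

Design and numerical details are in `docs/methods.md`.
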