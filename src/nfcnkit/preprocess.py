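"""Normalization, feature selection, scaling, clustering and SVD scoring.

Functions operate on the gene x cell :class:`~nfcnkit.containers.CountMatrix`;
each has a scikit-learn style estimator counterpart working on the cell x
gene orientation so the steps compose with sklearn pipelines.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.extmath import randomized_svd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, GeneSet

DEFAULT_SCALE = 10_000.0


# ---------------------------------------------------------------------------
# CP10K log-normalization
# ---------------------------------------------------------------------------

class LogNormalizer(BaseEstimator, TransformerMixin):
    """Per-cell depth normalization to ``scale`` counts followed by log1p.

    ``transform`` expects cells in rows. Columns sums of expm1-transformed
    output equal ``scale`` for every non-empty cell (row), the conservation
    identity the pipeline relies on.
    """

    def __init__(self, scale: float = DEFAULT_SCALE):
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("counts must be non-negative")
        totals = X.sum(axis=1)
        empty = totals == 0
        if empty.any():
            warnings.warn(f"{int(empty.sum())} cells have zero total count; "
                          "their normalized profiles are set to zero")
        safe = np.where(empty, 1.0, totals)
        return np.log1p(self.scale * X / safe[:, None])


def lognormalize(counts: CountMatrix, scale: float = DEFAULT_SCALE) -> CountMatrix:
    """CP10K log-normalization: ln(1 + scale * count / cell_total)."""
    if counts.layer != "raw":
        raise ValueError("lognormalize expects the raw layer")
    vals = LogNormalizer(scale=scale).fit_transform(counts.values.T).T
    return counts.with_values(vals, layer="lognorm")


# ---------------------------------------------------------------------------
# Highly variable genes
# ---------------------------------------------------------------------------

def select_variable_genes(m: CountMatrix, n: int = 2000) -> np.ndarray:
    """Top ``n`` genes by dispersion after removing the mean-variance trend.

    The dispersion statistic is the residual of log10 variance around a
    lowess fit against log10 mean expression; ties break by gene id so the
    ranking is fully deterministic.
    """
    if m.layer != "lognorm":
        raise ValueError("select_variable_genes expects the lognorm layer")
    if n > m.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {m.n_genes}")
    mu = m.values.mean(axis=1)
    var = m.values.var(axis=1)
    eps = 1e-12
    lmu, lvar = np.log10(mu + eps), np.log10(var + eps)
    expressed = mu > 0
    if expressed.sum() >= 10:
        fit = lowess(lvar[expressed], lmu[expressed], frac=0.5,
                     return_sorted=False)
        disp = np.full(m.n_genes, -np.inf)
        disp[expressed] = lvar[expressed] - fit
    else:
        disp = lvar
    order = np.lexsort((m.gene_ids.astype(str), -disp))
    return m.gene_ids[order[:n]]


class VariableGeneSelector(BaseEstimator, TransformerMixin):
    """Select the ``n_top`` most dispersed features of a lognorm cell x gene matrix."""

    def __init__(self, n_top: int = 2000):
        self.n_top = n_top

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        ids = np.array([f"F{i:06d}" for i in range(X.shape[1])], dtype=object)
        m = CountMatrix(X.T, ids, _obs_ids(X.shape[0]), layer="lognorm")
        top = select_variable_genes(m, self.n_top)
        lookup = {g: i for i, g in enumerate(ids)}
        self.support_ = np.array(sorted(lookup[g] for g in top))
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def _obs_ids(n: int) -> np.ndarray:
    return np.array([f"O{i:06d}" for i in range(n)], dtype=object)


# ---------------------------------------------------------------------------
# Covariate regression + z-scaling
# ---------------------------------------------------------------------------

class CovariateScaler(BaseEstimator, TransformerMixin):
    """Residualize each feature on nuisance covariates, then z-score it.

    Covariates (batch as categorical, QC fractions as numeric) are expanded
    into a design matrix with intercept; residuals come from per-feature
    ordinary least squares. Constant features map to all-zero columns.
    """

    def __init__(self, covariates: pd.DataFrame | None = None):
        self.covariates = covariates

    @staticmethod
    def _design(cov: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(cov))]
        for name in cov.columns:
            col = cov[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, drop_first=True)
                for c in dummies.columns:
                    cols.append(dummies[c].to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        cov = self.covariates
        if cov is None:
            cov = pd.DataFrame(index=range(X.shape[0]))
        if len(cov) != X.shape[0]:
            raise ValueError("covariates must have one row per cell")
        self.design_ = self._design(cov)
        self.coef_, *_ = np.linalg.lstsq(self.design_, X, rcond=None)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        resid = X - self.design_ @ self.coef_
        sd = resid.std(axis=0)
        mean = resid.mean(axis=0)
        out = np.zeros_like(resid)
        ok = sd > 1e-12
        out[:, ok] = (resid[:, ok] - mean[ok]) / sd[ok]
        return out


def regress_and_scale(m: CountMatrix, covariates: pd.DataFrame) -> CountMatrix:
    """OLS-residualize every gene against per-cell covariates and z-score."""
    if m.layer != "lognorm":
        raise ValueError("regress_and_scale expects the lognorm layer")
    if len(covariates) != m.n_cells:
        raise ValueError("covariates incomplete: need one row per cell")
    scaler = CovariateScaler(covariates.reset_index(drop=True))
    vals = scaler.fit_transform(m.values.T).T
    return m.with_values(vals, layer="scaled")


def qc_covariates(counts: CountMatrix, batches=None,
                  mito_prefix: str = "MT-", ribo_prefixes=("RPS", "RPL")
                  ) -> pd.DataFrame:
    """Assemble the standard nuisance table: batch, pct_mito, pct_ribo."""
    totals = counts.values.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    names = counts.gene_ids.astype(str)
    mito = np.char.startswith(names, mito_prefix)
    ribo = np.zeros(len(names), dtype=bool)
    for p in ribo_prefixes:
        ribo |= np.char.startswith(names, p)
    tab = pd.DataFrame({
        "pct_mito": counts.values[mito].sum(axis=0) / totals if mito.any()
        else np.zeros(counts.n_cells),
        "pct_ribo": counts.values[ribo].sum(axis=0) / totals if ribo.any()
        else np.zeros(counts.n_cells),
    })
    if batches is not None:
        tab.insert(0, "batch", pd.Categorical(np.asarray(batches).astype(str)))
    return tab


# ---------------------------------------------------------------------------
# Dimensionality selection (Horn-style parallel analysis)
# ---------------------------------------------------------------------------

class ParallelAnalysisPCA(BaseEstimator):
    """Number of nontrivial principal components by parallel analysis.

    The observed eigenvalue spectrum is compared rank-by-rank with the 95th
    percentile of eigenvalues obtained from matrices whose features are
    independently permuted across observations; ``n_components_`` counts the
    leading consecutive eigenvalues exceeding their null.
    """

    def __init__(self, n_max: int = 100, n_perm: int = 20,
                 percentile: float = 95.0, random_state: int = 0):
        self.n_max = n_max
        self.n_perm = n_perm
        self.percentile = percentile
        self.random_state = random_state

    @staticmethod
    def _eigvals(X: np.ndarray, k: int, seed: int) -> np.ndarray:
        _, s, _ = randomized_svd(X, n_components=k, random_state=seed)
        return s**2 / (X.shape[0] - 1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_obs, n_feat = X.shape
        k = min(self.n_max, n_obs - 1, n_feat)
        if k < 1 or np.linalg.matrix_rank(X[: min(n_obs, 50)]) < 2:
            raise ValueError("matrix too degenerate for parallel analysis")
        Xc = X - X.mean(axis=0)
        self.eigenvalues_ = self._eigvals(Xc, k, self.random_state)
        rng = np.random.default_rng(self.random_state)
        null = np.empty((self.n_perm, k))
        for p in range(self.n_perm):
            perm = rng.permuted(Xc, axis=0)  # permute each feature independently
            null[p] = self._eigvals(perm, k, self.random_state + 1 + p)
        self.null_quantiles_ = np.percentile(null, self.percentile, axis=0)
        passing = self.eigenvalues_ > self.null_quantiles_
        n = 0
        for flag in passing:
            if not flag:
                break
            n += 1
        self.n_components_ = max(1, n)
        return self


def nontrivial_components(m: CountMatrix, n_max: int = 100,
                          n_perm: int = 20, seed: int = 0) -> int:
    """Count nontrivial PCs of a scaled matrix against permuted nulls."""
    if m.layer != "scaled":
        raise ValueError("nontrivial_components expects the scaled layer")
    if n_max > min(m.n_genes, m.n_cells) - 1:
        raise ValueError("n_max exceeds min(genes, cells) - 1")
    est = ParallelAnalysisPCA(n_max=n_max, n_perm=n_perm, random_state=seed)
    est.fit(m.values.T)
    return est.n_components_


# ---------------------------------------------------------------------------
# SNN clustering
# ---------------------------------------------------------------------------

class SNNClusterer(BaseEstimator, ClusterMixin):
    """Shared-nearest-neighbor graph + Leiden modularity communities.

    A kNN graph is symmetrized into SNN edges weighted by the Jaccard
    overlap of neighborhoods; communities come from the Leiden algorithm on
    the RB-configuration modularity objective at the given resolution.
    Deterministic for a fixed ``random_state``.
    """

    def __init__(self, k_neighbors: int = 20, resolution: float = 0.8,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        import igraph
        import leidenalg

        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if X.shape[1] < 2:
            raise ValueError("embedding must have at least 2 dimensions")
        if n <= self.k_neighbors:
            raise ValueError("fewer cells than k_neighbors")
        nn = NearestNeighbors(n_neighbors=self.k_neighbors).fit(X)
        knn = nn.kneighbors(return_distance=False)
        neigh_sets = [set(row) | {i} for i, row in enumerate(knn)]
        edges, weights = [], []
        for i in range(n):
            for j in knn[i]:
                j = int(j)
                if j <= i:
                    continue
                inter = len(neigh_sets[i] & neigh_sets[j])
                union = len(neigh_sets[i] | neigh_sets[j])
                w = inter / union
                if w > 0:
                    edges.append((i, j))
                    weights.append(w)
        g = igraph.Graph(n=n, edges=edges)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights=weights, resolution_parameter=self.resolution,
            seed=self.random_state, n_iterations=2)
        self.labels_ = np.asarray(part.membership)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def snn_cluster(embedding: np.ndarray, k_neighbors: int = 20,
                resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Cluster a cell x k embedding; returns integer labels per cell."""
    return SNNClusterer(k_neighbors=k_neighbors, resolution=resolution,
                        random_state=seed).fit_predict(embedding)


# ---------------------------------------------------------------------------
# SVD gene-set enrichment
# ---------------------------------------------------------------------------

class GeneSetSVDScorer(BaseEstimator, TransformerMixin):
    """Per-cell activity of gene sets from the first right-singular vector.

    For each gene set the member-gene submatrix (genes x cells) is
    decomposed; the first right-singular vector, sign-oriented to correlate
    non-negatively with mean member expression, is min-max rescaled to
    [0, 1] and reported as the per-cell score.
    """

    def __init__(self, gene_sets=None, gene_ids=None):
        self.gene_sets = gene_sets
        self.gene_ids = gene_ids

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        ids = np.asarray(self.gene_ids, dtype=object)
        m = CountMatrix(X.T, ids, _obs_ids(X.shape[0]), layer="scaled")
        return np.column_stack([svd_enrichment(m, gs) for gs in self.gene_sets])


def svd_enrichment(m: CountMatrix, gs: GeneSet) -> np.ndarray:
    """First right-singular-vector activity of ``gs`` members, in [0, 1]."""
    idx = m.gene_index(gs.genes)
    if len(idx) < 2:
        missing = sorted(set(gs.genes) - set(m.gene_ids))
        raise ValueError(
            f"gene set {gs.name!r} has {len(idx)} member(s) in the matrix "
            f"(need >=2); missing: {missing[:10]}")
    sub = np.asarray(m.values[idx], dtype=float)
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    v = vt[0]
    mean_expr = sub.mean(axis=0)
    if np.dot(v, mean_expr - mean_expr.mean()) < 0 or (
            np.allclose(mean_expr, mean_expr.mean()) and v.sum() < 0):
        v = -v
    v = v / np.linalg.norm(v)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-15:
        return np.full(m.n_cells, 0.5)
    return (v - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Quantile outlier rejection
# ---------------------------------------------------------------------------

def quantile_filter(scores: np.ndarray, q: float = 0.95) -> np.ndarray:
    """Retain values inside the central ``q`` mass of the empirical distribution.

    Two-sided: a value is rejected if it lies outside the
    [(1-q)/2, (1+q)/2] empirical quantiles. With fewer than 10 values no
    filtering is applied (all retained, with a warning).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    if scores.size < 10:
        warnings.warn("fewer than 10 values: quantile filter skipped")
        return np.ones(scores.size, dtype=bool)
    lo, hi = np.quantile(scores, [(1 - q) / 2, (1 + q) / 2])
    return (scores >= lo) & (scores <= hi)
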