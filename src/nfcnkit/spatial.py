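"""Spatially resolved analytics over rectangular spot grids.

Covers the spatial arm of the pipeline: per-spot gene-set scoring, surface
matrices with squared-distance smoothing, the four-program cellular-state
representation, a denoising autoencoder with Bayesian correlation of
denoised programs, Moran's I with permutation inference, and
distance-to-signature profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, GeneSet, SpatialGrid
from .preprocess import lognormalize, regress_and_scale, svd_enrichment


# ---------------------------------------------------------------------------
# Per-spot signature scoring
# ---------------------------------------------------------------------------

def score_spots(grid: SpatialGrid, gene_set: GeneSet) -> np.ndarray:
    """Per-spot activity of ``gene_set`` in [0, 1].

    Spot counts are CP10K log-normalized, z-scored per gene, and scored with
    the first-right-singular-vector enrichment used on single cells.
    """
    m = CountMatrix(grid.counts.T, grid.gene_ids, grid.spot_ids, layer="raw")
    ln = lognormalize(m)
    scaled = regress_and_scale(ln, pd.DataFrame(index=range(m.n_cells)))
    return svd_enrichment(scaled, gene_set)


# ---------------------------------------------------------------------------
# Surface matrices
# ---------------------------------------------------------------------------

def surface_matrix(grid: SpatialGrid, values: np.ndarray,
                   bandwidth_threshold: float) -> np.ndarray:
    """Dense (n_rows x n_cols) smoothed field over the grid extent.

    Smoothing weight between covered positions p, q is
    ``exp(-||p - q||^2 / theta)`` on physical (um) coordinates, rows
    normalized so the output at a covered position is a convex combination
    of the input values; positions without a spot are 0.
    """
    theta = float(bandwidth_threshold)
    if theta <= 0:
        raise ValueError("bandwidth threshold must be positive")
    values = np.asarray(values, dtype=float)
    if values.shape[0] != grid.n_spots:
        raise ValueError("one value per spot required")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    coords = grid.coords_um()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    w = np.exp(-d2 / theta)
    smoothed = (w @ values) / w.sum(axis=1)
    out = np.zeros((grid.n_rows, grid.n_cols))
    out[grid.rows, grid.cols] = smoothed
    return out


# ---------------------------------------------------------------------------
# Cellular-state representation
# ---------------------------------------------------------------------------

@dataclass
class StateCoordinates:
    """Two-dimensional state-plot coordinates per spot."""

    A1: np.ndarray
    A2: np.ndarray
    color: np.ndarray
    scores: np.ndarray  # the four input scores, spots x 4


def _signed_log2(delta: np.ndarray) -> np.ndarray:
    return np.sign(delta) * np.log2(np.abs(delta) + 1.0)


def state_coordinates(gs_scores: np.ndarray) -> StateCoordinates:
    """Map four per-spot program scores to the 2-D state representation.

    The vertical axis separates the first program pair from the second:
    ``A1 = max(GS1, GS2) - max(GS3, GS4)``. The horizontal axis is the
    signed log2 contrast of the winning pair: for ``A1 > 0``,
    ``A2 = sign(GS1-GS2) * log2(|GS1-GS2| + 1)``, analogously with
    (GS3, GS4) for ``A1 <= 0``. ``color`` is the 0.5-quantile-centered
    normal-fit quantile of the winning score.
    """
    gs = np.asarray(gs_scores, dtype=float)
    if gs.ndim != 2 or gs.shape[1] != 4:
        raise ValueError("gs_scores must be spots x 4")
    if np.isnan(gs).any():
        raise ValueError("missing score")
    a1 = np.maximum(gs[:, 0], gs[:, 1]) - np.maximum(gs[:, 2], gs[:, 3])
    upper = a1 > 0
    a2 = np.where(upper, _signed_log2(gs[:, 0] - gs[:, 1]),
                  _signed_log2(gs[:, 2] - gs[:, 3]))
    winner = np.where(upper, np.maximum(gs[:, 0], gs[:, 1]),
                      np.maximum(gs[:, 2], gs[:, 3]))
    mu, sd = winner.mean(), winner.std()
    if sd < 1e-12:
        color = np.full(len(winner), 0.5)
    else:
        from scipy.stats import norm

        color = norm.cdf(winner, loc=mu, scale=sd)
    return StateCoordinates(A1=a1, A2=a2, color=color, scores=gs)


# ---------------------------------------------------------------------------
# Denoising autoencoder
# ---------------------------------------------------------------------------

class AutoencoderDenoiser(BaseEstimator, TransformerMixin):
    """Dense undercomplete autoencoder trained by backpropagation.

    Encoder maps the input through ReLU hidden layers to a ``bottleneck``-
    unit latent code; the decoder mirrors the shape with an unconstrained
    (linear) output layer. Training minimizes mean squared reconstruction
    error with full-batch Adam, so runs are bitwise reproducible for a fixed
    ``random_state``. Features are standardized internally and restored on
    output.
    """

    def __init__(self, bottleneck: int = 32, hidden: tuple = (64,),
                 epochs: int = 400, learning_rate: float = 1e-2,
                 standardize: bool = True, random_state: int = 0):
        self.bottleneck = bottleneck
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.standardize = standardize
        self.random_state = random_state

    # -- forward / backward ---------------------------------------------
    def _init_layers(self, d: int, rng) -> list:
        dims = [d, *self.hidden, self.bottleneck, *reversed(self.hidden), d]
        layers = []
        for i in range(len(dims) - 1):
            fan_in, fan_out = dims[i], dims[i + 1]
            W = rng.normal(0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            b = np.zeros(fan_out)
            layers.append([W, b])
        return layers

    @staticmethod
    def _forward(layers, X):
        acts = [X]
        a = X
        last = len(layers) - 1
        for i, (W, b) in enumerate(layers):
            z = a @ W + b
            a = z if i == last else np.maximum(z, 0.0)
            acts.append(a)
        return acts

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("NaN in autoencoder input")
        if X.shape[0] < 50:
            raise ValueError("need at least 50 observations to train")
        rng = np.random.default_rng(self.random_state)
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.sd_ = np.where(sd < 1e-12, 1.0, sd)
            Xs = (X - self.mean_) / self.sd_
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.sd_ = np.ones(X.shape[1])
            Xs = X

        layers = self._init_layers(X.shape[1], rng)
        mom = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
        vel = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        n = X.shape[0]
        self.loss_history_ = []
        t = 0
        for epoch in range(self.epochs):
            acts = self._forward(layers, Xs)
            err = acts[-1] - Xs
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"autoencoder loss diverged at epoch {epoch}: {loss}")
            self.loss_history_.append(loss)
            grad = 2.0 * err / err.size
            t += 1
            for i in range(len(layers) - 1, -1, -1):
                W, b = layers[i]
                a_prev = acts[i]
                if i != len(layers) - 1:
                    grad = grad * (acts[i + 1] > 0)
                gW = a_prev.T @ grad
                gb = grad.sum(axis=0)
                grad = grad @ W.T
                for slot, g in ((0, gW), (1, gb)):
                    mom[i][slot] = beta1 * mom[i][slot] + (1 - beta1) * g
                    vel[i][slot] = beta2 * vel[i][slot] + (1 - beta2) * g**2
                    mhat = mom[i][slot] / (1 - beta1**t)
                    vhat = vel[i][slot] / (1 - beta2**t)
                    layers[i][slot] = layers[i][slot] - lr * mhat / (np.sqrt(vhat) + eps)
        self.layers_ = layers
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean_) / self.sd_
        out = self._forward(self.layers_, Xs)[-1]
        return out * self.sd_ + self.mean_

    def reconstruction_mse(self, X) -> float:
        X = np.asarray(X, dtype=float)
        return float(((self.transform(X) - X) ** 2).mean())


def autoencoder_denoise(matrix: np.ndarray, bottleneck: int = 32,
                        epochs: int = 400, learning_rate: float = 1e-2,
                        seed: int = 0) -> np.ndarray:
    """Denoise a spot x gene matrix; thin wrapper over AutoencoderDenoiser."""
    ae = AutoencoderDenoiser(bottleneck=bottleneck, epochs=epochs,
                             learning_rate=learning_rate, random_state=seed)
    return ae.fit(matrix).transform(matrix)


# ---------------------------------------------------------------------------
# Bayesian correlation (robust bivariate-t model)
# ---------------------------------------------------------------------------

@dataclass
class CorrelationPosterior:
    """Posterior over the correlation of a robust bivariate-t model."""

    samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_samples: int
    seed: int


def _bivariate_t_logpdf(xy: np.ndarray, mu: np.ndarray, s1: float, s2: float,
                        rho: float, nu: float) -> float:
    """Sum log density of a bivariate Student-t with shape from (s1, s2, rho)."""
    det = (s1 * s2) ** 2 * (1 - rho**2)
    z1 = (xy[:, 0] - mu[0]) / s1
    z2 = (xy[:, 1] - mu[1]) / s2
    q = (z1**2 - 2 * rho * z1 * z2 + z2**2) / (1 - rho**2)
    n = xy.shape[0]
    const = (gammaln((nu + 2) / 2) - gammaln(nu / 2)
             - math.log(nu * math.pi) - 0.5 * math.log(det))
    return n * const - (nu + 2) / 2 * np.log1p(q / nu).sum()


def bayesian_correlation(x: np.ndarray, y: np.ndarray, n_samples: int = 4000,
                         seed: int = 0, n_burn: int = 1000) -> CorrelationPosterior:
    """Posterior over the correlation rho of a bivariate-t model.

    Heavy-tailed likelihood (Student-t errors), uniform prior on rho,
    flat priors on locations and log scales, exponential prior (mean 29)
    on the degrees of freedom above 2. Sampled with seeded random-walk
    Metropolis; the point estimate is the posterior mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")

    xy = np.column_stack([x, y])
    r0 = float(np.clip(np.corrcoef(x, y)[0, 1], -0.99, 0.99))
    # theta = (mu1, mu2, log s1, log s2, atanh(rho), log(nu - 2))
    theta = np.array([x.mean(), y.mean(), math.log(x.std()),
                      math.log(y.std()), math.atanh(r0), math.log(8.0)])

    def logpost(th) -> float:
        mu = th[:2]
        s1, s2 = math.exp(th[2]), math.exp(th[3])
        rho = math.tanh(th[4])
        rho = max(min(rho, 1 - 1e-9), -1 + 1e-9)
        nu = 2.0 + math.exp(th[5])
        ll = _bivariate_t_logpdf(xy, mu, s1, s2, rho, nu)
        # Uniform prior on rho: Jacobian d rho / d z = 1 - rho^2.
        lp = math.log1p(-rho**2)
        # Exponential(29) prior on nu - 2, with Jacobian exp(th[5]).
        lp += -(nu - 2.0) / 29.0 + th[5]
        return ll + lp

    rng = np.random.default_rng(seed)
    scale = np.array([x.std(), y.std(), 1.0, 1.0, 1.0, 1.0]) / math.sqrt(x.size)
    scale[4:] = 2.0 / math.sqrt(x.size)
    scale[5] = 0.5
    cur_lp = logpost(theta)
    rho_draws = np.empty(n_samples)
    accept = 0
    total = n_burn + n_samples
    for i in range(total):
        prop = theta + rng.normal(size=6) * scale
        lp = logpost(prop)
        if math.log(rng.random() + 1e-300) < lp - cur_lp:
            theta, cur_lp = prop, lp
            accept += 1
        if i == n_burn // 2:
            # one adaptation pass during burn-in
            rate = accept / (i + 1)
            scale *= math.exp(rate - 0.25)
        if i >= n_burn:
            rho_draws[i - n_burn] = math.tanh(theta[4])

    lo, hi = np.quantile(rho_draws, [0.025, 0.975])
    return CorrelationPosterior(
        samples=rho_draws, mean=float(rho_draws.mean()),
        ci_low=float(lo), ci_high=float(hi), n_samples=n_samples, seed=seed)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def grid_adjacency(grid: SpatialGrid, scheme: str = "queen") -> sparse.csr_matrix:
    """Row-standardized spot adjacency (rook: 4-neighborhood; queen: 8)."""
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif scheme == "queen":
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    else:
        raise ValueError("scheme must be 'rook' or 'queen'")
    index = {(r, c): i for i, (r, c) in enumerate(zip(grid.rows, grid.cols))}
    rows, cols = [], []
    for i, (r, c) in enumerate(zip(grid.rows, grid.cols)):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    w = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(grid.n_spots, grid.n_spots))
    rs = np.asarray(w.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    return sparse.diags(1.0 / rs) @ w


def morans_i(values: np.ndarray, grid: SpatialGrid, scheme: str = "queen",
             n_perm: int = 999, seed: int = 0,
             alternative: str = "greater") -> tuple:
    """Moran's I with a permutation p-value.

    I = (n / sum W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) on the
    row-standardized adjacency; the p-value compares the observed I with
    ``n_perm`` random relabelings of the spots.
    """
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_spots or values.size < 5:
        raise ValueError("need one value per spot and at least 5 spots")
    if values.std() == 0:
        raise ValueError("Moran's I undefined for a constant field")
    W = grid_adjacency(grid, scheme)
    z = values - values.mean()
    s0 = W.sum()
    denom = (z**2).sum()

    def stat(zv: np.ndarray) -> float:
        return float(values.size / s0 * (zv @ (W @ zv)) / denom)

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm)
    for p in range(n_perm):
        perm_stats[p] = stat(rng.permutation(z))
    if alternative == "greater":
        extreme = (perm_stats >= i_obs).sum()
    elif alternative == "less":
        extreme = (perm_stats <= i_obs).sum()
    elif alternative == "two-sided":
        center = perm_stats.mean()
        extreme = (np.abs(perm_stats - center) >= abs(i_obs - center)).sum()
    else:
        raise ValueError("alternative must be greater/less/two-sided")
    pval = (extreme + 1) / (n_perm + 1)
    return i_obs, float(pval)


# ---------------------------------------------------------------------------
# Distance-to-signature profiles
# ---------------------------------------------------------------------------

def distance_profile(grid: SpatialGrid, target_signature: GeneSet,
                     reference_signature: GeneSet, n_bins: int = 20
                     ) -> pd.DataFrame:
    """Mean distance to the reference high-enrichment territory, by target
    probability bin.

    Per spot, the target probability is the rank-normalized enrichment of
    ``target_signature``; the distance is the physical distance (um) to the
    nearest spot in the top decile of ``reference_signature`` enrichment.
    Returns a frame with bin centers, mean distance and spot counts.
    """
    t_scores = score_spots(grid, target_signature)
    r_scores = score_spots(grid, reference_signature)
    order = np.argsort(np.argsort(t_scores, kind="stable"), kind="stable")
    prob = order / max(len(t_scores) - 1, 1)
    thr = np.quantile(r_scores, 0.9)
    ref_idx = np.flatnonzero(r_scores >= thr)
    if ref_idx.size == 0:
        raise ValueError("reference top decile is empty")
    coords = grid.coords_um()
    d = np.linalg.norm(coords[:, None, :] - coords[None, ref_idx, :],
                       axis=-1).min(axis=1)
    bins = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(prob, bins) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        rows.append({
            "bin_center": (bins[b] + bins[b + 1]) / 2,
            "mean_distance_um": float(d[mask].mean()) if mask.any() else np.nan,
            "n_spots": int(mask.sum()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Connected-pair density mapping
# ---------------------------------------------------------------------------

def connected_pair_density(pairs, grid: SpatialGrid, signatures: dict
                           ) -> np.ndarray:
    """Per-spot density of mapped connected pairs.

    Each connected pair contributes the product of its ligand and receiver
    cluster signature enrichments per spot; contributions are summed over
    pairs and min-max normalized. This realizes the co-enrichment reading
    of pair colocalization on spot arrays that lack single-cell
    resolution. The mapping is computed from all connected pairs: the
    density map itself is the spatial evidence, while the centroid
    proximity filter is a separate downstream pruning step.
    """
    df = pairs.connected
    density = np.zeros(grid.n_spots)
    if df.empty:
        return density
    combos = df.groupby(["ligand_cluster", "receiver_cluster"]).size()
    cache: dict = {}

    def scores_for(label):
        if label not in cache:
            cache[label] = score_spots(grid, signatures[label])
        return cache[label]

    for (lc, rc), n in combos.items():
        if lc not in signatures or rc not in signatures:
            continue
        density += n * scores_for(lc) * scores_for(rc)
    top = density.max()
    if top > 0:
        density = density / top
    return density
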