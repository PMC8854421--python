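"""Nearest Functionally Connected Neighbor (NFCN) inference.

NFCN pairs candidate ligand-releasing cells with receiver cells when four
pieces of evidence line up: the ligand is expressed and its upstream
induction program is active in the sender, and the receptor is expressed
with its downstream activation program active in the receiver. Cells are
aligned along a kernel-smoothed "interaction trajectory"; eligibility uses
the upper 70% of both score axes, pairs are scored conjunctively, the top
1% of pair scores is flagged as connected, and spatially implausible pairs
(putative distance above 150 um) are excluded using spot-level signature
mapping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountMatrix, GeneSet, SpatialGrid
from .preprocess import quantile_filter, svd_enrichment

KERNELS = ("gaussian", "cauchy")
H_BOUNDS = (0.3, 0.7)


@dataclass
class LigandReceptorSpec:
    """The four gene programs and the receiver cell labels."""

    ligand_genes: GeneSet
    induction_genes: GeneSet
    receptor_genes: GeneSet
    activation_genes: GeneSet
    target_cell_labels: frozenset

    def __post_init__(self) -> None:
        self.target_cell_labels = frozenset(self.target_cell_labels)

    def validate_against(self, gene_ids) -> None:
        present = set(gene_ids)
        sets = {
            "ligand": set(self.ligand_genes.genes) & present,
            "induction": set(self.induction_genes.genes) & present,
            "receptor": set(self.receptor_genes.genes) & present,
            "activation": set(self.activation_genes.genes) & present,
        }
        for name, s in sets.items():
            if not s:
                raise ValueError(f"{name} gene set empty after intersection")
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sets[a] & sets[b]:
                    raise ValueError(f"{a} and {b} gene sets overlap in the matrix")


@dataclass
class TrajectoryScores:
    """Per-cell interaction-trajectory coordinates (ligand and receiver sides)."""

    cell_ids: np.ndarray
    side: np.ndarray  # "ligand" or "receiver"
    clusters: np.ndarray
    A_exp: np.ndarray
    A_eff: np.ndarray
    retained: np.ndarray
    n_exp: np.ndarray  # min-max of A_exp within side (NaN if rejected)
    n_eff: np.ndarray
    f_hat: np.ndarray  # KDE of n_exp within side, at the cell
    trajectory_position: np.ndarray
    rank: np.ndarray  # 1 = most extreme within side
    kernel: str = "gaussian"
    h: float = 0.5


@dataclass
class ConnectedPairs:
    """Emitted candidate pairs plus selection thresholds and spatial status.

    ``pairs`` holds every eligible ligand x eligible receiver combination
    with its conjunctive score; rows with ``connected`` True are the top
    ``top_fraction`` by pair score. ``status`` is one of ``retained``,
    ``excluded`` (putative distance above the limit) or ``unmapped``.
    """

    pairs: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def connected(self) -> pd.DataFrame:
        return self.pairs[self.pairs["connected"]]

    def retained_connected(self) -> pd.DataFrame:
        c = self.connected
        return c[c["status"] != "excluded"]


@dataclass
class NFCNScoreMatrix:
    """Cluster x cluster connectivity summary (scores in [0, 1])."""

    scores: pd.DataFrame  # ligand clusters x receiver clusters
    n_pairs: pd.DataFrame

    def argmax(self):
        arr = self.scores.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        return self.scores.index[i], self.scores.columns[j]


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def downsample_representative(cell_ids, strata, n: int = 3000, seed: int = 0
                              ) -> np.ndarray:
    """Proportional stratified sample of up to ``n`` cells without replacement."""
    cell_ids = np.asarray(cell_ids)
    strata = np.asarray(strata)
    if cell_ids.size == 0:
        raise ValueError("no cells to downsample")
    if cell_ids.size <= n:
        return cell_ids.copy()
    labels, counts = np.unique(strata, return_counts=True)
    if n < len(labels):
        raise ValueError("n must be at least the number of strata")
    rng = np.random.default_rng(seed)
    # Largest-remainder allocation keeps totals exactly n.
    quota = counts * n / counts.sum()
    alloc = np.floor(quota).astype(int)
    rem = n - alloc.sum()
    order = np.argsort(-(quota - alloc))
    alloc[order[:rem]] += 1
    keep = []
    for lab, k in zip(labels, alloc):
        members = np.flatnonzero(strata == lab)
        k = min(k, members.size)
        keep.append(rng.choice(members, size=k, replace=False))
    keep = np.sort(np.concatenate(keep))
    return cell_ids[keep]


def minmax_normalize(a: np.ndarray) -> np.ndarray:
    """(a - min) / (max - min); errors on a constant vector."""
    a = np.asarray(a, dtype=float)
    lo, hi = np.min(a), np.max(a)
    if hi == lo:
        raise ValueError("min-max normalization undefined for a constant vector")
    return (a - lo) / (hi - lo)


def _kernel(u: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return np.exp(-0.5 * u**2) / math.sqrt(2 * math.pi)
    if kernel == "cauchy":
        return 1.0 / (math.pi * (1.0 + u**2))
    raise ValueError(f"kernel must be one of {KERNELS}")


def kde_density(points: np.ndarray, x: np.ndarray | float | None = None,
                kernel: str = "gaussian", h: float = 0.5) -> np.ndarray:
    """Kernel density estimate f(x) = (1/n) sum K_h(x - x_i), K_h(u)=K(u/h)/h.

    The bandwidth must satisfy 0.3 < h < 0.7, the stated operating range of
    the estimator. If ``x`` is None the density is evaluated at the sample
    points themselves.
    """
    lo, hi = H_BOUNDS
    if not lo < h < hi:
        raise ValueError(f"bandwidth h={h} outside the required open interval "
                         f"({lo}, {hi})")
    points = np.asarray(points, dtype=float)
    if x is None:
        x = points
    x = np.atleast_1d(np.asarray(x, dtype=float))
    u = (x[:, None] - points[None, :]) / h
    f = _kernel(u, kernel).sum(axis=1) / (points.size * h)
    return f


# ---------------------------------------------------------------------------
# Trajectory construction
# ---------------------------------------------------------------------------

def build_interaction_trajectory(m: CountMatrix, spec: LigandReceptorSpec,
                                 clusters, kernel: str = "gaussian",
                                 h: float = 0.5, q: float = 0.95
                                 ) -> TrajectoryScores:
    """Score and align all cells along the ligand->receptor trajectory.

    Candidate senders (cells whose cluster is not a target label) get
    ``A_exp`` = mean scaled ligand-gene expression and ``A_eff`` = SVD
    enrichment of the induction program; receivers analogously with the
    receptor and activation programs. Both scores are outlier-filtered
    (central 95% mass), min-max normalized within side, combined into a
    signed position (negative pole = strongest senders) and locally averaged
    with kernel weights in ``n_exp``.
    """
    if m.layer != "scaled":
        raise ValueError("build_interaction_trajectory expects the scaled layer")
    spec.validate_against(m.gene_ids)
    clusters = np.asarray(clusters)
    if clusters.shape[0] != m.n_cells:
        raise ValueError("clusters must label every cell")

    is_receiver = np.isin(clusters, list(spec.target_cell_labels))
    side = np.where(is_receiver, "receiver", "ligand").astype(object)

    n = m.n_cells
    A_exp = np.full(n, np.nan)
    A_eff = np.full(n, np.nan)
    retained = np.zeros(n, dtype=bool)
    n_exp = np.full(n, np.nan)
    n_eff = np.full(n, np.nan)
    f_hat = np.full(n, np.nan)
    position = np.full(n, np.nan)
    rank = np.zeros(n, dtype=int)

    for side_name, mask, expr_gs, eff_gs, sign in (
            ("ligand", ~is_receiver, spec.ligand_genes, spec.induction_genes, -1.0),
            ("receiver", is_receiver, spec.receptor_genes, spec.activation_genes, +1.0)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"no cells on the {side_name} side")
        sub = m.subset_cells(idx)
        expr_idx = sub.gene_index(expr_gs.genes)
        A_exp[idx] = sub.values[expr_idx].mean(axis=0)
        A_eff[idx] = svd_enrichment(sub, eff_gs)

        # The 95% rejection robustifies the distribution fit: min-max bounds
        # and the KDE come from the retained central mass, and every
        # cell's score is then normalized with those bounds (clipped to
        # [0, 1]), so outlying but genuine candidates are not discarded.
        keep = quantile_filter(A_exp[idx], q) & quantile_filter(A_eff[idx], q)
        kept = idx[keep]
        retained[kept] = True

        def _fit_minmax(values, inliers):
            lo, hi = values[inliers].min(), values[inliers].max()
            if hi == lo:
                raise ValueError(
                    "min-max normalization undefined for a constant vector")
            return np.clip((values - lo) / (hi - lo), 0.0, 1.0)

        n_exp[idx] = _fit_minmax(A_exp[idx], keep)
        n_eff[idx] = _fit_minmax(A_eff[idx], keep)
        f_hat[idx] = kde_density(n_exp[kept], x=n_exp[idx], kernel=kernel, h=h)

        raw_pos = sign * (n_exp[idx] + n_eff[idx]) / 2.0
        # KDE-weighted local averaging along the n_exp axis, fitted on the
        # retained cells.
        w = _kernel((n_exp[idx][:, None] - n_exp[kept][None, :]) / h, kernel)
        position[idx] = (w @ raw_pos[keep]) / w.sum(axis=1)
        order = np.argsort(-np.abs(position[idx]), kind="stable")
        r = np.empty(idx.size, dtype=int)
        r[order] = np.arange(1, idx.size + 1)
        rank[idx] = r

    return TrajectoryScores(
        cell_ids=m.cell_ids.copy(), side=side, clusters=clusters.copy(),
        A_exp=A_exp, A_eff=A_eff, retained=retained, n_exp=n_exp, n_eff=n_eff,
        f_hat=f_hat, trajectory_position=position, rank=rank,
        kernel=kernel, h=h)


# ---------------------------------------------------------------------------
# Pair selection
# ---------------------------------------------------------------------------

def select_connected(ts: TrajectoryScores, ci: float = 0.70,
                     top_fraction: float = 0.01) -> ConnectedPairs:
    """Form eligible sender x receiver pairs and flag the top-scoring ones.

    Eligibility requires a retained cell to be at or above the ``ci``
    empirical percentile of both ``n_exp`` and ``n_eff`` within its side.
    Pair score is the product of the four normalized scores; the connected
    flag marks the top ``top_fraction`` of pair scores (deterministic
    tie-break by cell ids).
    """
    if not 0 < ci < 1:
        raise ValueError("ci must be in (0, 1)")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")

    eligible = {}
    for side in ("ligand", "receiver"):
        inlier = (ts.side == side) & ts.retained
        if not inlier.any():
            eligible[side] = np.array([], dtype=int)
            continue
        # Thresholds from the retained central mass; applied to every cell
        # on the side (high outliers stay eligible).
        thr_exp = np.quantile(ts.n_exp[inlier], ci)
        thr_eff = np.quantile(ts.n_eff[inlier], ci)
        side_mask = (ts.side == side) & ~np.isnan(ts.n_exp)
        eligible[side] = np.flatnonzero(
            side_mask & (ts.n_exp >= thr_exp) & (ts.n_eff >= thr_eff))

    L, R = eligible["ligand"], eligible["receiver"]
    thresholds = {"ci": ci, "top_fraction": top_fraction, "max_dist_um": None}
    if L.size == 0 or R.size == 0:
        empty = pd.DataFrame(columns=[
            "ligand_cell", "receiver_cell", "pair_score", "connected",
            "distance_um", "status"])
        return ConnectedPairs(empty, thresholds)

    li, ri = np.meshgrid(L, R, indexing="ij")
    li, ri = li.ravel(), ri.ravel()
    score = (ts.n_exp[li] * ts.n_eff[li] * ts.n_exp[ri] * ts.n_eff[ri])
    df = pd.DataFrame({
        "ligand_cell": ts.cell_ids[li],
        "receiver_cell": ts.cell_ids[ri],
        "ligand_cluster": ts.clusters[li],
        "receiver_cluster": ts.clusters[ri],
        "pair_score": score,
        "distance_um": np.nan,
        "status": "retained",
    })
    n_top = max(1, int(math.ceil(top_fraction * len(df))))
    order = np.lexsort((df["receiver_cell"].astype(str),
                        df["ligand_cell"].astype(str),
                        -df["pair_score"].to_numpy()))
    connected = np.zeros(len(df), dtype=bool)
    connected[order[:n_top]] = True
    df["connected"] = connected
    return ConnectedPairs(df, thresholds)


# ---------------------------------------------------------------------------
# Spatial plausibility
# ---------------------------------------------------------------------------

def signature_spot_positions(grid: SpatialGrid, signatures: dict,
                             top_k: int = 5) -> dict:
    """Putative physical position per cluster: enrichment-weighted centroid
    of its signature's ``top_k`` highest-scoring spots.

    With few cells per spot the identity of the top spots carries
    substantial sampling noise, so centroids of broad territories move by
    on the order of a spot pitch between replicates; at legacy-ST pitch
    (200 um) a 150 um threshold on centroid distance is therefore a
    conservative, near same-spot colocation requirement.
    """
    from .spatial import score_spots

    coords = grid.coords_um()
    positions = {}
    for label, gs in signatures.items():
        try:
            scores = score_spots(grid, gs)
        except ValueError:
            positions[label] = None
            continue
        order = np.argsort(-scores, kind="stable")[:top_k]
        w = scores[order]
        if w.sum() <= 0:
            positions[label] = None
            continue
        positions[label] = (coords[order] * w[:, None]).sum(axis=0) / w.sum()
    return positions


def spatial_proximity_filter(pairs: ConnectedPairs, grid: SpatialGrid,
                             signatures: dict, max_dist_um: float = 150.0
                             ) -> ConnectedPairs:
    """Exclude pairs whose putative partner distance exceeds ``max_dist_um``.

    ``signatures`` maps cluster label -> GeneSet; each cell inherits the
    centroid position of its cluster signature. Cells whose signature scores
    no spot are marked ``unmapped`` and retained with a warning.
    """
    if grid.pitch_um is None or grid.pitch_um <= 0:
        raise ValueError("grid lacks physical (um) coordinates")
    df = pairs.pairs.copy()
    if df.empty:
        return ConnectedPairs(df, {**pairs.thresholds, "max_dist_um": max_dist_um})
    positions = signature_spot_positions(grid, signatures)

    def pos_of(label):
        return positions.get(label)

    dist = np.full(len(df), np.nan)
    status = np.array(["retained"] * len(df), dtype=object)
    lp = df["ligand_cluster"].map(pos_of)
    rp = df["receiver_cluster"].map(pos_of)
    unmapped = lp.isna() | rp.isna()
    if unmapped.any():
        warnings.warn(f"{int(unmapped.sum())} pairs could not be mapped to "
                      "spots; retained as 'unmapped'")
        status[unmapped.to_numpy()] = "unmapped"
    ok = ~unmapped.to_numpy()
    if ok.any():
        lxy = np.vstack(lp[ok].to_numpy())
        rxy = np.vstack(rp[ok].to_numpy())
        d = np.linalg.norm(lxy - rxy, axis=1)
        dist[ok] = d
        status[np.flatnonzero(ok)[d > max_dist_um]] = "excluded"
    df["distance_um"] = dist
    df["status"] = status
    return ConnectedPairs(df, {**pairs.thresholds, "max_dist_um": max_dist_um})


# ---------------------------------------------------------------------------
# Cluster-level summary
# ---------------------------------------------------------------------------

def nfcn_score(pairs: ConnectedPairs, clusters: dict | None = None,
               labels=None) -> NFCNScoreMatrix:
    """Cluster x cluster NFCN score: mean pair score of retained connected
    pairs, normalized to [0, 1] by the matrix maximum.

    ``labels``, when given, fixes the matrix axes (sorted unique labels) so
    an empty pair set yields an all-zero matrix rather than an empty one.
    """
    df = pairs.retained_connected()
    if clusters is not None:
        df = df.copy()
        df["ligand_cluster"] = df["ligand_cell"].map(clusters)
        df["receiver_cluster"] = df["receiver_cell"].map(clusters)
    axis = (sorted(set(map(str, np.asarray(labels, dtype=object))))
            if labels is not None else None)
    if df.empty:
        if axis is None:
            z = pd.DataFrame(dtype=float)
            return NFCNScoreMatrix(z, z.copy())
        z = pd.DataFrame(0.0, index=axis, columns=axis)
        return NFCNScoreMatrix(z, z.astype(int))
    grouped = df.groupby(["ligand_cluster", "receiver_cluster"])["pair_score"]
    mean = grouped.mean().unstack(fill_value=0.0)
    count = grouped.size().unstack(fill_value=0)
    if axis is not None:
        mean = mean.reindex(index=axis, columns=axis, fill_value=0.0)
        count = count.reindex(index=axis, columns=axis, fill_value=0)
    top = mean.to_numpy().max()
    if top > 0:
        mean = mean / top
    return NFCNScoreMatrix(mean, count)


# ---------------------------------------------------------------------------
# Evaluation against planted truth
# ---------------------------------------------------------------------------

def pair_precision_recall(pairs: ConnectedPairs, truth_pairs: set,
                          subset: str = "emitted") -> tuple:
    """Precision and recall of emitted (or flagged) pairs vs a truth pair set."""
    df = pairs.pairs if subset == "emitted" else pairs.retained_connected()
    if df.empty:
        return 0.0, 0.0
    predicted = set(zip(df["ligand_cell"], df["receiver_cell"]))
    tp = len(predicted & truth_pairs)
    precision = tp / len(predicted)
    recall = tp / len(truth_pairs) if truth_pairs else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# End-to-end estimator
# ---------------------------------------------------------------------------

class NFCN(BaseEstimator):
    """End-to-end NFCN estimator over a scaled expression matrix.

    Parameters mirror the published procedure: downsampling to
    ``n_representative`` cells, Gaussian or Cauchy kernel with bandwidth in
    (0.3, 0.7), 95% quantile outlier rejection, eligibility above the 70th
    percentile on both axes, top 1% connected flag, and an optional 150 um
    spatial plausibility filter.

    Fitted attributes: ``trajectory_``, ``pairs_``, ``score_matrix_``.
    """

    def __init__(self, spec: LigandReceptorSpec | None = None,
                 n_representative: int = 3000, kernel: str = "gaussian",
                 h: float = 0.5, q: float = 0.95, ci: float = 0.70,
                 top_fraction: float = 0.01, max_dist_um: float = 150.0,
                 random_state: int = 0):
        self.spec = spec
        self.n_representative = n_representative
        self.kernel = kernel
        self.h = h
        self.q = q
        self.ci = ci
        self.top_fraction = top_fraction
        self.max_dist_um = max_dist_um
        self.random_state = random_state

    def fit(self, m: CountMatrix, clusters, grid: SpatialGrid | None = None,
            signatures: dict | None = None):
        clusters = np.asarray(clusters)
        keep_ids = downsample_representative(
            m.cell_ids, clusters, n=self.n_representative,
            seed=self.random_state)
        keep = np.isin(m.cell_ids, keep_ids)
        sub = m.subset_cells(keep)
        self.trajectory_ = build_interaction_trajectory(
            sub, self.spec, clusters[keep], kernel=self.kernel, h=self.h,
            q=self.q)
        self.pairs_ = select_connected(self.trajectory_, ci=self.ci,
                                       top_fraction=self.top_fraction)
        if grid is not None and signatures is not None:
            self.pairs_ = spatial_proximity_filter(
                self.pairs_, grid, signatures, max_dist_um=self.max_dist_um)
        self.score_matrix_ = nfcn_score(self.pairs_, labels=clusters)
        return self
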