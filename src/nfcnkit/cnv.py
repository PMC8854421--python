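"""Expression-based copy-number estimation.

Large-scale chromosomal gains and losses leave a footprint in expression:
averaging relative (reference-subtracted) expression over a 100-gene window
ordered along the genome smooths single-gene variability and exposes the
shift. The reference is a set of non-malignant cells (the study used 400
CD8+ T cells); relative values are clamped to +-2.6 before smoothing so
single highly expressed genes cannot dominate a window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix, GenomicAnnotation

DEFAULT_WINDOW = 100
DEFAULT_CLIP = 2.6
DEFAULT_N_REFERENCE = 400


@dataclass
class CNVMatrix:
    """Cell x genomic-window smoothed relative expression."""

    values: np.ndarray  # cell x window
    cell_ids: np.ndarray
    window_genes: np.ndarray  # gene id per window (ordered)
    window_chrom: np.ndarray  # chromosome per window
    params: dict

    def chromosome_mean(self, chrom: str) -> np.ndarray:
        mask = self.window_chrom == chrom
        return self.values[:, mask].mean(axis=1)


def call_reference_cells(cell_ids, predicate_mask, n: int = DEFAULT_N_REFERENCE,
                         seed: int = 0) -> np.ndarray:
    """Sample up to ``n`` reference cells from those passing the predicate."""
    cell_ids = np.asarray(cell_ids)
    mask = np.asarray(predicate_mask, dtype=bool)
    passing = cell_ids[mask]
    if passing.size == 0:
        raise ValueError("no cells pass the reference predicate")
    if passing.size < n:
        warnings.warn(f"only {passing.size} cells pass the predicate; "
                      "using all of them")
        return passing.copy()
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(passing, size=n, replace=False))


def clip_relative_expression(m: CountMatrix, reference_cells,
                             clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Reference-centered expression, clamped to [-clip, clip].

    Per gene, subtract the mean over the reference cells from every cell's
    log-normalized value, then clamp.
    """
    if m.layer != "lognorm":
        raise ValueError("clip_relative_expression expects the lognorm layer")
    ref_mask = np.isin(m.cell_ids, np.asarray(reference_cells))
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        raise ValueError("reference cells not found in the matrix")
    if n_ref < 10:
        raise ValueError(f"need at least 10 reference cells, got {n_ref}")
    rel = m.values - m.values[:, ref_mask].mean(axis=1, keepdims=True)
    return np.clip(rel, -clip, clip)


def moving_average_cnv(rel: np.ndarray, gene_ids, ann: GenomicAnnotation,
                       cell_ids=None, window: int = DEFAULT_WINDOW,
                       recenter: bool = True) -> CNVMatrix:
    """Centered moving average of relative expression along the genome.

    Genes are sorted by (chromosome order, start, gene id); windows are
    centered, shrink at chromosome edges and never span chromosomes. With
    ``recenter`` the per-cell median is subtracted afterwards, removing
    ploidy-wide offsets.
    """
    rel = np.asarray(rel, dtype=float)
    gene_ids = np.asarray(gene_ids, dtype=object)
    if cell_ids is None:
        cell_ids = np.array([f"C{i:05d}" for i in range(rel.shape[1])],
                            dtype=object)
    tab = ann.table.set_index("gene")
    annotated = np.isin(gene_ids, tab.index.to_numpy())
    if not annotated.any():
        raise ValueError("no annotated genes")
    rank = ann.chrom_rank()
    meta = pd.DataFrame({
        "gene": gene_ids[annotated],
        "row": np.flatnonzero(annotated),
    })
    meta["chrom"] = tab.loc[meta["gene"], "chrom"].to_numpy()
    meta["start"] = tab.loc[meta["gene"], "start"].to_numpy()
    meta["crank"] = meta["chrom"].map(rank)
    meta = meta.sort_values(["crank", "start", "gene"], kind="stable")

    half = window // 2
    blocks, chrom_out, gene_out = [], [], []
    for chrom, grp in meta.groupby("chrom", sort=False):
        rows = grp["row"].to_numpy()
        X = rel[rows]  # genes_on_chrom x cells
        g = len(rows)
        csum = np.vstack([np.zeros((1, X.shape[1])), np.cumsum(X, axis=0)])
        idx = np.arange(g)
        if g <= window:
            # short chromosome: every window covers all its genes
            lo = np.zeros(g, dtype=int)
            hi = np.full(g, g)
        else:
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + (window - half), g)  # [lo, hi), length <= window
        sums = csum[hi] - csum[lo]
        blocks.append(sums / (hi - lo)[:, None])
        chrom_out.extend([chrom] * g)
        gene_out.extend(grp["gene"].tolist())
    smoothed = np.vstack(blocks).T  # cells x windows
    if recenter:
        smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)
    return CNVMatrix(
        values=smoothed, cell_ids=np.asarray(cell_ids, dtype=object),
        window_genes=np.asarray(gene_out, dtype=object),
        window_chrom=np.asarray(chrom_out, dtype=object),
        params={"window": window, "clip": None, "recenter": recenter},
    )


class CNVProfiler(BaseEstimator, TransformerMixin):
    """Fit/transform wrapper: reference profile from ``fit``, CNV windows from
    ``transform``.

    ``fit`` expects the log-normalized gene x cell matrix restricted to
    reference cells is not required -- pass the full matrix plus the
    reference cell ids; ``transform`` returns the cell x window CNV matrix.
    """

    def __init__(self, annotation: GenomicAnnotation | None = None,
                 window: int = DEFAULT_WINDOW, clip: float = DEFAULT_CLIP,
                 recenter: bool = True):
        self.annotation = annotation
        self.window = window
        self.clip = clip
        self.recenter = recenter

    def fit(self, m: CountMatrix, reference_cells=None):
        if m.layer != "lognorm":
            raise ValueError("CNVProfiler expects the lognorm layer")
        ref_mask = np.isin(m.cell_ids, np.asarray(reference_cells))
        if ref_mask.sum() < 10:
            raise ValueError("need at least 10 reference cells")
        self.reference_mean_ = m.values[:, ref_mask].mean(axis=1)
        self.gene_ids_ = m.gene_ids.copy()
        return self

    def transform(self, m: CountMatrix) -> CNVMatrix:
        if not np.array_equal(m.gene_ids, self.gene_ids_):
            raise ValueError("gene ids differ from the fitted matrix")
        rel = np.clip(m.values - self.reference_mean_[:, None],
                      -self.clip, self.clip)
        out = moving_average_cnv(rel, m.gene_ids, self.annotation,
                                 cell_ids=m.cell_ids, window=self.window,
                                 recenter=self.recenter)
        out.params["clip"] = self.clip
        return out


def estimate_cnv(m: CountMatrix, ann: GenomicAnnotation, reference_cells,
                 window: int = DEFAULT_WINDOW, clip: float = DEFAULT_CLIP,
                 recenter: bool = True) -> CNVMatrix:
    """One-shot CNV profile: clip relative expression, then moving average."""
    rel = clip_relative_expression(m, reference_cells, clip=clip)
    out = moving_average_cnv(rel, m.gene_ids, ann, cell_ids=m.cell_ids,
                             window=window, recenter=recenter)
    out.params["clip"] = clip
    return out
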