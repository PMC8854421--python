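"""Core in-memory containers shared across the pipeline.

The pipeline's native orientation is gene x cell (rows are genes), matching
the convention of expression matrices written as MTX + genes.tsv +
barcodes.tsv. Estimator classes that follow the scikit-learn protocol take
the transposed cell x gene view; converters are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LAYERS = ("raw", "lognorm", "scaled")


@dataclass
class CountMatrix:
    """Gene x cell expression matrix with a layer tag.

    Parameters
    ----------
    values
        2-D array, genes in rows, cells in columns. The ``raw`` layer is
        integer-valued; ``lognorm`` holds CP10K log1p values; ``scaled``
        holds per-gene z-scored residuals.
    gene_ids, cell_ids
        Row / column identifiers, unique.
    layer
        One of ``raw``, ``lognorm``, ``scaled``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.layer == "raw":
            if np.any(self.values < 0):
                raise ValueError("raw layer must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.gene_ids.copy(),
                           self.cell_ids.copy(), self.layer)

    def with_values(self, values: np.ndarray, layer: str | None = None) -> "CountMatrix":
        return CountMatrix(values, self.gene_ids, self.cell_ids,
                           layer if layer is not None else self.layer)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of ``genes`` that are present, preserving query order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids, self.layer)

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        return CountMatrix(self.values[:, mask_or_idx], self.gene_ids,
                           self.cell_ids[mask_or_idx], self.layer)

    def to_anndata(self):
        """Cell x gene :class:`anndata.AnnData` view (optional dependency)."""
        import anndata

        return anndata.AnnData(
            X=self.values.T.copy(),
            obs=pd.DataFrame(index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.gene_ids)),
        )

    @classmethod
    def from_anndata(cls, adata, layer: str = "raw") -> "CountMatrix":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return cls(np.asarray(X).T, np.asarray(adata.var_names, dtype=object),
                   np.asarray(adata.obs_names, dtype=object), layer)


@dataclass(frozen=True)
class GeneSet:
    """Named list of gene identifiers (signature, program, pathway)."""

    name: str
    genes: tuple

    def __init__(self, name: str, genes: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(dict.fromkeys(genes)))

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, gene_ids: Iterable[str]) -> "GeneSet":
        present = set(gene_ids)
        return GeneSet(self.name, [g for g in self.genes if g in present])


@dataclass
class SpatialGrid:
    """Rectangular spot array with physical coordinates and spot x gene counts."""

    spot_ids: np.ndarray
    rows: np.ndarray  # 0-based array row per spot
    cols: np.ndarray  # 0-based array column per spot
    pitch_um: float
    counts: np.ndarray  # spot x gene
    gene_ids: np.ndarray
    n_rows: int
    n_cols: int
    region: np.ndarray | None = None  # per-spot region label (ground truth)
    members: list | None = None  # per-spot list of member cell indices

    def __post_init__(self) -> None:
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        coords = set(zip(self.rows.tolist(), self.cols.tolist()))
        if len(coords) != len(self.spot_ids):
            raise ValueError("spot array coordinates must be unique")
        if self.rows.max(initial=-1) >= self.n_rows or self.cols.max(initial=-1) >= self.n_cols:
            raise ValueError("grid extent does not cover all spots")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def x_um(self) -> np.ndarray:
        return self.cols * self.pitch_um

    @property
    def y_um(self) -> np.ndarray:
        return self.rows * self.pitch_um

    def coords_um(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class GenomicAnnotation:
    """Gene -> (chromosome, start, end) with an explicit chromosome order.

    Coordinates are 0-based, half-open [start, end).
    """

    table: pd.DataFrame  # columns: gene, chrom, start, end
    chrom_order: tuple = ()

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("duplicate gene entries in annotation")
        if (self.table["start"] < 0).any():
            raise ValueError("starts must be >= 0")
        if not self.chrom_order:
            self.chrom_order = tuple(pd.unique(self.table["chrom"]))

    def chrom_rank(self) -> Mapping[str, int]:
        return {c: i for i, c in enumerate(self.chrom_order)}

    def genes_on(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "gene"].to_numpy()
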