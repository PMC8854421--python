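"""Readers and writers for the standard interchange formats.

MTX (Matrix Market sparse triplets) + genes.tsv/barcodes.tsv for expression,
TSV for annotations, spot coordinates and result tables, GMT for gene-set
collections, BED-like TSV for gene positions, JSON for ground-truth
sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import CountMatrix, GeneSet, GenomicAnnotation, SpatialGrid


# -- expression matrices ----------------------------------------------------

def write_counts_mtx(counts: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(outdir / "matrix.mtx"),
                     sparse.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)


def read_counts_mtx(indir, layer: str = "raw") -> CountMatrix:
    indir = Path(indir)
    mat = scipy_io.mmread(str(indir / "matrix.mtx"))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    vals = np.asarray(mat.todense())
    if layer == "raw":
        vals = vals.astype(np.int64)
    return CountMatrix(vals, genes, cells, layer)


def write_counts_tsv(counts: CountMatrix, path) -> None:
    pd.DataFrame(counts.values, index=counts.gene_ids,
                 columns=counts.cell_ids).to_csv(path, sep="\t")


def read_counts_tsv(path, layer: str = "raw") -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), df.index.to_numpy(),
                       df.columns.to_numpy(), layer)


# -- gene sets (GMT) --------------------------------------------------------

def write_gmt(gene_sets, path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


def read_gmt(path) -> list:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[2:]))
    return sets


# -- gene positions (BED-like) ---------------------------------------------

def write_gene_positions(ann: GenomicAnnotation, path) -> None:
    ann.table[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_gene_positions(path) -> GenomicAnnotation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"])
    return GenomicAnnotation(df[["gene", "chrom", "start", "end"]])


# -- spot tables ------------------------------------------------------------

def write_spot_table(grid: SpatialGrid, path) -> None:
    pd.DataFrame({
        "spot": grid.spot_ids, "row": grid.rows, "col": grid.cols,
        "x_um": grid.x_um, "y_um": grid.y_um,
        "region": grid.region if grid.region is not None else "",
    }).to_csv(path, sep="\t", index=False)


def write_cell_annotation(cell_ids, clusters, batches, path) -> None:
    pd.DataFrame({"cell": cell_ids, "cluster": clusters,
                  "batch": batches}).to_csv(path, sep="\t", index=False)


# -- ground truth sidecar ---------------------------------------------------

def write_ground_truth(truth, path) -> None:
    payload = {
        "cell_labels": list(map(str, truth.cell_labels)),
        "batches": [int(b) for b in truth.batches],
        "exhaustion": [float(e) for e in truth.exhaustion],
        "programs": {name: list(gs.genes)
                     for name, gs in truth.program_gene_members.items()},
        "spot_regions": {str(k): str(v) for k, v in truth.spot_regions.items()},
        "spot_composition": {str(k): {str(t): float(f) for t, f in comp.items()}
                             for k, comp in truth.spot_composition.items()},
        "cnv_truth": {str(k): float(v) for k, v in truth.cnv_truth.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_synthetic_dataset(outdir, counts, truth, grid=None, ann=None) -> None:
    """Write a complete synthetic dataset in the standard layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(counts, outdir)
    write_cell_annotation(counts.cell_ids, truth.cell_labels, truth.batches,
                          outdir / "cells.tsv")
    write_gmt(truth.program_gene_members.values(), outdir / "programs.gmt")
    write_ground_truth(truth, outdir / "truth.json")
    if grid is not None:
        write_spot_table(grid, outdir / "spots.tsv")
        pd.DataFrame(grid.counts, index=grid.spot_ids,
                     columns=grid.gene_ids).to_csv(outdir / "spot_counts.tsv",
                                                   sep="\t")
    if ann is not None:
        write_gene_positions(ann, outdir / "genes.bed")
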