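"""Single-cell spatial expression matrices from masks + spot tables.

Sub-micron spatial transcriptomics platforms report expression as points:
(gene, x, y, count) rows in a tab-delimited GEM table. Given an instance
mask over the same pixel frame, each point is assigned the mask label at
its pixel, counts are aggregated per (cell, gene), and the result is a
sparse cells × genes matrix with per-cell centroid and area metadata —
an open, diffable stand-in (MatrixMarket + TSV sidecars) for the binary
cell-level expression formats used downstream.

Points falling on background (label 0) are excluded, never redistributed;
total counts are conserved: matrix total + background total = input total.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .morphkit import extract_cell_records

_GENE_SYNONYMS = ("geneid", "gene", "gene_id", "genename")
_COUNT_SYNONYMS = ("midcount", "umicount", "count", "midcounts", "umi_count")


@dataclass
class ExpressionPointTable:
    """Validated spot-level expression points in the mask pixel frame."""

    points: pd.DataFrame  # columns: gene, x, y, count
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["line", "reason"])
    )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_count(self) -> int:
        return int(self.points["count"].sum())


@dataclass
class CellExpressionMatrix:
    """Sparse cells × genes counts with per-cell geometry metadata."""

    counts: sparse.csr_matrix  # shape (n_cells, n_genes), integer
    cells: pd.DataFrame  # columns: label, centroid_x, centroid_y, area_px2
    genes: list[str]

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def _resolve_column(columns: list[str], synonyms: tuple[str, ...], what: str) -> str:
    lower = {c.lower(): c for c in columns}
    for syn in synonyms:
        if syn in lower:
            return lower[syn]
    raise ValueError(f"GEM file is missing a {what} column (looked for {synonyms})")


def read_gem(path: str, one_based: bool = False) -> ExpressionPointTable:
    """Parse a GEM (or gzipped GEM) table of expression points.

    Accepts MIDCount/UMICount/count and geneID/gene header synonyms and
    skips leading ``#`` comment lines. Rows with non-integer coordinates,
    negative coordinates, or count < 1 are rejected and reported with
    their 1-based file line numbers. ``one_based`` shifts coordinates
    down by 1 for exports whose pixel origin is (1, 1).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = fh.readlines()
    n_comments = 0
    while n_comments < len(lines) and lines[n_comments].startswith("#"):
        n_comments += 1
    if n_comments >= len(lines):
        raise ValueError(f"{path}: empty GEM file")
    header = lines[n_comments].rstrip("\n").split("\t")
    gene_col = _resolve_column(header, _GENE_SYNONYMS, "gene id")
    count_col = _resolve_column(header, _COUNT_SYNONYMS, "count")
    x_col = _resolve_column(header, ("x",), "x coordinate")
    y_col = _resolve_column(header, ("y",), "y coordinate")

    records, rejected = [], []
    for offset, line in enumerate(lines[n_comments + 1 :]):
        lineno = n_comments + 2 + offset  # 1-based file line
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        row = dict(zip(header, fields))
        gene = row.get(gene_col, "")
        try:
            x = int(row[x_col])
            y = int(row[y_col])
            count = int(row[count_col])
        except (KeyError, ValueError):
            rejected.append((lineno, "non-integer coordinate or count"))
            continue
        if one_based:
            x -= 1
            y -= 1
        if not gene:
            rejected.append((lineno, "empty gene id"))
        elif count < 1:
            rejected.append((lineno, f"count {count} < 1"))
        elif x < 0 or y < 0:
            rejected.append((lineno, f"negative coordinate ({x}, {y})"))
        else:
            records.append((gene, x, y, count))
    points = pd.DataFrame(records, columns=["gene", "x", "y", "count"])
    rej = pd.DataFrame(rejected, columns=["line", "reason"])
    return ExpressionPointTable(points=points, rejected=rej)


def write_gem(points: pd.DataFrame, path: str) -> None:
    """Write points (gene, x, y, count) as a GEM table (gzip if *.gz)."""
    out = points.rename(columns={"gene": "geneID", "count": "MIDCount"})
    out = out[["geneID", "x", "y", "MIDCount"]]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def assign_points(
    points: ExpressionPointTable | pd.DataFrame, mask: np.ndarray
) -> pd.DataFrame:
    """Exact pixel-lookup assignment of points to mask labels.

    Returns the point table with an added ``cell_label`` column (0 =
    background). Out-of-bounds points are dropped with a report; more
    than 50% out of bounds aborts with a coordinate-frame hint.
    """
    if mask is None:
        raise ValueError("mask is required")
    mask = np.asarray(mask)
    frame = points.points if isinstance(points, ExpressionPointTable) else points
    h, w = mask.shape
    x = frame["x"].to_numpy(dtype=np.int64)
    y = frame["y"].to_numpy(dtype=np.int64)
    in_bounds = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    n_oob = int((~in_bounds).sum())
    if len(frame) and n_oob > 0.5 * len(frame):
        raise ValueError(
            f"{n_oob}/{len(frame)} points fall outside the {h}×{w} mask — "
            "likely a coordinate-frame mismatch (check --one-based or the mask crop)"
        )
    out = frame.loc[in_bounds].copy()
    out["cell_label"] = mask[y[in_bounds], x[in_bounds]]
    return out


def aggregate_expression(
    assigned: pd.DataFrame,
    mask: np.ndarray,
    keep_empty_cells: bool = True,
) -> CellExpressionMatrix:
    """Sum point counts per (cell, gene) into a sparse matrix.

    Background points (label 0) are excluded. Every mask label gets a row
    (zero rows included unless ``keep_empty_cells`` is False) so the cell
    metadata table is complete; centroids and areas come from
    connected-region analysis of the mask.
    """
    records = extract_cell_records(np.asarray(mask))
    meta = pd.DataFrame(
        {
            "label": [r.label for r in records],
            "centroid_x": [r.centroid[0] for r in records],
            "centroid_y": [r.centroid[1] for r in records],
            "area_px2": [r.area_px2 for r in records],
        }
    )
    in_cell = assigned[assigned["cell_label"] > 0]
    genes = sorted(in_cell["gene"].unique().tolist())
    if not keep_empty_cells:
        occupied = set(in_cell["cell_label"].unique().tolist())
        meta = meta[meta["label"].isin(occupied)].reset_index(drop=True)
    cell_index = {lab: i for i, lab in enumerate(meta["label"].tolist())}
    gene_index = {g: j for j, g in enumerate(genes)}
    rows = in_cell["cell_label"].map(cell_index).to_numpy(dtype=np.int64) \
        if len(in_cell) else np.zeros(0, dtype=np.int64)
    cols = in_cell["gene"].map(gene_index).to_numpy(dtype=np.int64) \
        if len(in_cell) else np.zeros(0, dtype=np.int64)
    data = in_cell["count"].to_numpy(dtype=np.int64)
    counts = sparse.coo_matrix(
        (data, (rows, cols)), shape=(len(meta), len(genes)), dtype=np.int64
    ).tocsr()
    counts.sum_duplicates()
    return CellExpressionMatrix(counts=counts, cells=meta.reset_index(drop=True), genes=genes)


def bin_expression(
    points: ExpressionPointTable | pd.DataFrame,
    mask: np.ndarray,
    keep_empty_cells: bool = True,
) -> CellExpressionMatrix:
    """assign_points → aggregate_expression in one call."""
    assigned = assign_points(points, mask)
    return aggregate_expression(assigned, mask, keep_empty_cells=keep_empty_cells)


def write_cell_matrix(matrix: CellExpressionMatrix, out_dir: str) -> None:
    """Write matrix.mtx + genes.tsv + cells.tsv into ``out_dir``.

    MatrixMarket coordinate format with integer field; round-trips
    losslessly through :func:`read_cell_matrix`.
    """
    os.makedirs(out_dir, exist_ok=True)
    spio.mmwrite(
        os.path.join(out_dir, "matrix.mtx"),
        matrix.counts.tocoo(),
        field="integer",
    )
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("gene\n")
        for g in matrix.genes:
            fh.write(f"{g}\n")
    matrix.cells.to_csv(os.path.join(out_dir, "cells.tsv"), sep="\t", index=False)


def read_cell_matrix(out_dir: str) -> CellExpressionMatrix:
    counts = sparse.csr_matrix(spio.mmread(os.path.join(out_dir, "matrix.mtx")))
    counts = counts.astype(np.int64)
    genes = pd.read_csv(os.path.join(out_dir, "genes.tsv"), sep="\t")["gene"].tolist()
    genes = [str(g) for g in genes]
    cells = pd.read_csv(os.path.join(out_dir, "cells.tsv"), sep="\t")
    return CellExpressionMatrix(counts=counts, cells=cells, genes=genes)


def to_anndata(matrix: CellExpressionMatrix):
    """Optional AnnData export (cells as obs with centroid/area, genes as var)."""
    import anndata as ad

    obs = matrix.cells.copy()
    obs.index = obs["label"].astype(str)
    var = pd.DataFrame(index=pd.Index(matrix.genes, name="gene"))
    return ad.AnnData(X=matrix.counts.copy(), obs=obs, var=var)
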