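"""Morphological and spatial quantification of instance masks.

Six metrics summarise how cells are arranged in an image and how clearly
they are imaged. With N cells of areas A_i, perimeters P_i and centroids
(x_i, y_i):

* mean_distance — mean over cells of the nearest-neighbour centroid
  distance d_min,i (cell dispersion; pixels).
* compactness — (mean_distance)² / Ā with Ā the mean cell area
  (nearest-neighbour spacing normalised to cell size; dimensionless).
* density — N / A_total with A_total the full image pixel count
  (cells per pixel).
* distribution — coefficient of variation σ/μ of the local densities
  3 / D_i,3, where D_i,3 is the sum of cell i's three smallest neighbour
  distances (0 for a perfectly uniform layout, larger for clustering).
* shape_complexity — mean(P²) / mean(A); exactly 16 for squares under the
  pixel-edge perimeter convention used here, larger for ragged boundaries.
* edge_contrast — mean Sobel gradient magnitude on cell boundary pixels
  divided by that on background pixels (≫1 for crisp boundaries, →1 as
  boundaries fade into background noise).

Perimeter is counted as boundary pixel edges (an s×s square has perimeter
4s exactly), which keeps closed-form checks exact. Metrics that need a
minimum number of cells (2 for distances, 4 for distribution) or a usable
background are reported as None with a reason flag, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist, squareform
from skimage.color import rgb2gray


@dataclass(frozen=True)
class CellRecord:
    """Per-cell geometry from connected-region analysis."""

    label: int
    area_px2: float
    perimeter_px: float
    centroid: tuple[float, float]  # (x, y) = (col, row)


@dataclass(frozen=True)
class MorphoReport:
    n_cells: int
    mean_distance: float | None
    compactness: float | None
    density: float | None
    distribution: float | None
    shape_complexity: float | None
    edge_contrast: float | None
    flags: dict = field(default_factory=dict)

    def as_row(self, image_id: str = "") -> dict:
        return {
            "image_id": image_id,
            "n_cells": self.n_cells,
            "mean_distance": self.mean_distance,
            "compactness": self.compactness,
            "density": self.density,
            "distribution": self.distribution,
            "shape_complexity": self.shape_complexity,
            "edge_contrast": self.edge_contrast,
            "flags": ";".join(f"{k}:{v}" for k, v in self.flags.items()),
        }


def extract_cell_records(mask: np.ndarray) -> list[CellRecord]:
    """Connected-region analysis: area, pixel-edge perimeter, centroid per label.

    Area is the pixel count. Perimeter counts pixel edges between a cell
    and any non-cell pixel (image border included), so an s×s square has
    perimeter 4s and a single pixel has perimeter 4. Centroid is the mean
    pixel coordinate, returned as (x, y) = (column, row).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []

    # Boundary-edge count per label: compare each pixel with its 4-neighbours,
    # padding with -1 so the image border always counts as "different".
    padded = np.pad(mask.astype(np.int64), 1, constant_values=-1)
    core = padded[1:-1, 1:-1]
    diff_edges = np.zeros_like(core)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr,
                       1 + dc : padded.shape[1] - 1 + dc]
        diff_edges += (neigh != core).astype(np.int64)

    idx = np.arange(labels.max() + 1)
    areas = ndimage.sum_labels(np.ones_like(mask), mask, idx)
    perims = ndimage.sum_labels(np.where(mask > 0, diff_edges, 0), mask, idx)
    rows, cols = np.indices(mask.shape)
    cy = ndimage.sum_labels(rows, mask, idx)
    cx = ndimage.sum_labels(cols, mask, idx)

    records = []
    for lab in labels.tolist():
        a = float(areas[lab])
        records.append(
            CellRecord(
                label=int(lab),
                area_px2=a,
                perimeter_px=float(perims[lab]),
                centroid=(float(cx[lab] / a), float(cy[lab] / a)),
            )
        )
    return records


def _nearest_neighbor_distances(records: list[CellRecord]) -> np.ndarray:
    pts = np.array([r.centroid for r in records])
    dmat = squareform(pdist(pts))
    np.fill_diagonal(dmat, np.inf)
    return dmat


def spatial_metrics(
    records: list[CellRecord], image_area_px: float
) -> tuple[float | None, float | None, float | None, float | None, dict]:
    """(mean_distance, compactness, density, distribution, flags).

    Distances need ≥2 cells; distribution needs ≥4 (three nearest
    neighbours per cell). σ_local is the population standard deviation.
    """
    if image_area_px <= 0:
        raise ValueError("image_area_px must be positive")
    n = len(records)
    flags: dict = {}
    density = n / image_area_px if n else None
    if n == 0:
        flags["density"] = "no cells"
    mean_distance = compactness = distribution = None
    if n < 2:
        flags["mean_distance"] = flags["compactness"] = "need >= 2 cells"
        flags["distribution"] = "need >= 4 cells"
    else:
        dmat = _nearest_neighbor_distances(records)
        d_min = dmat.min(axis=1)
        mean_distance = float(d_min.mean())
        mean_area = float(np.mean([r.area_px2 for r in records]))
        compactness = mean_distance**2 / mean_area
        if n < 4:
            flags["distribution"] = "need >= 4 cells"
        else:
            d_sorted = np.sort(dmat, axis=1)
            d3 = d_sorted[:, :3].sum(axis=1)  # three smallest neighbour distances
            local = 3.0 / d3
            mu = local.mean()
            sigma = local.std()  # population sd (divisor N)
            distribution = float(sigma / mu)
    return mean_distance, compactness, density, distribution, flags


def shape_complexity(records: list[CellRecord]) -> tuple[float | None, dict]:
    """mean(P²)/mean(A) over cells; None with a reason when there are no cells.

    Note this is the ratio of means, not the mean of per-cell ratios —
    large cells weigh in through both numerator and denominator.
    """
    if not records:
        return None, {"shape_complexity": "no cells"}
    p2 = np.mean([r.perimeter_px**2 for r in records])
    a = np.mean([r.area_px2 for r in records])
    return float(p2 / a), {}


def sobel_gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """3×3 Sobel gradient magnitude with mirror-padded borders.

    RGB input is converted to luminance grayscale first.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = rgb2gray(image)
    gx = ndimage.sobel(image, axis=1, mode="mirror")
    gy = ndimage.sobel(image, axis=0, mode="mirror")
    return np.hypot(gx, gy)


def edge_contrast(
    image: np.ndarray, mask: np.ndarray, exclusion_px: int = 2
) -> tuple[float | None, dict]:
    """Mean boundary-pixel gradient over mean background gradient.

    Edge pixels are cell pixels with at least one 4-neighbour of a
    different label (including background). Background pixels are label-0
    pixels farther than ``exclusion_px`` (city-block) from any cell, so
    cell-edge gradients do not bleed into the background estimate.
    """
    mask = np.asarray(mask)
    if np.asarray(image).shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if mask.max() == 0:
        return None, {"edge_contrast": "no cells"}
    grad = sobel_gradient_magnitude(image)

    # Edge pixels: 4-neighbour label change; out-of-image counts as same.
    padded = np.pad(mask.astype(np.int64), 1, mode="edge")
    core = padded[1:-1, 1:-1]
    edge = np.zeros(mask.shape, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr,
                       1 + dc : padded.shape[1] - 1 + dc]
        edge |= neigh != core
    edge &= mask > 0

    dist = ndimage.distance_transform_cdt(mask == 0, metric="taxicab")
    background = (mask == 0) & (dist > exclusion_px)
    if not background.any():
        return None, {"edge_contrast": "no background beyond exclusion ring"}
    mu_cell = float(grad[edge].mean())
    mu_bg = float(grad[background].mean())
    if mu_bg == 0.0:
        return None, {"edge_contrast": "uniform background (zero gradient)"}
    return mu_cell / mu_bg, {}


def morpho_report(image: np.ndarray | None, mask: np.ndarray) -> MorphoReport:
    """Bundle all six metrics for one (image, mask) pair.

    ``image`` may be None when only mask-derived metrics are wanted; edge
    contrast is then flagged as unavailable.
    """
    mask = np.asarray(mask)
    records = extract_cell_records(mask)
    area_total = float(mask.shape[0] * mask.shape[1])
    mean_d, compact, density, distrib, flags = spatial_metrics(records, area_total)
    sc, sc_flags = shape_complexity(records)
    flags.update(sc_flags)
    if image is None:
        ec, ec_flags = None, {"edge_contrast": "no intensity image supplied"}
    else:
        ec, ec_flags = edge_contrast(image, mask)
    flags.update(ec_flags)
    return MorphoReport(
        n_cells=len(records),
        mean_distance=mean_d,
        compactness=compact,
        density=density,
        distribution=distrib,
        shape_complexity=sc,
        edge_contrast=ec,
        flags=flags,
    )
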