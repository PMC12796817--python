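"""Synthetic microscopy fixtures: paired image, instance mask, expression.

Two regimes bracket the conditions that make nuclei segmentation easy or
hard in real tissue:

* ``dense_lowcontrast`` emulates tightly packed, weakly stained regions
  (hippocampus-like): small inter-cell gaps on a small canvas and a
  foreground/background intensity gap of only 3× the noise sd.
* ``sparse_highcontrast`` emulates sparse, crisply stained regions: large
  gaps on a larger canvas and a 10× noise-sd intensity gap.

Cells are ellipses placed by rejection sampling (non-overlapping unless
requested), labelled 1..N in placement order; expression points are
sampled uniformly inside each cell. Everything is driven by one seed per
artifact, so fixtures are bit-reproducible. The generator makes no
attempt at photorealistic staining texture — it plants known geometry and
counts so that evaluation, morphometric and binning code can be checked
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .cellbin import ExpressionPointTable
from .morphkit import CellRecord, extract_cell_records

Regime = Literal["dense_lowcontrast", "sparse_highcontrast"]

#: Per-regime defaults: canvas edge, inter-cell gap (px) and the
#: foreground/background intensity gap as a multiple of noise_sd.
_REGIME_DEFAULTS = {
    "dense_lowcontrast": {"size": 256, "min_gap": 2, "contrast_mult": 3.0},
    "sparse_highcontrast": {"size": 384, "min_gap": 10, "contrast_mult": 10.0},
}


@dataclass(frozen=True)
class SynthParams:
    regime: Regime = "sparse_highcontrast"
    height: int = 0  # 0 → regime default canvas
    width: int = 0
    n_cells: int = 60
    radius_range: tuple[int, int] = (4, 8)
    overlap_allowed: bool = False
    noise_sd: float = 8.0
    n_genes: int = 20
    points_per_cell: int = 15
    background_point_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.regime not in _REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}")
        defaults = _REGIME_DEFAULTS[self.regime]
        if self.height == 0:
            object.__setattr__(self, "height", defaults["size"])
        if self.width == 0:
            object.__setattr__(self, "width", defaults["size"])
        if min(self.height, self.width) < 64:
            raise ValueError("canvas must be at least 64×64")
        if self.radius_range[0] < 2 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must satisfy 2 <= min <= max")
        if self.n_cells < 0 or self.noise_sd < 0:
            raise ValueError("n_cells and noise_sd must be non-negative")
        if not 0 <= self.background_point_fraction <= 1:
            raise ValueError("background_point_fraction must be in [0, 1]")


def _ellipse_pixels(
    cy: float, cx: float, ry: float, rx: float, theta: float, h: int, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer pixel coordinates inside a rotated ellipse, clipped to canvas."""
    rmax = int(np.ceil(max(ry, rx))) + 1
    r0, r1 = max(0, int(cy) - rmax), min(h, int(cy) + rmax + 1)
    c0, c1 = max(0, int(cx) - rmax), min(w, int(cx) + rmax + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    return rr[inside], cc[inside]


def generate_tissue(
    params: SynthParams,
) -> tuple[np.ndarray, np.ndarray, list[CellRecord]]:
    """Place elliptical cells and render (image, mask, planted records).

    Placement is rejection sampling against a dilated occupancy mask;
    after 200×n_cells failed draws an error advises reducing the count.
    The image is background level + intensity gap on cells + clipped
    Gaussian noise, uint8. Planted records are the exact geometry of the
    rendered mask (connected-region analysis of the ground truth).
    """
    defaults = _REGIME_DEFAULTS[params.regime]
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)
    mask = np.zeros((h, w), dtype=np.int32)
    min_gap = defaults["min_gap"]

    placed = 0
    attempts = 0
    max_attempts = max(1, 200 * params.n_cells)
    while placed < params.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {params.n_cells} cells on {h}×{w} after "
                f"{max_attempts} attempts — reduce n_cells or radius_range"
            )
        attempts += 1
        rlo, rhi = params.radius_range
        ry = rng.uniform(rlo, rhi)
        rx = rng.uniform(rlo, rhi)
        theta = rng.uniform(0, np.pi)
        margin = max(ry, rx) + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        rr, cc = _ellipse_pixels(cy, cx, ry, rx, theta, h, w)
        if rr.size == 0:
            continue
        if not params.overlap_allowed:
            # keep a min_gap empty ring: test a slightly inflated ellipse
            gr, gc = _ellipse_pixels(
                cy, cx, ry + min_gap, rx + min_gap, theta, h, w
            )
            if np.any(mask[gr, gc] > 0):
                continue
        placed += 1
        mask[rr, cc] = placed

    noise_sd = params.noise_sd
    gap = defaults["contrast_mult"] * noise_sd if noise_sd > 0 else 60.0
    background_level = 40.0
    image = np.full((h, w), background_level, dtype=np.float64)
    image[mask > 0] += gap
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=(h, w))
    image = np.clip(image, 0, 255).astype(np.uint8)
    return image, mask, extract_cell_records(mask)


@dataclass(frozen=True)
class PerturbationLedger:
    """Record of the edits applied to a mask (for evaluation cross-checks)."""

    dropped: tuple[int, ...] = field(default=())
    split: tuple[int, ...] = field(default=())
    shifted: tuple[int, ...] = field(default=())
    shift_px: int = 0


def perturb_mask(
    mask: np.ndarray,
    drop_fraction: float = 0.0,
    split_fraction: float = 0.0,
    shift_px: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, PerturbationLedger]:
    """Apply controlled segmentation errors to a ground-truth mask.

    Drops ⌊drop_fraction·N⌋ cells (known false negatives), splits
    ⌊split_fraction·N⌋ of the remaining cells in two along their longer
    centroid axis (known over-segmentation), then shifts the remaining
    cells by a random offset of at most ``shift_px`` per axis.
    """
    for frac in (drop_fraction, split_fraction):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must be in [0, 1]")
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    n = labels.size
    rng = np.random.default_rng(seed)

    n_drop = int(np.floor(drop_fraction * n))
    dropped = rng.choice(labels, size=n_drop, replace=False) if n_drop else np.array([], dtype=labels.dtype)
    remaining = np.setdiff1d(labels, dropped)

    n_split = min(int(np.floor(split_fraction * n)), remaining.size)
    to_split = rng.choice(remaining, size=n_split, replace=False) if n_split else np.array([], dtype=labels.dtype)

    out = mask.copy()
    for lab in dropped:
        out[out == lab] = 0
    next_label = int(labels.max()) + 1 if n else 1
    for lab in to_split:
        rr, cc = np.nonzero(out == lab)
        # split across the longer spatial extent through the centroid
        if rr.max() - rr.min() >= cc.max() - cc.min():
            half = rr > rr.mean()
        else:
            half = cc > cc.mean()
        if half.all() or not half.any():
            continue  # degenerate single-row cell: leave intact
        out[rr[half], cc[half]] = next_label
        next_label += 1

    shifted: list[int] = []
    if shift_px > 0:
        base = out.copy()
        out = np.zeros_like(base)
        h, w = base.shape
        for lab in np.unique(base)[1:] if base.max() else []:
            dy = int(rng.integers(-shift_px, shift_px + 1))
            dx = int(rng.integers(-shift_px, shift_px + 1))
            rr, cc = np.nonzero(base == lab)
            rr2, cc2 = rr + dy, cc + dx
            keep = (rr2 >= 0) & (rr2 < h) & (cc2 >= 0) & (cc2 < w)
            out[rr2[keep], cc2[keep]] = lab
            if dy or dx:
                shifted.append(int(lab))

    ledger = PerturbationLedger(
        dropped=tuple(int(x) for x in np.sort(dropped)),
        split=tuple(int(x) for x in np.sort(to_split)),
        shifted=tuple(shifted),
        shift_px=shift_px,
    )
    return out, ledger


def generate_expression(
    mask: np.ndarray, params: SynthParams
) -> tuple[ExpressionPointTable, pd.DataFrame]:
    """Sample expression points inside cells (plus background noise points).

    Each cell receives ``points_per_cell`` points uniform over its pixels
    with genes drawn from a fixed seeded categorical distribution; count
    per point is 1 + Poisson(0.5). Background points are added at
    ``background_point_fraction`` of the in-cell point count. Returns the
    point table and the planted per-cell totals for conservation checks.
    """
    if params.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mask = np.asarray(mask)
    rng = np.random.default_rng(params.seed + 1)  # independent stream from tissue
    gene_names = [f"gene{g:03d}" for g in range(params.n_genes)]
    # mildly skewed gene frequencies, fixed by seed
    probs = rng.dirichlet(np.full(params.n_genes, 2.0))

    labels = np.unique(mask)
    labels = labels[labels > 0]
    rows = []
    planted = []
    for lab in labels.tolist():
        rr, cc = np.nonzero(mask == lab)
        pick = rng.integers(0, rr.size, size=params.points_per_cell)
        gene_idx = rng.choice(params.n_genes, size=params.points_per_cell, p=probs)
        counts = 1 + rng.poisson(0.5, size=params.points_per_cell)
        for k in range(params.points_per_cell):
            rows.append(
                (gene_names[gene_idx[k]], int(cc[pick[k]]), int(rr[pick[k]]), int(counts[k]))
            )
        planted.append((int(lab), int(counts.sum())))

    n_cell_points = len(rows)
    n_bg = int(np.floor(params.background_point_fraction * n_cell_points))
    bg_rr, bg_cc = np.nonzero(mask == 0)
    if n_bg and bg_rr.size:
        pick = rng.integers(0, bg_rr.size, size=n_bg)
        gene_idx = rng.choice(params.n_genes, size=n_bg, p=probs)
        counts = 1 + rng.poisson(0.5, size=n_bg)
        for k in range(n_bg):
            rows.append(
                (gene_names[gene_idx[k]], int(bg_cc[pick[k]]), int(bg_rr[pick[k]]), int(counts[k]))
            )

    points = pd.DataFrame(rows, columns=["gene", "x", "y", "count"])
    planted_totals = pd.DataFrame(planted, columns=["label", "total_count"])
    return ExpressionPointTable(points=points), planted_totals


def regime_params(regime: Regime, n_cells: int = 60, seed: int = 0, **kw) -> SynthParams:
    """Convenience constructor using the regime's default canvas."""
    return SynthParams(regime=regime, n_cells=n_cells, seed=seed, **kw)
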