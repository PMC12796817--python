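"""Training-set preparation from whole-tissue images.

Whole-slide microscopy images are far too large to annotate or train on
directly, so small-sample fine-tuning workflows crop fixed-size patches
(256×256 for most segmentation backbones, 512×512 for some), mirror-pad
patches up to a larger canvas when a backbone demands it, convert binary
(semantic) annotation masks into instance masks with one unique integer id
per cell, and record everything in a plain-text trainset list that splits
patches into train/validation groups per sample (SN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from skimage.measure import label as _cc_label


@dataclass(frozen=True)
class TrainsetEntry:
    """One annotated patch in the trainset list."""

    image_path: str
    mask_path: str
    sn: str
    split: str  # "train" or "val"


@dataclass(frozen=True)
class Patch:
    """A cropped window plus its origin in whole-slide coordinates (row, col, 0-based)."""

    image: np.ndarray
    mask: np.ndarray | None
    row: int
    col: int


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3) or (image.ndim == 3 and image.shape[2] != 3):
        raise ValueError(f"image must be H×W or H×W×3, got shape {image.shape}")
    return image


def crop_patches(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    *,
    patch_size: int,
    stride: int,
) -> Iterator[Patch]:
    """Tile an image (and optionally its mask) into ``patch_size`` windows.

    Windows start at every multiple of ``stride``; partial windows at the
    right/bottom edges are dropped so every patch is exactly
    ``patch_size`` × ``patch_size`` and traceable to slide coordinates.
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    if patch_size <= 0 or stride <= 0:
        raise ValueError("patch_size and stride must be positive")
    if patch_size > min(h, w):
        raise ValueError(
            f"patch_size {patch_size} exceeds image extent {h}×{w}"
        )
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape[:2] != (h, w):
            raise ValueError(
                f"mask shape {mask.shape} does not match image {h}×{w}"
            )
    for r in range(0, h - patch_size + 1, stride):
        for c in range(0, w - patch_size + 1, stride):
            yield Patch(
                image=image[r : r + patch_size, c : c + patch_size],
                mask=None
                if mask is None
                else mask[r : r + patch_size, c : c + patch_size],
                row=r,
                col=c,
            )


def stitch_patches(
    patches: Sequence[Patch], height: int, width: int
) -> np.ndarray:
    """Reassemble non-overlapping patches onto an H×W canvas (inverse of
    :func:`crop_patches` with stride == patch_size on a divisible image)."""
    if not patches:
        raise ValueError("no patches to stitch")
    first = patches[0].image
    shape = (height, width) + first.shape[2:]
    out = np.zeros(shape, dtype=first.dtype)
    for p in patches:
        ph, pw = p.image.shape[:2]
        out[p.row : p.row + ph, p.col : p.col + pw] = p.image
    return out


def reflect_pad(patch: np.ndarray, target_size: int, *, is_mask: bool = False) -> np.ndarray:
    """Grow a patch to ``target_size`` square by mirror reflection.

    Reflection excludes the border pixel (``[1,2,3]`` padded by 2 gives
    ``[3,2,1,2,3,2,1]``), so cell morphology at the seam is preserved
    without a doubled boundary row. For instance masks, every reflected
    copy of a cell is a new object, so mirrored components are relabelled
    with fresh ids; the central region keeps the original labels.
    """
    patch = np.asarray(patch)
    h, w = patch.shape[:2]
    if target_size < max(h, w):
        raise ValueError(f"target_size {target_size} smaller than patch {h}×{w}")
    pad_h, pad_w = target_size - h, target_size - w
    if pad_h % 2 or pad_w % 2:
        raise ValueError(
            "padding must be symmetric: target_size minus patch extent must be even"
        )
    ph, pw = pad_h // 2, pad_w // 2
    if ph >= h or pw >= w:
        raise ValueError("padding amount exceeds patch extent; reflection undefined")
    pad_width = [(ph, ph), (pw, pw)] + [(0, 0)] * (patch.ndim - 2)
    out = np.pad(patch, pad_width, mode="reflect")
    if not is_mask:
        return out
    # Relabel mirrored copies: zero the central (original) region, then give
    # each connected same-label region in the padding a fresh id.
    out = out.astype(np.int64, copy=True)
    ring = out.copy()
    ring[ph : ph + h, pw : pw + w] = 0
    if ring.max() > 0:
        copies = _cc_label(ring, background=0, connectivity=2)
        next_label = int(patch.max()) + 1
        out[ph : ph + h, pw : pw + w] = patch
        sel = copies > 0
        out[sel] = copies[sel] + next_label - 1
    return out


def semantic_to_instance(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Convert a binary foreground mask into an instance mask.

    Each connected foreground component becomes one cell; labels are
    1..K in raster order of each component's first pixel. Connectivity 4
    joins edge neighbours only; 8 also joins diagonals (the default for
    nuclei blobs).
    """
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), [0, 1])
    if bad.size:
        raise ValueError(f"semantic mask must be binary; found values {bad.tolist()}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = _cc_label(mask, background=0, connectivity=1 if connectivity == 4 else 2)
    return _relabel_raster_order(lab)


def _relabel_raster_order(lab: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by raster order of each component's first pixel."""
    flat = lab.ravel()
    first = {}
    for idx in np.flatnonzero(flat):
        v = flat[idx]
        if v not in first:
            first[v] = idx
    order = sorted(first, key=first.get)
    remap = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[lab]


def build_trainset_list(
    entries: Sequence[tuple[str, str, str]],
    val_fraction: float,
    seed: int,
) -> list[TrainsetEntry]:
    """Split annotated patches into train/val proportionally within each SN.

    The validation count per SN group is round-half-up(group size ×
    ``val_fraction``); assignment is a deterministic seeded shuffle within
    the group, so reruns with the same seed reproduce the split exactly.
    """
    if not entries:
        raise ValueError("entry list is empty")
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must be in [0, 1)")
    image_paths = [e[0] for e in entries]
    if len(set(image_paths)) != len(image_paths):
        dupes = sorted({p for p in image_paths if image_paths.count(p) > 1})
        raise ValueError(f"duplicate image paths: {dupes}")

    groups: dict[str, list[tuple[str, str, str]]] = {}
    for e in entries:
        groups.setdefault(e[2], []).append(e)

    rng = np.random.default_rng(seed)
    out: list[TrainsetEntry] = []
    for sn in sorted(groups):
        group = groups[sn]
        n_val = int(np.floor(len(group) * val_fraction + 0.5))  # round half up
        order = rng.permutation(len(group))
        val_idx = set(order[:n_val].tolist())
        for i, (img, msk, _) in enumerate(group):
            out.append(
                TrainsetEntry(img, msk, sn, "val" if i in val_idx else "train")
            )
    return out


def write_trainset_list(entries: Sequence[TrainsetEntry], path: str) -> None:
    """Write the trainset list as TSV with header image_path/mask_path/sn/split."""
    with open(path, "w") as fh:
        fh.write("image_path\tmask_path\tsn\tsplit\n")
        for e in entries:
            fh.write(f"{e.image_path}\t{e.mask_path}\t{e.sn}\t{e.split}\n")


def read_trainset_list(path: str) -> list[TrainsetEntry]:
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["image_path", "mask_path", "sn", "split"]
        if header != expected:
            raise ValueError(f"bad trainset header {header}, expected {expected}")
        for line in fh:
            if not line.strip():
                continue
            img, msk, sn, split = line.rstrip("\n").split("\t")
            entries.append(TrainsetEntry(img, msk, sn, split))
    return entries
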