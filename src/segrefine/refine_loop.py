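"""Iterative segmentation refinement against a pluggable segmenter.

The workflow is: segment with a base model → evaluate against annotated
held-out patches → if below target, add the next batch of annotated
patches and re-fit — always from the *original* base state, never from a
previous fine-tuned checkpoint, so repeated rounds cannot compound drift
(catastrophic forgetting) — then re-evaluate, until a target F1 or a
round limit is reached.

Deep-learning backends (Cellpose, StarDist, U-Net) plug in through the
:class:`SegmenterAdapter` contract; the package ships a classical
threshold + watershed baseline so the loop runs end-to-end with no
training framework installed.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.segmentation import watershed

from . import evalkit
from .evalkit import MetricReport


@dataclass
class SegmenterAdapter:
    """Pluggable segmenter: a name, a base state, and two pure functions.

    ``segment(image, state)`` produces an instance mask and must be
    deterministic for a given state. ``finetune(entries, base_state)``
    returns a new state fitted on (image, mask) training pairs; callers
    must always pass the original ``base_state``, never a previously
    fine-tuned state.
    """

    name: str
    segment: Callable[[np.ndarray, Any], np.ndarray]
    finetune: Callable[[Sequence[tuple[np.ndarray, np.ndarray]], Any], Any]
    base_state: Any = None


@dataclass(frozen=True)
class RefineConfig:
    iou_threshold: float = 0.5
    target_f1: float = 0.85
    max_rounds: int = 5
    patch_size: int = 256
    output_dir: str = "runs"
    seed: int = 0

    def __post_init__(self):
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if not 0 < self.target_f1 <= 1:
            raise ValueError("target_f1 must be in (0, 1]")


def baseline_segment(
    image: np.ndarray, min_area_px: int = 9, min_peak_distance: int = 5
) -> np.ndarray:
    """Classical nuclei instance segmentation: Otsu + distance watershed.

    The global threshold maximises between-class variance of the
    intensity histogram (Otsu); foreground is split into instances by
    watershed from distance-transform peaks; components below
    ``min_area_px`` are removed. Fully deterministic, no learned state.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 3:
        image = rgb2gray(image)
    smoothed = ndimage.gaussian_filter(image, sigma=1.0)
    if np.ptp(smoothed) == 0:
        return np.zeros(image.shape, dtype=np.int32)
    thresh = threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any():
        return np.zeros(image.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        lab = _cc_label(fg, background=0, connectivity=2)
    else:
        lab = watershed(-dist, markers=markers, mask=fg)
    # prune small fragments and compact labels
    labels, counts = np.unique(lab[lab > 0], return_counts=True)
    small = set(labels[counts < min_area_px].tolist())
    if small:
        lab = np.where(np.isin(lab, list(small)), 0, lab)
    out = np.zeros_like(lab, dtype=np.int32)
    for new, old in enumerate(np.unique(lab[lab > 0]).tolist(), start=1):
        out[lab == old] = new
    return out


def _baseline_finetune(
    entries: Sequence[tuple[np.ndarray, np.ndarray]], base_state: dict | None
) -> dict:
    """Fit the baseline's size prior from annotated masks.

    Estimates min_area_px as half the 10th-percentile annotated cell area
    — the only knob a threshold/watershed segmenter can learn from labels.
    """
    areas = []
    for _, mask in entries:
        labels, counts = np.unique(mask[mask > 0], return_counts=True)
        areas.extend(counts.tolist())
    state = dict(base_state or {})
    if areas:
        state["min_area_px"] = max(1, int(0.5 * np.percentile(areas, 10)))
    return state


def make_baseline_adapter(min_area_px: int = 9) -> SegmenterAdapter:
    """The shipped classical adapter wrapping :func:`baseline_segment`."""
    base_state = {"min_area_px": min_area_px}
    return SegmenterAdapter(
        name="baseline",
        segment=lambda image, state: baseline_segment(
            image, min_area_px=(state or base_state)["min_area_px"]
        ),
        finetune=_baseline_finetune,
        base_state=base_state,
    )


@dataclass
class RoundLog:
    round_index: int
    trainset_size: int
    report_mean_f1: float
    reports: list[MetricReport] = field(default_factory=list)
    failed: bool = False


def _timestamped_dir(root: str) -> str:
    stamp = _dt.datetime.now().strftime("run_%Y%m%d_%H%M%S")
    path = os.path.join(root, stamp)
    suffix = 0
    while os.path.exists(path):
        suffix += 1
        path = os.path.join(root, f"{stamp}_{suffix}")
    os.makedirs(path)
    return path


def run_refinement_cycle(
    adapter: SegmenterAdapter,
    pool: Sequence[Sequence[tuple[np.ndarray, np.ndarray]]],
    test_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    config: RefineConfig,
) -> tuple[list[RoundLog], str]:
    """Run the refine loop: add a pool batch, re-fit from base, evaluate.

    ``pool`` is a sequence of batches of (image, mask) annotated patches;
    round r trains on the union of batches 0..r (cumulative, monotone).
    Each fit starts from ``adapter.base_state``. Evaluation is the mean
    F1 over the held-out ``test_pairs`` at ``config.iou_threshold``.
    Stops when mean F1 reaches ``config.target_f1`` or after
    ``config.max_rounds`` rounds; every round is appended to
    ``rounds.jsonl`` and a metrics CSV inside a fresh timestamped run
    directory, whose path is returned.
    """
    if not pool:
        raise ValueError("annotation pool is empty")
    if not test_pairs:
        raise ValueError("no held-out test pairs")
    run_dir = _timestamped_dir(config.output_dir)
    logs: list[RoundLog] = []
    cumulative: list[tuple[np.ndarray, np.ndarray]] = []
    jsonl_path = os.path.join(run_dir, "rounds.jsonl")

    n_rounds = min(config.max_rounds, len(pool))
    for r in range(n_rounds):
        cumulative = list(cumulative) + list(pool[r])
        try:
            state = adapter.finetune(cumulative, adapter.base_state)
            reports = [
                evalkit.evaluate_masks(
                    gt_mask,
                    adapter.segment(img, state),
                    config.iou_threshold,
                    image_id=f"test{i}",
                )
                for i, (img, gt_mask) in enumerate(test_pairs)
            ]
        except Exception as exc:  # noqa: BLE001 - adapter failure contract
            log = RoundLog(r, len(cumulative), float("nan"), [], failed=True)
            logs.append(log)
            with open(jsonl_path, "a") as fh:
                fh.write(json.dumps({"round": r, "failed": True, "error": str(exc)}) + "\n")
            break
        mean_f1 = float(np.mean([rep.f1 for rep in reports]))
        log = RoundLog(r, len(cumulative), mean_f1, reports)
        logs.append(log)
        evalkit.reports_to_frame(reports).to_csv(
            os.path.join(run_dir, f"metrics_round{r}.csv"), index=False
        )
        with open(os.path.join(run_dir, f"trainset_round{r}.txt"), "w") as fh:
            fh.write(f"{len(cumulative)} patches\n")
        with open(jsonl_path, "a") as fh:
            fh.write(
                json.dumps(
                    {
                        "round": r,
                        "trainset_size": len(cumulative),
                        "mean_f1": mean_f1,
                        "adapter": adapter.name,
                    }
                )
                + "\n"
            )
        if mean_f1 >= config.target_f1:
            break
    return logs, run_dir
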