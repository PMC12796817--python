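"""Instance-level segmentation evaluation.

A predicted cell counts as a true positive when it can be matched
one-to-one to a ground-truth cell with intersection-over-union (IoU) at or
above a threshold (0.5 by default). From the matched counts TP, FP, FN the
five standard metrics follow:

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    F1 = 2 P R / (P + R)                Jaccard = TP / (TP + FP + FN)
    Dice = 2 TP / (2 TP + FP + FN)

F1 and Dice are algebraically identical at the instance level, and
Jaccard = Dice / (2 − Dice); both identities are exercised by the test
suite over an exhaustive count grid.

Matching is greedy in descending IoU. For IoU strictly above 0.5 any cell
can overlap at most one partner that much, so the greedy matching is the
optimal one-to-one assignment; at exactly 0.5 ties are broken
deterministically by (gt_label, pred_label).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as srio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int
    matches: tuple[tuple[int, int, float], ...] = field(default=())

    def __post_init__(self):
        if self.tp != len(self.matches):
            raise ValueError("tp must equal the number of matches")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    image_id: str
    counts: MatchCounts
    precision: float
    recall: float
    f1: float
    jaccard: float
    dice: float


def iou_matrix(gt: np.ndarray, pred: np.ndarray) -> pd.DataFrame:
    """All overlapping (gt, pred) instance pairs with pixel IoU.

    Returns a frame with columns gt_label, pred_label, intersection_px,
    union_px, iou — one row per label pair whose pixel sets intersect.
    """
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    gt = gt.ravel().astype(np.int64)
    pred = pred.ravel().astype(np.int64)

    gt_labels, gt_areas = np.unique(gt[gt > 0], return_counts=True)
    pred_labels, pred_areas = np.unique(pred[pred > 0], return_counts=True)
    gt_area = dict(zip(gt_labels.tolist(), gt_areas.tolist()))
    pred_area = dict(zip(pred_labels.tolist(), pred_areas.tolist()))

    both = (gt > 0) & (pred > 0)
    keys = gt[both] * (pred.max() + 1) + pred[both]
    pair_keys, inter = np.unique(keys, return_counts=True)
    g = pair_keys // (pred.max() + 1)
    p = pair_keys % (pred.max() + 1)

    rows = []
    for gi, pi, ix in zip(g.tolist(), p.tolist(), inter.tolist()):
        union = gt_area[gi] + pred_area[pi] - ix
        rows.append((gi, pi, ix, union, ix / union))
    return pd.DataFrame(
        rows, columns=["gt_label", "pred_label", "intersection_px", "union_px", "iou"]
    )


def match_instances(
    pairs: pd.DataFrame,
    n_gt: int,
    n_pred: int,
    threshold: float = 0.5,
) -> MatchCounts:
    """One-to-one greedy matching of overlap pairs at an IoU threshold.

    ``n_gt`` and ``n_pred`` are the total instance counts of the two masks
    (needed because unmatched instances never appear in ``pairs``).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cand = pairs[pairs["iou"] >= threshold]
    cand = cand.sort_values(
        by=["iou", "gt_label", "pred_label"], ascending=[False, True, True]
    )
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for row in cand.itertuples(index=False):
        if row.gt_label in used_gt or row.pred_label in used_pred:
            continue
        used_gt.add(row.gt_label)
        used_pred.add(row.pred_label)
        matches.append((int(row.gt_label), int(row.pred_label), float(row.iou)))
    tp = len(matches)
    return MatchCounts(tp=tp, fp=n_pred - tp, fn=n_gt - tp, matches=tuple(matches))


def compute_metrics(counts: MatchCounts, image_id: str = "") -> MetricReport:
    """The five instance metrics from TP/FP/FN.

    Degenerate cases: both masks empty → all metrics 1.0 (nothing to get
    wrong); one side empty → precision and recall 0, keeping every metric
    defined and bounded so batch aggregates never see NaN.
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        one = 1.0
        return MetricReport(image_id, counts, one, one, one, one, one)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jaccard = tp / (tp + fp + fn)
    dice = 2 * tp / (2 * tp + fp + fn)
    return MetricReport(image_id, counts, precision, recall, f1, jaccard, dice)


def evaluate_masks(
    gt: np.ndarray,
    pred: np.ndarray,
    threshold: float = 0.5,
    image_id: str = "",
) -> MetricReport:
    """Convenience: IoU table → matching → metrics for one mask pair."""
    pairs = iou_matrix(gt, pred)
    n_gt = int(np.unique(gt[gt > 0]).size)
    n_pred = int(np.unique(pred[pred > 0]).size)
    counts = match_instances(pairs, n_gt, n_pred, threshold)
    return compute_metrics(counts, image_id=image_id)


_METRIC_COLS = ["precision", "recall", "f1", "jaccard", "dice"]


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    rows = [
        {
            "image_id": r.image_id,
            "tp": r.counts.tp,
            "fp": r.counts.fp,
            "fn": r.counts.fn,
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
            "jaccard": r.jaccard,
            "dice": r.dice,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def summarize_reports(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Unweighted per-image mean, median and sd of each metric."""
    frame = reports_to_frame(reports)
    stats = frame[_METRIC_COLS].agg(["mean", "median", "std"])
    stats.insert(0, "statistic", stats.index)
    return stats.reset_index(drop=True)


def evaluate_batch(
    pairs: Sequence[tuple[str, str]],
    threshold: float = 0.5,
    out_csv: str | None = None,
    out_xlsx: str | None = None,
) -> tuple[list[MetricReport], pd.DataFrame, list[tuple[str, str]]]:
    """Evaluate (gt path, pred path) mask pairs from disk.

    Unreadable files are logged and skipped so one corrupt mask does not
    sink the batch; failures are returned as (path, reason) tuples.
    Writes per-image metrics to ``out_csv`` (plus ``*_summary.csv``) and
    optionally an xlsx workbook.
    """
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    reports: list[MetricReport] = []
    failures: list[tuple[str, str]] = []
    for gt_path, pred_path in pairs:
        try:
            gt = srio.read_mask(gt_path)
            pred = srio.read_mask(pred_path)
            image_id = os.path.splitext(os.path.basename(gt_path))[0]
            reports.append(evaluate_masks(gt, pred, threshold, image_id=image_id))
        except Exception as exc:  # noqa: BLE001 - per-file error contract
            logger.warning("skipping pair (%s, %s): %s", gt_path, pred_path, exc)
            failures.append((gt_path, str(exc)))
    summary = summarize_reports(reports) if reports else pd.DataFrame()
    if out_csv and reports:
        frame = reports_to_frame(reports)
        frame.to_csv(out_csv, index=False)
        root, ext = os.path.splitext(out_csv)
        summary.to_csv(f"{root}_summary{ext or '.csv'}", index=False)
    if out_xlsx and reports:
        with pd.ExcelWriter(out_xlsx) as writer:
            reports_to_frame(reports).to_excel(writer, sheet_name="per_image", index=False)
            summary.to_excel(writer, sheet_name="summary", index=False)
    return reports, summary, failures
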