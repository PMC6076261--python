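"""Recovery metrics: scoring pipeline output against generator ground truth."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .synthgen import GroundTruth
from .types import CellRecord, TandemPunctum

__all__ = [
    "match_cells",
    "punctum_count_f1",
    "evaluate_hcs",
    "tandem_class_accuracy",
]


def match_cells(gt: GroundTruth, cells: Sequence[CellRecord],
                max_dist_px: float = 10.0) -> dict[int, int]:
    """Greedy nearest-center matching of ground-truth cells to segmented cells.

    Returns {gt index -> cell list index}; unmatched ground-truth cells are
    simply absent from the mapping.
    """
    if not cells:
        return {}
    centers = np.array([c.center for c in cells])
    pairs = []
    for gi, gcell in enumerate(gt.cells):
        d = np.hypot(centers[:, 0] - gcell["center"][0],
                     centers[:, 1] - gcell["center"][1])
        for ci in np.flatnonzero(d <= max_dist_px):
            pairs.append((d[ci], gi, int(ci)))
    pairs.sort()
    mapping: dict[int, int] = {}
    used: set[int] = set()
    for _, gi, ci in pairs:
        if gi not in mapping and ci not in used:
            mapping[gi] = ci
            used.add(ci)
    return mapping


def punctum_count_f1(true_counts: Sequence[int],
                     pred_counts: Sequence[int]) -> float:
    """Count-based F1 over paired cells.

    Per cell, min(true, predicted) puncta count as true positives; the
    remainder as misses or false detections.
    """
    t = np.asarray(true_counts, dtype=float)
    p = np.asarray(pred_counts, dtype=float)
    tp = np.minimum(t, p).sum()
    if t.sum() == 0 and p.sum() == 0:
        return 1.0
    precision = tp / p.sum() if p.sum() else 0.0
    recall = tp / t.sum() if t.sum() else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_hcs(gt: GroundTruth, cells: Sequence[CellRecord],
                 min_puncta: int = 5) -> dict:
    """Score one quantified HCS field against its ground truth."""
    mapping = match_cells(gt, cells)
    live_correct = 0
    true_counts, pred_counts = [], []
    gt_live_counts = []
    for gi, gcell in enumerate(gt.cells):
        if gi not in mapping:
            continue
        cell = cells[mapping[gi]]
        truth_live = gcell["live"]
        if (cell.viability == "live") == truth_live:
            live_correct += 1
        if truth_live:
            n_true = sum(1 for p in gt.puncta if p["cell_index"] == gi)
            true_counts.append(n_true)
            pred_counts.append(cell.n_puncta)
            gt_live_counts.append(n_true)
    n_matched = len(mapping)
    frac_true = (np.mean([c >= min_puncta for c in gt_live_counts])
                 if gt_live_counts else np.nan)
    frac_pred = (np.mean([c >= min_puncta for c in pred_counts])
                 if pred_counts else np.nan)
    return {
        "n_gt_cells": len(gt.cells),
        "n_matched": n_matched,
        "match_rate": n_matched / len(gt.cells) if gt.cells else 1.0,
        "live_dead_accuracy": live_correct / n_matched if n_matched else np.nan,
        "count_f1": punctum_count_f1(true_counts, pred_counts),
        "frac_ge_threshold_true": float(frac_true),
        "frac_ge_threshold_pred": float(frac_pred),
        "n_live_scored": len(true_counts),
    }


def tandem_class_accuracy(gt: GroundTruth,
                          classified_red: Sequence[TandemPunctum],
                          max_dist_px: float = 3.0) -> float:
    """Fraction of detected red puncta whose class matches the nearest
    ground-truth punctum within ``max_dist_px``."""
    if not gt.puncta:
        return np.nan
    gcenters = np.array([p["center"] for p in gt.puncta])
    gclasses = [p["color_class"] for p in gt.puncta]
    correct = total = 0
    for p in classified_red:
        d = np.hypot(gcenters[:, 0] - p.centroid[0],
                     gcenters[:, 1] - p.centroid[1])
        j = int(np.argmin(d))
        if d[j] <= max_dist_px:
            total += 1
            if p.color_class == gclasses[j]:
                correct += 1
    return correct / total if total else np.nan
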