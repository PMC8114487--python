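"""Segmentation quality metrics against manually annotated nuclei.

Four metrics compare a predicted label map with ground-truth nucleus
annotations at the IMC pitch:

* **recall curve** — per ground-truth nucleus, the best IOU against any
  overlapping predicted object; recall = TP / (TP + FN) at IOU
  thresholds 0.5..1.0 in steps of 0.05 (every annotated nucleus is
  either TP or FN at each threshold);
* **split fraction** — the fraction of annotated nuclei overlapped by
  two or more predicted objects (each covering at least 20% of the
  annotation's area) among those with any overlap;
* **edge-intersection score** — how often predicted cell boundaries cut
  through annotated nuclei (lower is better);
* **fragmentation by group** — per externally supplied cell group
  (e.g. phenocluster), the proportion of predicted events that take part
  in a fragmentation event among those overlapping >= 20% of any
  annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import ScoreConfig
from .model import LabelMap

__all__ = [
    "MatchRecord",
    "ScoreReport",
    "iou",
    "match_events",
    "recall_curve",
    "split_fraction",
    "edge_intersection_score",
    "fragmentation_by_group",
    "score_prediction",
    "boundary_pixels",
]


@dataclass
class MatchRecord:
    gt_label: int
    best_pred_label: int | None
    best_iou: float
    overlapping_pred_labels_20pct: list[int] = field(default_factory=list)


@dataclass
class ScoreReport:
    records: list[MatchRecord]
    recall_by_threshold: dict[float, float]
    split_fraction: float
    edge_intersection_score: float
    per_group_fragmentation: dict = field(default_factory=dict)


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two congruent binary masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IOU undefined: both masks are empty")
    return np.count_nonzero(a & b) / union


def _pair_counts(gt: np.ndarray, pred: np.ndarray):
    """Sparse joint histogram of (gt label, pred label) pixel counts."""
    g = gt.ravel().astype(np.int64)
    p = pred.ravel().astype(np.int64)
    np_max = int(p.max()) + 1 if p.size else 1
    key = g * np_max + p
    uk, counts = np.unique(key, return_counts=True)
    return uk // np_max, uk % np_max, counts


def match_events(
    ground_truth: LabelMap,
    prediction: LabelMap,
    score_config: ScoreConfig | None = None,
) -> list[MatchRecord]:
    """Per ground-truth nucleus, the best-IOU predicted object and the list
    of predicted objects covering at least ``overlap_fraction`` of its area.

    Every annotated nucleus yields exactly one record; a nucleus with no
    overlapping prediction records best_iou 0 and no best label.
    """
    cfg = score_config or ScoreConfig()
    if ground_truth.shape != prediction.shape:
        raise ValueError(
            f"label map shapes differ: {ground_truth.shape} vs {prediction.shape}"
        )
    gt = ground_truth.labels
    pred = prediction.labels
    gt_ids = ground_truth.label_ids()
    gt_area = dict(zip(*np.unique(gt[gt > 0], return_counts=True))) if gt_ids.size else {}
    pred_area = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))

    gi, pi, cnt = _pair_counts(gt, pred)
    keep = (gi > 0) & (pi > 0)
    gi, pi, cnt = gi[keep], pi[keep], cnt[keep]

    best: dict[int, tuple[float, int]] = {}
    overlaps: dict[int, list[int]] = {}
    for g, p, c in zip(gi, pi, cnt):
        g, p, c = int(g), int(p), int(c)
        union = gt_area[g] + pred_area[p] - c
        i = c / union
        if g not in best or i > best[g][0] or (i == best[g][0] and p < best[g][1]):
            best[g] = (i, p)
        if c >= cfg.overlap_fraction * gt_area[g]:
            overlaps.setdefault(g, []).append(p)

    records = []
    for g in gt_ids:
        g = int(g)
        if g in best:
            bi, bp = best[g]
            records.append(
                MatchRecord(g, bp, float(bi), sorted(overlaps.get(g, [])))
            )
        else:
            records.append(MatchRecord(g, None, 0.0, []))
    return records


def recall_curve(
    records: Sequence[MatchRecord], score_config: ScoreConfig | None = None
) -> dict[float, float]:
    """Recall = TP / (TP + FN) at each IOU threshold; TP at threshold t are
    the annotated nuclei whose best IOU >= t."""
    cfg = score_config or ScoreConfig()
    if not records:
        raise ValueError("recall undefined without ground-truth events")
    ious = np.asarray([r.best_iou for r in records])
    n = ious.size
    return {float(t): float(np.count_nonzero(ious >= t) / n) for t in cfg.iou_thresholds}


def split_fraction(records: Sequence[MatchRecord]) -> float:
    """Fraction of annotated nuclei overlapped (>= the overlap rule) by two
    or more predicted objects, among those with at least one such overlap."""
    n_any = sum(1 for r in records if len(r.overlapping_pred_labels_20pct) >= 1)
    if n_any == 0:
        raise ValueError("split fraction undefined: no annotation overlaps any prediction")
    n_split = sum(1 for r in records if len(r.overlapping_pred_labels_20pct) >= 2)
    return n_split / n_any


def boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighbourhood contains a different label (object
    pixels only; background does not form a boundary of its own)."""
    lab = np.asarray(labels)
    edge = np.zeros(lab.shape, dtype=bool)
    edge[1:, :] |= lab[1:, :] != lab[:-1, :]
    edge[:-1, :] |= lab[:-1, :] != lab[1:, :]
    edge[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    edge[:, :-1] |= lab[:, :-1] != lab[:, 1:]
    return edge & (lab > 0)


def edge_intersection_score(
    prediction_cells: LabelMap,
    ground_truth: LabelMap,
    definition: str = "gt_interior",
) -> float:
    """Probability-style score for predicted cell boundaries cutting through
    annotated nuclei; lower is better.

    ``gt_interior`` (default): boundary pixels strictly interior to an
    annotated nucleus (its own edge ring excluded) divided by the total
    annotated nucleus area — a boundary that grazes an annotation's rim is
    not a cut, one that crosses its interior is.  ``gt_area``: boundary
    pixels anywhere inside an annotation / total annotated area.
    ``boundary_length``: the gt_area numerator divided by the total
    boundary pixel count.
    """
    if prediction_cells.shape != ground_truth.shape:
        raise ValueError("prediction and ground truth shapes differ")
    gt_mask = ground_truth.labels > 0
    if not gt_mask.any():
        raise ValueError("edge intersection score undefined: empty ground truth")
    edges = boundary_pixels(prediction_cells.labels)
    if definition == "gt_interior":
        from scipy import ndimage as _ndi

        # interior of each annotated nucleus separately: a pixel whose full
        # 8-neighbourhood carries the same positive label
        lab = ground_truth.labels
        fp = np.ones((3, 3), dtype=bool)
        uniform = _ndi.maximum_filter(lab, footprint=fp) == _ndi.minimum_filter(
            lab, footprint=fp
        )
        interior = gt_mask & uniform
        return np.count_nonzero(edges & interior) / np.count_nonzero(gt_mask)
    inside = np.count_nonzero(edges & gt_mask)
    if definition == "gt_area":
        return inside / np.count_nonzero(gt_mask)
    if definition == "boundary_length":
        total = np.count_nonzero(edges)
        return inside / total if total else 0.0
    raise ValueError(f"unknown edge score definition {definition!r}")


def fragmentation_by_group(
    records: Sequence[MatchRecord],
    cell_groups: Mapping[int, object],
) -> dict:
    """Per cell group, the proportion of predicted events participating in a
    fragmentation event (two or more predicted objects each covering >= 20%
    of a single annotation) among the group's predicted events overlapping
    any annotation by >= 20%.  Groups with no qualifying event are reported
    as missing (absent from the result), not as zero.
    """
    qualifying: dict[int, bool] = {}  # pred label -> participates in a split
    for r in records:
        labs = r.overlapping_pred_labels_20pct
        frag = len(labs) >= 2
        for p in labs:
            qualifying[p] = qualifying.get(p, False) or frag

    per_group_counts: dict = {}
    for p, frag in qualifying.items():
        if p not in cell_groups:
            continue
        g = cell_groups[p]
        tot, nf = per_group_counts.get(g, (0, 0))
        per_group_counts[g] = (tot + 1, nf + (1 if frag else 0))
    return {g: nf / tot for g, (tot, nf) in per_group_counts.items()}


def score_prediction(
    prediction_nuclei: LabelMap,
    ground_truth: LabelMap,
    prediction_cells: LabelMap | None = None,
    cell_groups: Mapping[int, object] | None = None,
    score_config: ScoreConfig | None = None,
) -> ScoreReport:
    """Run the full metric suite and assemble a :class:`ScoreReport`."""
    cfg = score_config or ScoreConfig()
    records = match_events(ground_truth, prediction_nuclei, cfg)
    recalls = recall_curve(records, cfg)
    try:
        split = split_fraction(records)
    except ValueError:
        split = float("nan")
    eis = float("nan")
    if prediction_cells is not None:
        eis = edge_intersection_score(
            prediction_cells, ground_truth, cfg.edge_score_definition
        )
    frag = fragmentation_by_group(records, cell_groups) if cell_groups else {}
    return ScoreReport(
        records=records,
        recall_by_threshold=recalls,
        split_fraction=split,
        edge_intersection_score=eis,
        per_group_fragmentation=frag,
    )
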