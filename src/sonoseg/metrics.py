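"""Segmentation and needle-localization metrics with mm calibration.

Overlap metrics (IoU, Dice, precision, recall, pixel accuracy) operate on
binary masks. Needle metrics operate on mask geometry:

* MHD — modified Hausdorff distance, the max of the two directed mean
  nearest-neighbor distances between the predicted and ground-truth pixel
  sets; computed in pixels and converted to mm by the pixel spacing.
* TE — targeting error: |d_abs − d_seg|, the absolute difference of the
  perpendicular distances from the image center to the ground-truth and
  predicted needle lines (total-least-squares fits).
* NLSR — needle localization success: the masks intersect and
  |Sg ∩ Sp| > 0.5·min(|Sg|, |Sp|) (strict).
* NLR — predicted over true needle length, lengths measured as the extent
  of the foreground along the fitted principal axis.

Empty-mask conventions (the definitions do not cover them): both masks
empty gives 1 for the overlap metrics; line-based metrics raise
:class:`UndefinedMetricError` and the dataset evaluator reports such
samples as failures rather than scoring them 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ShapeError, UndefinedMetricError


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_pair(a, b):
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


# -- overlap metrics ----------------------------------------------------------

def iou(pred_mask, gt_mask) -> float:
    p, g = _check_pair(pred_mask, gt_mask)
    inter = np.logical_and(p, g).sum()
    union = p.sum() + g.sum() - inter
    if union == 0:
        return 1.0
    return float(inter / union)


def dice(pred_mask, gt_mask) -> float:
    p, g = _check_pair(pred_mask, gt_mask)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def precision(pred_mask, gt_mask) -> float:
    p, g = _check_pair(pred_mask, gt_mask)
    if p.sum() == 0:
        return 1.0 if g.sum() == 0 else 0.0
    return float(np.logical_and(p, g).sum() / p.sum())


def recall(pred_mask, gt_mask) -> float:
    p, g = _check_pair(pred_mask, gt_mask)
    if g.sum() == 0:
        return 1.0 if p.sum() == 0 else 0.0
    return float(np.logical_and(p, g).sum() / g.sum())


def pixel_accuracy(pred_labels, gt_labels, num_classes: int) -> float:
    """Trace over total of the num_classes × num_classes confusion matrix."""
    p = np.asarray(pred_labels).astype(int)
    g = np.asarray(gt_labels).astype(int)
    if p.shape != g.shape:
        raise ShapeError(f"label map shapes differ: {p.shape} vs {g.shape}")
    for name, arr in (("pred", p), ("gt", g)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    conf = np.bincount(g.ravel() * num_classes + p.ravel(),
                       minlength=num_classes ** 2).reshape(num_classes, num_classes)
    return float(np.trace(conf) / conf.sum())


# -- point-set / line metrics -------------------------------------------------

@dataclasses.dataclass
class PointSet:
    points: np.ndarray            # (n, 2) of (row, col), pixel units
    spacing: float = 1.0          # mm per pixel


@dataclasses.dataclass
class NeedleLine:
    """Total-least-squares line: point on line + unit direction."""

    point: np.ndarray             # (row, col) centroid
    direction: np.ndarray         # unit (d_row, d_col)

    @property
    def angle_deg(self) -> float:
        """Angle from the horizontal image axis, in (−90, 90]."""
        ang = np.degrees(np.arctan2(self.direction[0], self.direction[1]))
        if ang <= -90:
            ang += 180.0
        elif ang > 90:
            ang -= 180.0
        return float(ang)


def mhd(points_pred, points_gt, spacing: float | None = None) -> float:
    """Modified Hausdorff distance between two point sets.

    max of the two directed mean nearest-neighbor Euclidean distances; in
    pixels, or in mm when ``spacing`` is given.
    """
    xp = np.atleast_2d(np.asarray(points_pred, dtype=float))
    yg = np.atleast_2d(np.asarray(points_gt, dtype=float))
    if xp.size == 0 or yg.size == 0:
        raise UndefinedMetricError("MHD is undefined for an empty point set")
    forward = cKDTree(yg).query(xp)[0].mean()
    backward = cKDTree(xp).query(yg)[0].mean()
    d = float(max(forward, backward))
    return d * spacing if spacing is not None else d


def mask_points(mask) -> np.ndarray:
    return np.argwhere(_as_bool(mask)).astype(float)


def fit_needle_line(mask) -> NeedleLine:
    """Principal axis of the foreground pixel coordinates (TLS fit)."""
    pts = mask_points(mask)
    if pts.shape[0] < 2:
        raise UndefinedMetricError("line fit needs at least 2 foreground pixels")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    vals, vecs = np.linalg.eigh(cov)
    direction = vecs[:, int(np.argmax(vals))]
    direction = direction / np.linalg.norm(direction)
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction            # deterministic orientation
    return NeedleLine(point=centroid, direction=direction)


def _point_line_distance(point_rc, line: NeedleLine) -> float:
    v = np.asarray(point_rc, dtype=float) - line.point
    along = float(v @ line.direction)
    return float(np.linalg.norm(v - along * line.direction))


def targeting_error(gt_mask, pred_mask, image_size, spacing: float = 1.0) -> float:
    """TE = |d_abs − d_seg| × spacing, distances taken from the image center.

    ``image_size`` is (H, W); the center is (W/2, H/2) in (col, row) pixel
    units. Symmetric in its mask arguments by construction.
    """
    H, W = image_size
    center = np.array([H / 2.0, W / 2.0])     # (row, col)
    d_abs = _point_line_distance(center, fit_needle_line(gt_mask))
    d_seg = _point_line_distance(center, fit_needle_line(pred_mask))
    return abs(d_abs - d_seg) * spacing


def nlsr(gt_mask, pred_mask) -> bool:
    """Success iff the masks intersect and |∩| > 0.5·min(|Sg|, |Sp|), strictly."""
    g, p = _check_pair(gt_mask, pred_mask)
    inter = np.logical_and(g, p).sum()
    if inter == 0:
        return False
    return bool(inter > 0.5 * min(g.sum(), p.sum()))


def needle_length(mask) -> float:
    """Extent of the foreground projected on its fitted principal axis."""
    line = fit_needle_line(mask)
    proj = (mask_points(mask) - line.point) @ line.direction
    return float(proj.max() - proj.min())


def nlr(gt_mask, pred_mask) -> float:
    """Predicted over true needle length; not clipped at 1."""
    l_true = needle_length(gt_mask)
    if l_true == 0:
        raise UndefinedMetricError("true needle length is zero")
    return needle_length(pred_mask) / l_true


# -- dataset-level reporting --------------------------------------------------

_CONTINUOUS = ("dice", "iou", "precision", "recall", "pixel_accuracy",
               "mhd_mm", "te_mm", "nlr")


@dataclasses.dataclass
class EvaluationReport:
    per_sample: list[dict]
    aggregates: dict[str, dict]
    failures: dict[str, int]
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_sample)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"n_samples": self.n_samples, "aggregates": self.aggregates,
                   "failures": self.failures}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is None:
            return text
        Path(path).write_text(text)
        return text


def evaluate_dataset(pred_masks, gt_masks, spacing: float = 1.0) -> EvaluationReport:
    """Per-sample metrics plus mean ± std aggregation over paired masks.

    Samples where a line-based metric is undefined (e.g. an empty
    prediction) contribute to the per-metric failure counts and are
    excluded from that metric's aggregate — never scored as 0.
    """
    preds = list(pred_masks)
    gts = list(gt_masks)
    if len(preds) != len(gts):
        raise ShapeError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    if not preds:
        raise ValueError("evaluate_dataset needs at least one sample")

    rows: list[dict] = []
    failures = {m: 0 for m in ("mhd_mm", "te_mm", "nlr")}
    for i, (p, g) in enumerate(zip(preds, gts)):
        row: dict = {
            "sample": i,
            "dice": dice(p, g),
            "iou": iou(p, g),
            "precision": precision(p, g),
            "recall": recall(p, g),
            "pixel_accuracy": pixel_accuracy(_as_bool(p).astype(int),
                                             _as_bool(g).astype(int), 2),
            "nlsr_success": nlsr(g, p),
        }
        try:
            row["mhd_mm"] = mhd(mask_points(p), mask_points(g), spacing)
        except UndefinedMetricError:
            row["mhd_mm"] = np.nan
            failures["mhd_mm"] += 1
        try:
            row["te_mm"] = targeting_error(g, p, _as_bool(g).shape, spacing)
        except UndefinedMetricError:
            row["te_mm"] = np.nan
            failures["te_mm"] += 1
        try:
            row["nlr"] = nlr(g, p)
        except UndefinedMetricError:
            row["nlr"] = np.nan
            failures["nlr"] += 1
        rows.append(row)

    aggregates: dict[str, dict] = {}
    for m in _CONTINUOUS:
        vals = np.array([r[m] for r in rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            aggregates[m] = {"mean": float(vals.mean()),
                             "std": float(vals.std(ddof=0)), "n": int(vals.size)}
        else:
            aggregates[m] = {"mean": np.nan, "std": np.nan, "n": 0}
    successes = sum(bool(r["nlsr_success"]) for r in rows)
    aggregates["nlsr_pct"] = {"value": 100.0 * successes / len(rows), "n": len(rows)}
    return EvaluationReport(per_sample=rows, aggregates=aggregates,
                            failures=failures, n_samples=len(rows))
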