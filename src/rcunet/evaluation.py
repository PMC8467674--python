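"""The five segmentation metrics and their aggregation.

For a ground-truth mask GT and a segmentation result SR (same extent):

    TP = |GT n SR| / |GT|            true-positive rate w.r.t. GT
    FP = |SR \\ GT| / |GT|            false-positive rate w.r.t. GT (may exceed 1)
    DC = 2|GT n SR| / (|GT| + |SR|)  Dice coefficient
    JS = |GT n SR| / |GT u SR|       Jaccard similarity
    HD = max directed Hausdorff distance between the two point sets,
         Euclidean, in pixels

A segmentation counts as successful when JS > 0.75 (strict). Metrics that
are undefined for a pair (e.g. TP with an empty ground truth, HD with an
empty mask) raise :class:`UndefinedMetricError` from the low-level
functions and are recorded as missing - never as 0 - by the aggregators.

HD is computed on contour (boundary) pixels by default; ``hd_mode="area"``
uses every foreground pixel instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

SUCCESS_JS_THRESHOLD = 0.75

METRIC_NAMES = ("tp", "fp", "dc", "js", "hd")


class UndefinedMetricError(ValueError):
    pass


def _as_mask(arr, name) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))) and not np.all(
                np.isin(vals, (0, 255))):
            raise ValueError(f"{name} is not a binary mask")
        arr = arr > (127 if arr.max() > 1 else 0)
    return arr


def _check_pair(gt, sr):
    gt = _as_mask(gt, "GT")
    sr = _as_mask(sr, "SR")
    if gt.shape != sr.shape:
        raise ValueError(f"extent mismatch: GT {gt.shape} vs SR {sr.shape}")
    return gt, sr


def tp_rate(gt, sr) -> float:
    gt, sr = _check_pair(gt, sr)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise UndefinedMetricError("TP undefined for empty ground truth")
    return float((gt & sr).sum() / n_gt)


def fp_rate(gt, sr) -> float:
    gt, sr = _check_pair(gt, sr)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise UndefinedMetricError("FP undefined for empty ground truth")
    return float((sr & ~gt).sum() / n_gt)


def dice(gt, sr) -> float:
    gt, sr = _check_pair(gt, sr)
    denom = int(gt.sum()) + int(sr.sum())
    if denom == 0:
        raise UndefinedMetricError("DC undefined when both masks are empty")
    return float(2 * (gt & sr).sum() / denom)


def jaccard(gt, sr) -> float:
    gt, sr = _check_pair(gt, sr)
    union = int((gt | sr).sum())
    if union == 0:
        raise UndefinedMetricError("JS undefined when both masks are empty")
    return float((gt & sr).sum() / union)


def contour_points(mask: np.ndarray) -> np.ndarray:
    """(n, 2) row/col coordinates of boundary pixels (foreground pixels with
    at least one 4-neighbor outside the mask, image border included)."""
    eroded = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    return np.argwhere(mask & ~eroded).astype(np.float64)


def hausdorff(gt, sr, mode: str = "contour") -> float:
    """Symmetric Hausdorff distance in pixels between the two masks'
    point sets (contour pixels by default, all pixels with mode="area")."""
    gt, sr = _check_pair(gt, sr)
    if not gt.any() or not sr.any():
        raise UndefinedMetricError("HD undefined for an empty mask")
    if mode == "contour":
        pts_gt, pts_sr = contour_points(gt), contour_points(sr)
    elif mode == "area":
        pts_gt = np.argwhere(gt).astype(np.float64)
        pts_sr = np.argwhere(sr).astype(np.float64)
    else:
        raise ValueError(f"unknown HD mode {mode!r}")
    d1 = directed_hausdorff(pts_gt, pts_sr)[0]
    d2 = directed_hausdorff(pts_sr, pts_gt)[0]
    return float(max(d1, d2))


@dataclass
class MetricReport:
    """Scores of one GT/SR pair; undefined metrics are ``None``."""

    tp: float | None
    fp: float | None
    dc: float | None
    js: float | None
    hd: float | None

    @property
    def success(self) -> bool:
        return self.js is not None and self.js > SUCCESS_JS_THRESHOLD

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "dc": self.dc, "js": self.js,
                "hd": self.hd, "success": self.success}


def evaluate_pair(gt, sr, hd_mode: str = "contour") -> MetricReport:
    """All five metrics for one pair; undefined ones recorded as None."""
    values = {}
    for name, fn in (("tp", tp_rate), ("fp", fp_rate), ("dc", dice),
                     ("js", jaccard)):
        try:
            values[name] = fn(gt, sr)
        except UndefinedMetricError:
            values[name] = None
    try:
        values["hd"] = hausdorff(gt, sr, mode=hd_mode)
    except UndefinedMetricError:
        values["hd"] = None
    return MetricReport(**values)


def evaluate_set(pairs, hd_mode: str = "contour"):
    """Per-pair reports plus aggregate means over the defined values.

    Returns ``(reports, aggregate)`` where aggregate maps each metric to its
    mean, carries ``n_undefined`` counts per metric, and the strict
    JS > 0.75 ``success_count``.
    """
    reports = [evaluate_pair(gt, sr, hd_mode) for gt, sr in pairs]
    if not reports:
        raise ValueError("no pairs to evaluate")
    aggregate: dict = {"n": len(reports), "n_undefined": {}}
    any_defined = False
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports
                if getattr(r, name) is not None]
        aggregate[name] = float(np.mean(vals)) if vals else None
        aggregate["n_undefined"][name] = len(reports) - len(vals)
        any_defined = any_defined or bool(vals)
    if not any_defined:
        raise UndefinedMetricError("every metric undefined on every pair")
    aggregate["success_count"] = sum(r.success for r in reports)
    return reports, aggregate
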