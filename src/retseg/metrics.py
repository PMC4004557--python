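"""Pixel-level segmentation metrics and the edge-point width-evaluation protocol.

Segmentation quality against a manual gold standard is reported as

    TPR = TP / (TP + FN),   FPR = FP / (FP + TN),
    ACC = (TP + TN) / (TP + FP + TN + FN),

with counting restricted to the field of view (outside-FOV pixels are
trivially background and would inflate ACC).  Method-vs-literature deltas
use the relative improvement 100·(m_our − m_lit)/m_lit.

Width evaluation follows the edge-point protocol used with REVIEW-style
ground truth: expert-marked edge-point pairs are morphologically closed
into gold vessel segments, predicted measurements are associated to the
nearest ground-truth centre within the local true width, and per-cross-
section pixel differences along the lines joining each edge-point pair
yield the measurement-error standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology

from .io import FovMask

__all__ = [
    "EvalMetrics",
    "WidthEvalResult",
    "confusion",
    "improvement",
    "overlay",
    "close_gt_edges",
    "width_protocol",
]


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else 0.0

    @property
    def acc(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "tpr": self.tpr, "fpr": self.fpr, "acc": self.acc,
        }


@dataclass(frozen=True)
class WidthEvalResult:
    success_pct: float
    mean_width: float
    error_std: float
    n_associations: int = 0
    undefined: bool = False


def confusion(pred: np.ndarray, gold: np.ndarray, fov: FovMask | np.ndarray) -> EvalMetrics:
    """TP/FP/TN/FN over FOV pixels only."""
    pred = np.asarray(pred, bool)
    gold = np.asarray(gold, bool)
    fovp = fov.pixels if isinstance(fov, FovMask) else np.asarray(fov, bool)
    if pred.shape != gold.shape or pred.shape != fovp.shape:
        raise ValueError("shape mismatch between pred, gold and fov")
    if not fovp.any():
        raise ValueError("empty FOV")
    p, g = pred[fovp], gold[fovp]
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def improvement(m_our: float, m_lit: float) -> float:
    """Relative improvement in percent: 100·(m_our − m_lit)/m_lit."""
    if m_lit == 0:
        raise ValueError("literature value is zero; improvement undefined")
    return 100.0 * (m_our - m_lit) / m_lit


def overlay(pred: np.ndarray, gold: np.ndarray) -> np.ndarray:
    """Tri-colour agreement overlay as an H×W×3 float image.

    Blue = agreement (pred ∧ gold), yellow = false positives, green = false
    negatives, black elsewhere.
    """
    pred = np.asarray(pred, bool)
    gold = np.asarray(gold, bool)
    if pred.shape != gold.shape:
        raise ValueError("shape mismatch")
    img = np.zeros(pred.shape + (3,), dtype=np.float64)
    both = pred & gold
    img[both] = (0.0, 0.0, 1.0)
    img[pred & ~gold] = (1.0, 1.0, 0.0)
    img[~pred & gold] = (0.0, 1.0, 0.0)
    return img


def close_gt_edges(
    edge_points: list,
    shape: tuple,
    s: int = 3,
    n_vessels: int = 1,
    cap: int = 15,
) -> tuple:
    """Render edge points and close them into solid vessel segments.

    The points are drawn onto a blank grid and closed with a square element
    of side ``s``; if the closed image has more 8-connected components than
    ``n_vessels``, s is raised by 1 (up to ``cap``) until the components
    match — the smallest element that connects all the points is used.

    Returns (mask, s_used, unconnected_flag).
    """
    if len(edge_points) < 2:
        raise ValueError("need at least 2 edge points")
    if s < 1:
        raise ValueError("s must be ≥ 1")
    canvas = np.zeros(shape, dtype=bool)
    for x, y in edge_points:
        xi, yi = int(round(x)), int(round(y))
        if 0 <= yi < shape[0] and 0 <= xi < shape[1]:
            canvas[yi, xi] = True
    struct8 = np.ones((3, 3))
    while True:
        closed = morphology.closing(canvas, np.ones((s, s), dtype=bool))
        _, n = ndi.label(closed, structure=struct8)
        if n <= n_vessels:
            return closed, s, False
        if s >= cap:
            return closed, s, True
        s += 1


def _nearest(points: np.ndarray, q: np.ndarray) -> tuple:
    """Nearest row of `points` to q; smallest index on ties."""
    d = np.hypot(points[:, 0] - q[0], points[:, 1] - q[1])
    i = int(np.argmin(d))  # argmin returns the first minimum
    return i, float(d[i])


def width_protocol(
    pred_records: list,
    gt_table: list,
    shape: tuple,
    gt_edge_pairs: list | None = None,
    s: int = 3,
) -> WidthEvalResult:
    """Edge-point width-evaluation protocol.

    Parameters
    ----------
    pred_records : list of WidthRecord
        Predicted centre points and edge pairs.
    gt_table : list of (x, y, true_width)
        Ground-truth centre locations with the local true width.
    shape : (H, W)
        Grid shape for the rendered segment images.
    gt_edge_pairs : optional list of ((xa, ya), (xb, yb))
        Expert edge-point pairs; the straight line joining each pair is a
        measurement cross-section.  When absent, pairs are synthesised
        perpendicular from the gt table (centre ± width/2 along y).

    Notes
    -----
    success_pct: a ground-truth location scores when its nearest predicted
    centre lies within the local true width and that centre sits inside the
    closed ground-truth segment.  mean_width: foreground pixel count of the
    closed predicted-edge segment divided by its thinned-centreline pixel
    count.  error_std: standard deviation of the per-cross-section pixel
    disagreement between the closed predicted and ground-truth segments,
    with the number of cross-section lines as the denominator.
    """
    if not pred_records or not gt_table:
        return WidthEvalResult(0.0, float("nan"), float("nan"), 0, undefined=True)
    if gt_edge_pairs is None:
        gt_edge_pairs = [
            ((x, y - w / 2.0), (x, y + w / 2.0)) for x, y, w in gt_table
        ]
    gt_edge_points = [p for pair in gt_edge_pairs for p in pair]
    gt_mask, _, _ = close_gt_edges(gt_edge_points, shape, s=s)

    pred_edge_points = [r.edge_a for r in pred_records] + [r.edge_b for r in pred_records]
    pred_mask, s_used, _ = close_gt_edges(pred_edge_points, shape, s=s)
    pred_cl = morphology.thin(pred_mask)

    pred_centres = np.array([r.centre for r in pred_records], dtype=float)
    n_success = 0
    n_assoc = 0
    for x, y, w in gt_table:
        i, d = _nearest(pred_centres, np.array([x, y]))
        if d <= w:
            n_assoc += 1
            cx, cy = int(round(pred_centres[i, 0])), int(round(pred_centres[i, 1]))
            if 0 <= cy < shape[0] and 0 <= cx < shape[1] and gt_mask[cy, cx]:
                n_success += 1
    if n_assoc == 0:
        return WidthEvalResult(0.0, float("nan"), float("nan"), 0, undefined=True)
    success_pct = 100.0 * n_success / len(gt_table)

    # the closing rounds the segment ends into caps that belong to no cross
    # section; exclude the cap neighbourhoods of the centreline endpoints
    # from both counts so the area/length ratio estimates the true calibre
    area_mask, cl_mask = pred_mask, pred_cl
    nb = _cl_neighbour_count(pred_cl)
    eys, exs = np.nonzero(pred_cl & (nb <= 1))
    if len(eys):
        cap = np.zeros(shape, dtype=bool)
        rad = s_used + 1
        for ey, ex in zip(eys.tolist(), exs.tolist()):
            y0, y1 = max(0, ey - rad), min(shape[0], ey + rad + 1)
            x0, x1 = max(0, ex - rad), min(shape[1], ex + rad + 1)
            cap[y0:y1, x0:x1] = True
        area_mask = pred_mask & ~cap
        cl_mask = pred_cl & ~cap
    n_cl = int(cl_mask.sum())
    mean_width = float(area_mask.sum()) / n_cl if n_cl else float("nan")

    # per-cross-section error: pixel disagreement along the full straight
    # line through each gt edge pair (extended beyond the pair so that
    # over-segmentation outside the true band is seen)
    diff = pred_mask ^ gt_mask
    per_line = []
    for (xa, ya), (xb, yb) in gt_edge_pairs:
        mx, my = (xa + xb) / 2.0, (ya + yb) / 2.0
        dx, dy = xb - xa, yb - ya
        half = np.hypot(dx, dy) / 2.0
        if half == 0:
            continue
        ext = (half + s + 2.0) / half  # stretch factor beyond each edge point
        rr, cc = draw.line(
            int(round(my - dy / 2.0 * ext)), int(round(mx - dx / 2.0 * ext)),
            int(round(my + dy / 2.0 * ext)), int(round(mx + dx / 2.0 * ext)),
        )
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        per_line.append(int(diff[rr[ok], cc[ok]].sum()))
    err = np.asarray(per_line, dtype=float)
    error_std = float(np.sqrt(np.mean(err**2))) if err.size else float("nan")
    return WidthEvalResult(success_pct, mean_width, error_std, n_assoc)


def _cl_neighbour_count(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel, 1).astype(np.int8)
    out = np.zeros_like(padded)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if (dy, dx) != (0, 0):
                out += np.roll(np.roll(padded, dy, axis=0), dx, axis=1)
    return out[1:-1, 1:-1]
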