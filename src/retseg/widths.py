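"""Vessel centreline extraction and calibre measurement.

The segmentation mask is thinned to a one-pixel centreline.  At each
centreline pixel whose 3×3 neighbourhood forms a valid three-pixel path
(coordinate-distinct along exactly one image axis — 14 such window
configurations exist), the local vessel direction is the unit vector from
the first to the last path pixel.  The direction is rotated 90°
counter-clockwise and the perpendicular profile is rasterized outward in
both senses until it leaves the vessel; the outermost foreground pixels are
the edge points and the width is their Euclidean distance plus one pixel
extent, so that an axis-aligned bar of height h measures exactly h.

Coordinates are 0-based (x = column, y = row) with y increasing downward;
in this convention a 90° CCW rotation maps (dx, dy) → (dy, −dx).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import morphology

__all__ = [
    "WidthRecord",
    "centreline",
    "enumerate_window_configs",
    "detect_candidates",
    "measure_width",
    "profile_vessel",
]


@dataclass(frozen=True)
class WidthRecord:
    """One calibre measurement: centre, along-vessel direction, edge pair."""

    centre: tuple  # (x, y)
    direction: tuple  # unit (dx, dy)
    edge_a: tuple
    edge_b: tuple
    width: float
    clipped: bool = False


def centreline(mask: np.ndarray, min_spur: int = 3) -> np.ndarray:
    """Morphological thinning to a 1-px skeleton, with short spurs pruned.

    Spurs (open-ended skeleton twigs) shorter than ``min_spur`` pixels are
    artefacts of boundary roughness and are removed; pruning never deletes a
    whole component, so 8-connected component count is preserved.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    skel = morphology.thin(mask)
    return _prune_spurs(skel, min_spur)


def _neighbour_count(skel: np.ndarray) -> np.ndarray:
    padded = np.pad(skel, 1).astype(np.int8)
    c = np.zeros_like(padded, dtype=np.int8)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            c += np.roll(np.roll(padded, dy, axis=0), dx, axis=1)
    return c[1:-1, 1:-1]


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Delete endpoint-to-branch-point twigs of length < ``max_len``.

    A spur is walked from its endpoint; if a branch point (≥ 3 skeleton
    neighbours) is met within ``max_len`` steps the walked pixels are
    removed.  Plain open lines (no branch point) are left untouched, so
    this never shortens or erases a simple centreline.
    """
    skel = skel.copy()
    H, W = skel.shape
    nb = _neighbour_count(skel)
    ys, xs = np.nonzero(skel & (nb == 1))
    for y0, x0 in zip(ys.tolist(), xs.tolist()):
        path = [(y0, x0)]
        prev = None
        y, x = y0, x0
        hit_branch = False
        for _ in range(max_len):
            nbrs = [
                (y + dy, x + dx)
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)
                and 0 <= y + dy < H and 0 <= x + dx < W
                and skel[y + dy, x + dx] and (y + dy, x + dx) != prev
            ]
            if len(nbrs) != 1:
                hit_branch = len(nbrs) >= 2
                break
            prev = (y, x)
            y, x = nbrs[0]
            nbrs_next = _count_neighbours_at(skel, y, x)
            if nbrs_next >= 3:
                hit_branch = True
                break
            path.append((y, x))
        if hit_branch:
            for py, px in path:
                skel[py, px] = False
    return skel


def _count_neighbours_at(skel: np.ndarray, y: int, x: int) -> int:
    H, W = skel.shape
    return sum(
        1
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dy, dx) != (0, 0)
        and 0 <= y + dy < H and 0 <= x + dx < W and skel[y + dy, x + dx]
    )


def enumerate_window_configs() -> set:
    """All valid 3×3 window configurations for centreline orientation.

    A configuration is an unordered pair of distinct 8-neighbour offsets
    {(dx1,dy1), (dx2,dy2)} such that the three path pixels (the two offsets
    plus the window centre) have pairwise-distinct coordinates along exactly
    one image axis.  There are 14 such configurations.
    """
    offs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    configs = set()
    for i in range(len(offs)):
        for j in range(i + 1, len(offs)):
            a, b = offs[i], offs[j]
            xs = {a[0], 0, b[0]}
            ys = {a[1], 0, b[1]}
            if (len(xs) == 3) != (len(ys) == 3):  # exactly one axis distinct
                configs.add(frozenset((a, b)))
    return configs


_CONFIGS = None


def _configs() -> set:
    global _CONFIGS
    if _CONFIGS is None:
        _CONFIGS = enumerate_window_configs()
    return _CONFIGS


def detect_candidates(cl: np.ndarray) -> list:
    """Candidate (centre, direction) pairs from the centreline image.

    A centreline pixel qualifies when its two 8-neighbours on the line form
    a valid window configuration through it.  Branch points (≥3 centreline
    neighbours) and endpoints are rejected.  When both orientation groups of
    a window match, the configuration whose off-centre pixels have the
    larger y-coordinates wins.  Direction is the unit vector from the first
    to the last path pixel, returned as (dx, dy).
    """
    cl = np.asarray(cl, dtype=bool)
    configs = _configs()
    H, W = cl.shape
    ys, xs = np.nonzero(cl)
    out = []
    for y, x in zip(ys.tolist(), xs.tolist()):
        nbrs = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                yy, xx = y + dy, x + dx
                if 0 <= yy < H and 0 <= xx < W and cl[yy, xx]:
                    nbrs.append((dx, dy))
        if len(nbrs) < 2 or len(nbrs) > 2:
            continue  # endpoint, isolated, or branch pixel
        matching = [
            frozenset((a, b))
            for k, a in enumerate(nbrs)
            for b in nbrs[k + 1 :]
            if frozenset((a, b)) in configs
        ]
        if not matching:
            # pure-diagonal continuation: the two line neighbours are exact
            # opposites, so the tangent is unambiguous even though the
            # triple is coordinate-distinct along both axes and therefore
            # not one of the 14 window configurations
            a, b = nbrs
            if a == (-b[0], -b[1]):
                matching = [frozenset((a, b))]
            else:
                continue
        # prefer the configuration with larger off-centre y-coordinates
        cfg = max(matching, key=lambda c: sum(dy for _, dy in c))
        a, b = sorted(cfg)
        vx, vy = float(b[0] - a[0]), float(b[1] - a[1])
        n = np.hypot(vx, vy)
        out.append(((x, y), (vx / n, vy / n)))
    return out


def _trace(mask: np.ndarray, x0: int, y0: int, dx: float, dy: float, gap_tolerance: int):
    """Walk the rasterized ray from (x0,y0); return the last foreground pixel
    and whether the walk hit the image border while still on the vessel.

    Largest-component stepping: the dominant axis advances one pixel per
    step and the other axis is carried proportionally and rounded.
    """
    H, W = mask.shape
    major = max(abs(dx), abs(dy))
    stepx, stepy = dx / major, dy / major
    last = (x0, y0)
    gaps = 0
    k = 0
    while True:
        k += 1
        x = x0 + int(round(stepx * k))
        y = y0 + int(round(stepy * k))
        if not (0 <= x < W and 0 <= y < H):
            return last, True
        if mask[y, x]:
            last = (x, y)
            gaps = 0
        else:
            gaps += 1
            if gaps > gap_tolerance:
                return last, False


def measure_width(
    mask: np.ndarray,
    centre: tuple,
    direction: tuple,
    gap_tolerance: int = 0,
) -> WidthRecord:
    """Measure the vessel width at ``centre`` perpendicular to ``direction``.

    The along-vessel direction is rotated 90° CCW ((dx,dy) → (dy,−dx)) and
    the perpendicular profile is walked outward in both senses until the
    first background pixel (``gap_tolerance`` background pixels are
    forgiven before stopping).  Width is the Euclidean distance between the
    outermost foreground pixels plus 1 (pixel-extent correction).
    """
    mask = np.asarray(mask, dtype=bool)
    x0, y0 = int(centre[0]), int(centre[1])
    if not mask[y0, x0]:
        raise ValueError(f"centre {centre} is not a foreground pixel")
    dx, dy = direction
    n = np.hypot(dx, dy)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("direction must be unit-norm")
    px, py = dy, -dx  # 90° CCW in image coordinates (y down)
    edge_a, clip_a = _trace(mask, x0, y0, px, py, gap_tolerance)
    edge_b, clip_b = _trace(mask, x0, y0, -px, -py, gap_tolerance)
    width = float(np.hypot(edge_a[0] - edge_b[0], edge_a[1] - edge_b[1])) + 1.0
    return WidthRecord(
        centre=(x0, y0),
        direction=(dx, dy),
        edge_a=edge_a,
        edge_b=edge_b,
        width=width,
        clipped=clip_a or clip_b,
    )


def profile_vessel(mask: np.ndarray, gap_tolerance: int = 0) -> list:
    """Measure the width at every valid centreline candidate of a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    cl = centreline(mask)
    records = []
    for centre, direction in detect_candidates(cl):
        records.append(measure_width(mask, centre, direction, gap_tolerance))
    return records


def records_to_csv(records: list, path: str) -> None:
    """Export width records as CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(
            ["x", "y", "dir_x", "dir_y", "edge_ax", "edge_ay", "edge_bx", "edge_by", "width", "clipped"]
        )
        for r in records:
            wr.writerow(
                [r.centre[0], r.centre[1], f"{r.direction[0]:.6f}", f"{r.direction[1]:.6f}",
                 r.edge_a[0], r.edge_a[1], r.edge_b[0], r.edge_b[1], f"{r.width:.4f}", int(r.clipped)]
            )
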