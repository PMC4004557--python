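"""Gray-level co-occurrence second-order entropy thresholding.

The binarization threshold is chosen to maximise the *second-order* (pixel
transition) entropy rather than the histogram entropy.  The co-occurrence
matrix t_ij counts ordered gray-level transitions from each pixel to its
right neighbour and to the neighbour below; p_ij is its normalisation.  A
candidate threshold t splits the matrix into four quadrants; the within-
object quadrant (levels > t on both axes — vessels are bright after the
top-hat) and within-background quadrant (levels ≤ t on both axes) are each
renormalized and their transition entropies

    H_O(t) = −½ Σ p̂ log₂ p̂   (object quadrant)
    H_B(t) = −½ Σ p̂ log₂ p̂   (background quadrant)

summed into H_T(t) = H_O(t) + H_B(t).  The optimal threshold is
argmax_t H_T(t) (smallest t on ties).  Cross quadrants (object↔background
transitions) are computed and exposed but excluded from H_T by default.

The same threshold drives two binarization regimes via a scale factor:
the mask regime (scale 0.3–0.8, default 0.5) extracts a generous vessel
mask, and the reflex regime (scale 0.8–3, default 1.5) keeps only strongly
bright pixels, recovering vessels split by the central light reflex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import FovMask, GrayImage

log = logging.getLogger(__name__)

__all__ = [
    "QuantizedImage",
    "CooccurrenceMatrix",
    "EntropyProfile",
    "quantize",
    "cooccurrence",
    "entropy_curve",
    "optimal_threshold",
    "binarize",
]


@dataclass(frozen=True)
class QuantizedImage:
    """Integer gray levels in 0..L (quantization floor(f·L) clipped to L)."""

    levels: np.ndarray
    L: int

    def __post_init__(self) -> None:
        if self.levels.min() < 0 or self.levels.max() > self.L:
            raise ValueError("quantized levels out of range")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """(L+1)×(L+1) right/below transition counts and their probabilities."""

    counts: np.ndarray
    probs: np.ndarray

    @property
    def L(self) -> int:
        return self.counts.shape[0] - 1


@dataclass(frozen=True)
class EntropyProfile:
    """Per-threshold entropies for t in 0..L−1."""

    h_object: np.ndarray
    h_background: np.ndarray
    h_total: np.ndarray
    h_cross: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def quantize(gray: GrayImage, L: int = 255) -> QuantizedImage:
    """Quantize a [0,1] image to integer levels 0..L by floor(f·L)."""
    if not (15 <= L <= 255):
        raise ValueError(f"L={L} outside [15, 255]")
    q = np.floor(gray.pixels * L).astype(np.int64)
    return QuantizedImage(levels=np.clip(q, 0, L), L=L)


def cooccurrence(q: QuantizedImage) -> CooccurrenceMatrix:
    """Count ordered gray-level transitions to the right and below neighbours.

    An M×N image contributes M(N−1) + (M−1)N transitions in total.
    """
    lv = q.levels
    if lv.shape[0] < 2 or lv.shape[1] < 2:
        raise ValueError("image must be at least 2×2")
    n = q.L + 1
    right = lv[:, :-1].ravel() * n + lv[:, 1:].ravel()
    below = lv[:-1, :].ravel() * n + lv[1:, :].ravel()
    counts = np.bincount(np.concatenate([right, below]), minlength=n * n)
    counts = counts.reshape(n, n)
    total = counts.sum()
    return CooccurrenceMatrix(counts=counts, probs=counts / total)


def _quadrant_entropy(s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """−½ Σ p̂ log₂ p̂ of a renormalized quadrant, from its mass s1 and
    unnormalized plogp sum s2 = Σ p log₂ p; empty quadrant contributes 0.

    Cumulative-sum inclusion–exclusion can leave ~1e-17 residues on truly
    empty quadrants, so masses below 1e-12 are treated as empty and the
    result is clamped at 0 (a renormalized distribution's entropy is ≥ 0).
    """
    out = np.zeros_like(s1)
    nz = s1 > 1e-12
    out[nz] = -0.5 * (s2[nz] / s1[nz] - np.log2(s1[nz]))
    return np.maximum(out, 0.0)


def entropy_curve(C: CooccurrenceMatrix) -> EntropyProfile:
    """Second-order entropy profile H_O, H_B, H_T over thresholds 0..L−1.

    Implemented with 2-D cumulative sums of p and p·log₂p, so each
    threshold's quadrant sums are O(1).
    """
    p = C.probs
    L = C.L
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    cp = p.cumsum(axis=0).cumsum(axis=1)
    cl = plogp.cumsum(axis=0).cumsum(axis=1)
    total_p, total_l = cp[-1, -1], cl[-1, -1]

    t = np.arange(L)  # thresholds 0..L-1
    # background quadrant: i ≤ t, j ≤ t
    bg_p, bg_l = cp[t, t], cl[t, t]
    # object quadrant: i > t, j > t (inclusion–exclusion on the suffix block)
    ob_p = total_p - cp[t, -1] - cp[-1, t] + cp[t, t]
    ob_l = total_l - cl[t, -1] - cl[-1, t] + cl[t, t]
    h_b = _quadrant_entropy(bg_p, bg_l)
    h_o = _quadrant_entropy(np.maximum(ob_p, 0.0), ob_l)
    # cross quadrants (object→background plus background→object), exposed only
    cr_p = np.maximum(total_p - bg_p - ob_p, 0.0)
    cr_l = total_l - bg_l - ob_l
    h_c = _quadrant_entropy(cr_p, cr_l)
    return EntropyProfile(h_object=h_o, h_background=h_b, h_total=h_o + h_b, h_cross=h_c)


def optimal_threshold(E: EntropyProfile) -> int:
    """argmax_t H_T(t); ties resolved to the smallest t."""
    h = np.asarray(E.h_total)
    if h.size == 0:
        raise ValueError("empty entropy profile")
    if np.allclose(h, h[0]):
        log.warning("flat entropy profile; threshold defaults to 0")
        return 0
    return int(np.argmax(h))


def binarize(
    q: QuantizedImage,
    t_opt: int,
    scale: float,
    fov: FovMask | None = None,
) -> np.ndarray:
    """Threshold at scale·t_opt: pixel true iff level ≥ scale·t_opt, in FOV.

    ``scale`` selects the regime: mask extraction uses 0.3–0.8 (default 0.5,
    generous mask), central-reflex recovery uses 0.8–3 (default 1.5, strict).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    thr = scale * t_opt
    if thr > q.L:
        log.warning("scaled threshold %.1f exceeds L=%d; mask is empty", thr, q.L)
        mask = np.zeros(q.levels.shape, dtype=bool)
    else:
        mask = q.levels >= thr
    if fov is not None:
        mask = mask & fov.pixels
    return mask
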