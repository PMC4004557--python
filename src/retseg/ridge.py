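"""Single-scale Hessian eigenvalue ridge enhancement (Frangi-style vesselness).

A vessel rendered bright by the top-hat preprocessing is a ridge: across the
vessel the second derivative is strongly negative, along it near zero.  The
Gaussian-scale Hessian captures this; its eigenvalues, ordered by magnitude
|λ1| ≤ |λ2|, feed the two-term 2-D vesselness

    V = exp(−R_b² / 2β²) · (1 − exp(−S² / 2c²)),   λ2 < 0
    V = 0                                          otherwise,

with R_b = λ1/λ2 (blob-vs-line anisotropy) and S = sqrt(λ1² + λ2²)
(second-order structure strength).  A single scale σ is used; DRIVE-scale
vessels span roughly 1–10 px, and σ = 1.5 px responds across that range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import GrayImage

__all__ = ["EigenField", "VesselnessImage", "hessian_eigen", "vesselness"]


@dataclass(frozen=True)
class EigenField:
    """Per-pixel 2×2 Hessian eigendecomposition, γ-normalized by σ².

    lambda1/lambda2 are ordered by magnitude (|λ1| ≤ |λ2|); v1 is the unit
    eigenvector of λ1, i.e. the local along-ridge direction on a vessel.
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    v1: np.ndarray  # H×W×2 unit vectors, (row, col) components
    scale: float


@dataclass(frozen=True)
class VesselnessImage:
    pixels: np.ndarray
    beta: float
    c: float


def hessian_eigen(gray: GrayImage, sigma: float = 1.5) -> EigenField:
    """Gaussian-derivative Hessian and its closed-form eigendecomposition.

    The three second derivatives are computed by Gaussian derivative filters
    at scale ``sigma`` and multiplied by σ² (γ-normalization, γ = 2) so that
    responses are comparable across scales.  The symmetric 2×2 eigensystem is
    solved in closed form per pixel.
    """
    if sigma < 0.5:
        raise ValueError(f"sigma {sigma} below minimum 0.5")
    f = np.asarray(gray.pixels, dtype=np.float64)
    if not np.isfinite(f).all():
        raise ValueError("non-finite input image")
    s2 = sigma * sigma
    # the sampled second-derivative Gaussian kernel has a small DC gain
    # (its weights do not sum exactly to zero); subtract it so constants
    # have an exactly zero Hessian
    probe = np.ones(2 * int(4.0 * sigma + 0.5) + 3)
    dc2 = ndi.gaussian_filter1d(probe, sigma, order=2, mode="nearest")[len(probe) // 2]
    # axis 0 = rows (y), axis 1 = cols (x)
    hrr = s2 * (ndi.gaussian_filter(f, sigma, order=(2, 0), mode="nearest") - dc2 * f)
    hcc = s2 * (ndi.gaussian_filter(f, sigma, order=(0, 2), mode="nearest") - dc2 * f)
    hrc = s2 * ndi.gaussian_filter(f, sigma, order=(1, 1), mode="nearest")

    # eigenvalues of [[hrr, hrc], [hrc, hcc]]
    tr_half = 0.5 * (hrr + hcc)
    disc = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc**2, 0.0))
    e_lo = tr_half - disc  # algebraically smaller
    e_hi = tr_half + disc
    # order by magnitude
    swap = np.abs(e_lo) > np.abs(e_hi)
    lam1 = np.where(swap, e_hi, e_lo)
    lam2 = np.where(swap, e_lo, e_hi)

    # eigenvector for lam1: (H - lam1 I) v = 0 has two row equations;
    # take whichever candidate vector has the larger norm for stability
    ar, ac = hrc, lam1 - hrr
    br, bc = lam1 - hcc, hrc
    use_a = np.hypot(ar, ac) >= np.hypot(br, bc)
    vr = np.where(use_a, ar, br)
    vc = np.where(use_a, ac, bc)
    norm = np.hypot(vr, vc)
    degenerate = norm < 1e-12  # isotropic point: any direction serves
    vr = np.where(degenerate, 1.0, vr / np.where(degenerate, 1.0, norm))
    vc = np.where(degenerate, 0.0, vc / np.where(degenerate, 1.0, norm))
    v1 = np.stack([vr, vc], axis=-1)
    return EigenField(lambda1=lam1, lambda2=lam2, v1=v1, scale=sigma)


def vesselness(
    eig: EigenField, beta: float = 0.5, c: float | str = "auto"
) -> VesselnessImage:
    """Two-term Frangi response for bright ridges (λ2 < 0), rescaled to [0, 1].

    ``c='auto'`` sets the structure-norm scale to half the maximum Frobenius
    norm of the Hessian over the image, the usual data-driven choice.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    lam1, lam2 = eig.lambda1, eig.lambda2
    S = np.hypot(lam1, lam2)
    if c == "auto":
        c_val = 0.5 * S.max()
        if c_val <= 0:
            c_val = 1.0
    else:
        c_val = float(c)
        if c_val <= 0:
            raise ValueError("c must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(np.abs(lam2) > 0, lam1 / lam2, 0.0)
    resp = np.exp(-(rb**2) / (2.0 * beta**2)) * (1.0 - np.exp(-(S**2) / (2.0 * c_val**2)))
    resp = np.where(lam2 < 0, resp, 0.0)
    m = resp.max()
    if m > 0:
        resp = resp / m
    return VesselnessImage(pixels=resp, beta=beta, c=c_val)
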