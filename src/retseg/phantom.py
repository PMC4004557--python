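"""Synthetic fundus phantoms with exhaustive pixel-level ground truth.

The phantom emulates the features of a colour fundus photograph that the
segmentation pipeline actually exercises: a bright circular field of view,
dark curvilinear vessels of known width in the green channel (optionally
carrying a brighter central-light-reflex core line), a smooth multiplicative
illumination gradient, fine-grained speckle noise on one image half and
coarse-grained blob noise on the other (so the texture partition has an
unambiguous ground truth), and optional bright pathology blobs.  Every
generated image comes with its gold vessel mask, a centreline/width table,
the true texture partition, vessel edge-point pairs and the analytic FOV
disc.  All randomness flows from the spec's seed, so fixtures are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .io import ColorFundusImage, FovMask
from .texture import COARSE, FINE, TexturePartition

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "generate_bar", "generate_taper"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic fundus generator (defaults = study conditions)."""

    size: tuple = (256, 256)
    n_vessels: int = 4
    width_range: tuple = (2.0, 8.0)
    tortuosity: float = 0.15  # rad of direction drift per step, pre-smoothing
    reflex: bool = False
    reflex_depth: float = 0.5  # fraction of vessel contrast restored at the core
    reflex_core_width: float = 1.0  # px
    background: float = 0.65  # green-channel background level inside the FOV
    vessel_contrast: float = 0.25  # green-channel dip at the vessel centre
    illum_gradient: float = 0.2  # multiplicative amplitude in [0, 0.5]
    fine_noise: tuple = (0.08, 3)  # (density, max granule diameter px)
    coarse_noise: tuple = (0.04, 12)  # (density, granule diameter 8..20 px)
    pathology_blobs: int = 0
    pathology_radius: tuple = (6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_range[0] < 1:
            raise ValueError("vessel widths must be ≥ 1 px")
        if self.width_range[1] > min(self.size):
            raise ValueError("vessel width exceeds image size")
        if not (0.0 <= self.illum_gradient <= 0.5):
            raise ValueError("illum_gradient outside [0, 0.5]")
        for dens, _ in (self.fine_noise, self.coarse_noise):
            if not (0.0 <= dens <= 1.0):
                raise ValueError("noise density outside [0, 1]")


@dataclass(frozen=True)
class PhantomTruth:
    gold_mask: np.ndarray
    centreline_widths: list  # (x, y, true_width)
    partition_truth: TexturePartition
    edge_points: list  # ((xa, ya), (xb, yb)) pairs
    fov: FovMask
    green_plane: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _fov_disc(size: tuple) -> np.ndarray:
    h, w = size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = 0.45 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _vessel_path(rng: np.random.Generator, size: tuple, tortuosity: float) -> np.ndarray:
    """Smooth random curve crossing the FOV, sampled at ~1 px steps."""
    h, w = size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = 0.45 * min(h, w)
    theta0 = rng.uniform(0, 2 * np.pi)
    x, y = cx + r * np.cos(theta0), cy + r * np.sin(theta0)
    heading = theta0 + np.pi + rng.uniform(-0.5, 0.5)  # roughly inward
    n_steps = int(3 * r)
    drift = rng.normal(0.0, tortuosity, n_steps)
    kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
    drift = np.convolve(drift, kernel / kernel.sum(), mode="same")
    pts = []
    for k in range(n_steps):
        pts.append((x, y))
        heading += drift[k]
        x += np.cos(heading)
        y += np.sin(heading)
        if (x - cx) ** 2 + (y - cy) ** 2 > (1.05 * r) ** 2 and k > 10:
            break
    return np.asarray(pts)


def _speckle(rng, img, half_mask, density, dia_lo, dia_hi, amplitude):
    """Scatter dark granules of the given diameter range over one half."""
    h, w = img.shape
    area = half_mask.sum()
    mean_granule = np.pi * ((dia_lo + dia_hi) / 4.0) ** 2
    n = max(1, int(density * area / max(mean_granule, 1.0)))
    ys, xs = np.nonzero(half_mask)
    idx = rng.integers(0, len(ys), n)
    yy, xx = np.mgrid[0:h, 0:w]
    for i in idx:
        rad = rng.uniform(dia_lo / 2.0, dia_hi / 2.0)
        amp = rng.uniform(0.5, 1.0) * amplitude
        cy, cx = ys[i], xs[i]
        sl = (slice(max(0, cy - int(rad) - 1), cy + int(rad) + 2),
              slice(max(0, cx - int(rad) - 1), cx + int(rad) + 2))
        d2 = (yy[sl] - cy) ** 2 + (xx[sl] - cx) ** 2
        img[sl] -= amp * (d2 <= rad * rad)
    return img


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Build a synthetic colour fundus image and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    fov = _fov_disc(spec.size)
    yy, xx = np.mgrid[0:h, 0:w]

    green = np.full((h, w), spec.background, dtype=np.float64)

    # vessels: distance to the nearest centreline sample governs the band
    gold = np.zeros((h, w), dtype=bool)
    centreline_widths: list = []
    edge_points: list = []
    vessel_drop = np.zeros((h, w), dtype=np.float64)
    for _ in range(spec.n_vessels):
        path = _vessel_path(rng, spec.size, spec.tortuosity)
        width = rng.uniform(*spec.width_range)
        tree = cKDTree(path)
        pix = np.stack([xx.ravel(), yy.ravel()], axis=1)
        d, _ = tree.query(pix, distance_upper_bound=width / 2.0 + 3.0)
        d = d.reshape(h, w)
        band = d <= width / 2.0
        gold |= band & fov
        # smooth cross-section: Gaussian with FWHM equal to the vessel
        # width, as in the matched-filter vessel models of the field;
        # narrow vessels (< 3 px) keep a flat 1-px core so they do not
        # vanish under the sampling grid
        sigma_v = max(width, 2.0) / 2.355
        profile = np.where(np.isfinite(d), np.exp(-np.square(np.where(np.isfinite(d), d, 0.0)) / (2.0 * sigma_v**2)), 0.0)
        drop = spec.vessel_contrast * profile
        if spec.reflex:
            core = np.clip(spec.reflex_core_width / 2.0 + 0.5 - d, 0.0, 1.0)
            drop -= spec.reflex_depth * spec.vessel_contrast * core
        vessel_drop = np.maximum(vessel_drop, drop)
        # truth tables, sampled along the path inside the FOV
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        r_fov = 0.45 * min(h, w)
        half = (width - 1) / 2.0  # outermost pixel-centre offset of the band
        for k in range(5, len(path) - 5):
            x, y = path[k]
            if (x - cx) ** 2 + (y - cy) ** 2 > (r_fov - max(2.0, width / 2.0)) ** 2:
                continue
            centreline_widths.append((float(x), float(y), float(width)))
            if k % 2 == 0:
                t = path[min(k + 1, len(path) - 1)] - path[max(k - 1, 0)]
                t = t / np.linalg.norm(t)
                nx, ny = -t[1], t[0]
                edge_points.append(
                    (
                        (x + nx * half, y + ny * half),
                        (x - nx * half, y - ny * half),
                    )
                )
    green -= vessel_drop

    # background noise: fine speckle left half, coarse blobs right half
    left = fov & (xx < w // 2)
    right = fov & (xx >= w // 2)
    fine_density, fine_granule = spec.fine_noise
    coarse_density, coarse_granule = spec.coarse_noise
    # granule dip amplitude ~10–20% of vessel contrast, the ratio seen in
    # fundus-camera background mottle relative to vessel contrast
    if fine_density > 0:
        green = _speckle(rng, green, left, fine_density, 1, fine_granule,
                         0.16 * spec.vessel_contrast)
    if coarse_density > 0:
        green = _speckle(
            rng, green, right, coarse_density,
            max(8, coarse_granule - 4), min(20, coarse_granule + 4),
            0.12 * spec.vessel_contrast,
        )

    # bright pathology blobs
    for _ in range(spec.pathology_blobs):
        rad = rng.uniform(*spec.pathology_radius)
        ys, xs = np.nonzero(fov)
        i = rng.integers(0, len(ys))
        d2 = (yy - ys[i]) ** 2 + (xx - xs[i]) ** 2
        green += 0.15 * np.exp(-d2 / (2.0 * (rad / 2.0) ** 2))

    # multiplicative illumination gradient, left-to-right
    if spec.illum_gradient > 0:
        ramp = 1.0 + spec.illum_gradient * (2.0 * xx / (w - 1) - 1.0)
        green *= ramp

    green = np.clip(green, 0.0, 1.0)
    green[~fov] *= 0.02  # near-black outside the field of view
    red = np.clip(green * 1.25 + 0.05, 0.0, 1.0) * fov
    blue = np.clip(green * 0.55, 0.0, 1.0) * fov

    img = ColorFundusImage(
        pixels=np.stack([red, green, blue], axis=-1), source_path="<phantom>"
    )
    partition = np.zeros((h, w), dtype=np.int32)
    partition[left] = FINE
    partition[right] = COARSE
    truth = PhantomTruth(
        gold_mask=gold,
        centreline_widths=centreline_widths,
        partition_truth=TexturePartition(
            labels=partition, connectivity_threshold={FINE: 5, COARSE: 16}
        ),
        edge_points=edge_points,
        fov=FovMask(fov),
        green_plane=green,
    )
    return img, truth


def generate_bimodal(
    seed: int,
    modes: tuple = (3.0, 12.0),
    spread: float = 1.2,
    L: int = 15,
    salt: float = 0.05,
    size: tuple = (64, 64),
) -> tuple:
    """Two-mode test image for threshold selection.

    Half the pixels draw from a Gaussian around each mode (in units of gray
    levels out of ``L``); a ``salt`` fraction is set to the maximum.
    Returns (image in [0,1], high_mode_mask) where the mask marks the pixels
    drawn from the upper mode.
    """
    rng = np.random.default_rng(seed)
    lo, hi = modes
    high = rng.random(size) < 0.5
    vals = np.where(
        high, rng.normal(hi, spread, size), rng.normal(lo + 0.5, spread, size)
    )
    saltpix = rng.random(size) < salt
    vals[saltpix] = float(L)
    return np.clip(vals / L, 0.0, 1.0), high & ~saltpix


def generate_bar(
    width: float, angle: float, length: float, size: tuple = (64, 64)
) -> tuple:
    """Oriented bar whose perpendicular thickness is the requested width.

    Returns (mask, true_width).  The bar passes through the grid centre at
    the given angle (degrees, 0 = horizontal).
    """
    if width < 1:
        raise ValueError("width must be ≥ 1")
    h, w = size
    cy, cx = h // 2, w // 2
    theta = np.deg2rad(angle)
    ux, uy = np.cos(theta), np.sin(theta)
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    along = dx * ux + dy * uy
    perp = -dx * uy + dy * ux
    mask = (np.abs(perp) <= width / 2.0) & (np.abs(along) <= length / 2.0)
    return mask, float(width)


def generate_taper(
    width_start: float, width_end: float, length: int, size: tuple = (64, 96)
) -> tuple:
    """Horizontal bar whose width tapers linearly from start to end.

    Returns (mask, width_table) with width_table a list of (x, y, width).
    """
    h, w = size
    cy = h // 2
    x0 = (w - length) // 2
    yy, xx = np.mgrid[0:h, 0:w]
    frac = np.clip((xx - x0) / max(length - 1, 1), 0.0, 1.0)
    local_w = width_start + (width_end - width_start) * frac
    mask = (np.abs(yy - cy) <= local_w / 2.0) & (xx >= x0) & (xx < x0 + length)
    table = [
        (float(x), float(cy), float(width_start + (width_end - width_start) * (x - x0) / max(length - 1, 1)))
        for x in range(x0, x0 + length)
    ]
    return mask, table
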