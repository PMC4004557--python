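"""Segmentation orchestration: routing the pipeline steps by image class.

Fundus photographs fall into three classes and each gets a different subset
of the five pipeline steps:

  class 1 — uniform illumination, well-localised central reflex: steps 2+5
  class 2 — uniform illumination, vessels broken by the reflex:   steps 2+3+5
  class 3 — non-uniform illumination and/or pathology:            steps 1–5

Step 1 is the texture partition, step 2 the curvature/entropy extraction
(top-hat → Hessian vesselness → entropy mask → product → global threshold),
step 3 the texture-adaptive connectivity filter, step 4 the strict
reflex-regime binarization, and step 5 the superposition + radius-2 closing
that fuses the reflex vessels back in and clips to the FOV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.morphology import disk

from . import entropy as ent
from .config import DEFAULTS, ResolvedConfig
from .io import (ColorFundusImage, FovMask, GrayImage, compute_fov_mask,
                 extract_green, extract_luma, tophat_preprocess)
from .ridge import VesselnessImage, hessian_eigen, vesselness
from .texture import TexturePartition, partition_texture

log = logging.getLogger(__name__)

__all__ = [
    "ImageClass",
    "SegmentationResult",
    "combine_enhanced_mask",
    "global_threshold",
    "connectivity_filter",
    "recover_central_reflex",
    "segment_retina",
]


class ImageClass(Enum):
    CLASS1 = 1
    CLASS2 = 2
    CLASS3 = 3

    @property
    def steps(self) -> frozenset:
        return {
            ImageClass.CLASS1: frozenset({2, 5}),
            ImageClass.CLASS2: frozenset({2, 3, 5}),
            ImageClass.CLASS3: frozenset({1, 2, 3, 4, 5}),
        }[self]


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    steps_applied: frozenset
    params: dict
    fov: FovMask
    partition: TexturePartition | None = field(default=None, repr=False)
    intermediates: dict = field(default_factory=dict, repr=False)


def _clip_to_fov(pre: GrayImage, fov: FovMask, margin: int = 2) -> GrayImage:
    """Zero the preprocessed image outside the slightly eroded FOV.

    The black top-hat raises a bright ring just outside the FOV rim (the
    closing fills the dark surround near the disc edge); left in place it
    would dominate the vesselness normalisation and the entropy statistics,
    which is exactly the rim artefact the dedicated FOV mask exists to
    remove.
    """
    interior = ndi.binary_erosion(fov.pixels, iterations=margin) if margin else fov.pixels
    p = pre.pixels * interior
    m = p.max()
    return GrayImage(p / m if m > 0 else p)


def combine_enhanced_mask(vessel: VesselnessImage, mask: np.ndarray) -> GrayImage:
    """Elementwise product of the vesselness image with a 0/1 mask."""
    mask = np.asarray(mask, bool)
    if vessel.pixels.shape != mask.shape:
        raise ValueError("shape mismatch between vesselness and mask")
    return GrayImage(vessel.pixels * mask)


def global_threshold(img: GrayImage, t: float = 0.1) -> np.ndarray:
    """Pixel true iff intensity > t (operating range 0.04–0.2)."""
    if not (0.04 <= t <= 0.2):
        raise ValueError(f"global threshold {t} outside [0.04, 0.2]")
    return img.pixels > t


def connectivity_filter(
    mask: np.ndarray,
    partition: TexturePartition | None,
    min_fine: int = 5,
    min_coarse: int = 16,
) -> np.ndarray:
    """Remove small connected components, with a texture-adaptive size cut.

    Each 8-connected component is assigned to the texture label covering the
    majority of its pixels and removed when its pixel count is ≤ that
    label's threshold (strictly "larger than" survives).  Without a
    partition a single global threshold ``min_fine`` applies.
    """
    if not (5 <= min_fine <= min_coarse <= 16):
        raise ValueError("need 5 ≤ min_fine ≤ min_coarse ≤ 16")
    mask = np.asarray(mask, bool)
    lab, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return mask.copy()
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    if partition is None:
        cut = np.full(n, min_fine, dtype=float)
    else:
        thr = partition.connectivity_threshold
        fine_thr = thr.get(1, min_fine)
        coarse_thr = thr.get(2, min_coarse)
        # majority texture label per component
        fine_count = ndi.sum_labels(
            (partition.labels == 1).astype(float), lab, index=np.arange(1, n + 1)
        )
        coarse_count = ndi.sum_labels(
            (partition.labels == 2).astype(float), lab, index=np.arange(1, n + 1)
        )
        cut = np.where(coarse_count > fine_count, coarse_thr, fine_thr)
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes > cut
    return keep[lab]


def recover_central_reflex(
    curv_seg: np.ndarray,
    reflex_seg: np.ndarray | None,
    image_class: ImageClass,
) -> np.ndarray:
    """Fuse the reflex-regime segmentation and close the reflex gap.

    Class 1: the gap is thin, a radius-2 disc closing of the curvature
    segmentation alone suffices.  Classes 2–3: pixelwise OR with the strict
    entropy segmentation, then the same radius-2 closing.
    """
    curv_seg = np.asarray(curv_seg, bool)
    if image_class is ImageClass.CLASS1 or reflex_seg is None:
        fused = curv_seg
    else:
        reflex_seg = np.asarray(reflex_seg, bool)
        if reflex_seg.shape != curv_seg.shape:
            raise ValueError("shape mismatch between segmentations")
        fused = curv_seg | reflex_seg
    return morphology.closing(fused, disk(2))


def segment_retina(
    color: ColorFundusImage,
    params: ResolvedConfig | dict | None = None,
    image_class: ImageClass = ImageClass.CLASS3,
) -> SegmentationResult:
    """Run the class-routed segmentation pipeline on a colour fundus image."""
    if params is None:
        cfg = dict(DEFAULTS)
    elif isinstance(params, ResolvedConfig):
        cfg = dict(params.values)
    else:
        cfg = {**DEFAULTS, **params}
    steps = image_class.steps
    inter: dict = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    green = stage("extract_green", extract_green, color)
    fov = stage("fov", compute_fov_mask, green, cfg["fov.sobel_threshold"])
    pre = stage("tophat", tophat_preprocess, green, cfg["preprocess.tophat_radius"])
    pre = _clip_to_fov(pre, fov)
    inter["preprocessed"] = pre

    partition = None
    if 1 in steps:
        partition = stage(
            "texture_partition",
            partition_texture,
            pre,
            fov,
            levels=cfg["texture.levels"],
            k=cfg["texture.k"],
            hminima=cfg["texture.hminima"],
            presmooth_radius=cfg["texture.presmooth_radius"],
            override=cfg["texture.override"],
            min_fine=cfg["segment.min_fine"],
            min_coarse=cfg["segment.min_coarse"],
            seed=cfg["seed"],
        )
        inter["partition"] = partition

    # step 2: curvature enhancement × entropy mask, globally thresholded
    eig = stage("hessian", hessian_eigen, pre, cfg["enhance.sigma"])
    ves = stage("vesselness", vesselness, eig, cfg["enhance.beta"], cfg["enhance.c"])
    q = stage("quantize", ent.quantize, pre, cfg["entropy.L"])
    C = stage("cooccurrence", ent.cooccurrence, q)
    prof = stage("entropy_curve", ent.entropy_curve, C)
    t_opt = stage("optimal_threshold", ent.optimal_threshold, prof)
    emask = stage("entropy_mask", ent.binarize, q, t_opt, cfg["entropy.mask_scale"], fov)
    product = stage("combine", combine_enhanced_mask, ves, emask)
    curv_seg = stage("global_threshold", global_threshold, product, cfg["segment.global_threshold"])
    curv_seg &= fov.pixels
    inter.update(vesselness=ves, entropy_mask=emask, t_opt=t_opt, curv_seg=curv_seg.copy())

    # step 3: texture-adaptive connectivity filter
    if 3 in steps:
        curv_seg = stage(
            "connectivity_filter",
            connectivity_filter,
            curv_seg,
            partition,
            cfg["segment.min_fine"],
            cfg["segment.min_coarse"],
        )
        inter["filtered_seg"] = curv_seg.copy()

    # step 4 (and the class-2 entropy-filtering variant): strict reflex regime
    reflex_seg = None
    if 4 in steps or (image_class is ImageClass.CLASS2 and cfg["segment.class2_reflex"]):
        if cfg["entropy.reflex_channel"] == "luma":
            src = stage("tophat_luma", tophat_preprocess, extract_luma(color),
                        cfg["preprocess.tophat_radius"])
            q_r = stage("quantize_luma", ent.quantize, src, cfg["entropy.L"])
            C_r = stage("cooccurrence_luma", ent.cooccurrence, q_r)
            t_r = stage("optimal_threshold_luma", ent.optimal_threshold,
                        stage("entropy_curve_luma", ent.entropy_curve, C_r))
        else:
            q_r, t_r = q, t_opt
        reflex_seg = stage(
            "reflex_binarize", ent.binarize, q_r, t_r, cfg["entropy.reflex_scale"], fov
        )
        # the larger threshold targets pixels near the centrelines of
        # reflex-affected vessels: keep only the halo of the curvature
        # segmentation so isolated background clutter is not resurrected
        halo = cfg["segment.reflex_dilation"]
        if halo > 0:
            reflex_seg &= morphology.dilation(curv_seg, disk(halo))
        reflex_seg = stage(
            "reflex_filter",
            connectivity_filter,
            reflex_seg,
            partition,
            cfg["segment.min_fine"],
            cfg["segment.min_coarse"],
        )
        inter["reflex_seg"] = reflex_seg

    # step 5: superposition + radius-2 closing, final FOV clip
    final = stage("recover", recover_central_reflex, curv_seg, reflex_seg, image_class)
    final &= fov.pixels

    return SegmentationResult(
        mask=final,
        steps_applied=steps,
        params=cfg,
        fov=fov,
        partition=partition,
        intermediates=inter,
    )
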