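"""Vessel segmentation and projection-artifact removal.

The averaged registered image is turned into a per-pixel vessel
probability map, binarized at 0.5, and used to mask the registered stack
so background noise does not contribute to the temporal statistics.  The
probability-map producer is a deterministic multiscale-vesselness +
contrast-normalization segmenter; the interface is pluggable, so a
learned segmenter emitting the same [0, 1] map can be dropped in.

Large superficial vessels project ghost images into the deep layer;
their footprint is excluded (not merely zeroed) from all deep-layer
quantification.
"""
from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import binary_dilation, binary_opening, gaussian_filter
from scipy.special import expit
from skimage.filters import sato, threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .datatypes import (
    LARGE_VESSEL_THRESHOLD_PX,
    ImageStack,
    ProbabilityMap,
    RegisteredStack,
    VesselMask,
)

__all__ = [
    "segment_vessels",
    "binarize_and_mask",
    "large_vessel_footprint",
    "remove_projection_artifacts",
]


def segment_vessels(image: np.ndarray,
                    scales: Sequence[float] = (1.0, 2.0, 4.0),
                    vesselness_weight: float = 0.3,
                    background_sigma: float = 25.0,
                    noise_floor: float = 0.02) -> ProbabilityMap:
    """Per-pixel vessel confidence from intensity + multiscale tubularity.

    The image is background-flattened (subtraction of a wide Gaussian),
    split from background with a multi-Otsu threshold (three classes —
    background, capillaries, saturated large vessels — taking the lowest
    split so the bright large-vessel mode cannot absorb the capillary
    class) turned into a soft logistic probability, and blended with a
    per-scale-normalized Sato tubularity response so thin bright tubular
    structures score above the 0.5 binarization threshold.
    Deterministic; a constant (or near-constant, below ``noise_floor``
    dynamic range) image yields an all-zero map.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("segment_vessels expects a 2-D image")

    bs = image - gaussian_filter(image, background_sigma)
    if bs.max() - bs.min() < noise_floor:
        return ProbabilityMap(np.zeros_like(image))

    try:
        thr = threshold_multiotsu(bs, classes=3)[0]
    except ValueError:  # too few distinct values for 3 classes
        thr = threshold_otsu(bs)
    thr = max(thr, noise_floor)
    p_int = expit((bs - thr) / (0.25 * thr))

    vesselness = np.zeros_like(image)
    for s in scales:
        resp = np.clip(sato(image, sigmas=[s], black_ridges=False), 0, None)
        m = np.percentile(resp, 99.5)
        if m >= noise_floor:
            vesselness = np.maximum(vesselness, np.clip(resp / m, 0.0, 1.0))

    p = np.clip((1.0 - vesselness_weight) * p_int
                + vesselness_weight * vesselness, 0.0, 1.0)
    return ProbabilityMap(p)


def binarize_and_mask(pmap: ProbabilityMap, stack: RegisteredStack,
                      threshold: float = 0.5
                      ) -> tuple[VesselMask, np.ndarray]:
    """Threshold the probability map and mask every registered frame.

    Returns the binary mask and the frame-wise product of the registered
    stack with it.  Masking is idempotent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if pmap.values.shape != stack.frames.shape[1:]:
        raise ValueError("probability map and stack shapes disagree")
    mask = VesselMask(pmap.values >= threshold, threshold=threshold)
    masked = stack.frames * mask.values[None].astype(float)
    return mask, masked


def large_vessel_footprint(svc_mask: np.ndarray,
                           width_threshold_px: int = LARGE_VESSEL_THRESHOLD_PX,
                           margin_px: int = 2) -> np.ndarray:
    """Footprint of SVC vessels wider than ``width_threshold_px``.

    A morphological opening with a disk of radius ``width_threshold_px/2``
    keeps only structures at least that wide; the surviving footprint is
    dilated by ``margin_px`` so blurred ghost edges are caught too.
    """
    svc_mask = np.asarray(svc_mask).astype(bool)
    r = max(int(round(width_threshold_px / 2)), 1)
    wide = binary_opening(svc_mask, structure=disk(r))
    if margin_px > 0:
        wide = binary_dilation(wide, structure=disk(margin_px))
    return wide


def remove_projection_artifacts(
        dvc_stack: Union[ImageStack, np.ndarray],
        svc_segmentation: Union[ProbabilityMap, VesselMask, np.ndarray],
        width_threshold_px: int = LARGE_VESSEL_THRESHOLD_PX,
        margin_px: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Excise large-SVC-vessel ghosts from every deep-layer frame.

    Returns ``(frames, invalid)`` where the footprint pixels are zeroed in
    every frame and flagged in ``invalid`` so they can be excluded from
    the denominators of all downstream metrics (zeros alone would corrupt
    the temporal means).  Capillary-scale SVC vessels leave the deep
    layer untouched.
    """
    frames = dvc_stack.frames if isinstance(dvc_stack, ImageStack) \
        else np.asarray(dvc_stack, dtype=float)
    if isinstance(svc_segmentation, ProbabilityMap):
        svc_mask = svc_segmentation.values >= 0.5
    elif isinstance(svc_segmentation, VesselMask):
        svc_mask = svc_segmentation.values
    else:
        svc_mask = np.asarray(svc_segmentation).astype(bool)
    if svc_mask.shape != frames.shape[1:]:
        raise ValueError("SVC segmentation and DVC stack are on "
                         "different grids")
    footprint = large_vessel_footprint(svc_mask, width_threshold_px,
                                       margin_px)
    out = frames.copy()
    out[:, footprint] = 0.0
    return out, footprint
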