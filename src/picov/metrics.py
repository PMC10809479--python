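"""Perfusion heterogeneity and density metrics.

The pixel intensity coefficient of variation (PICoV) is the ratio of the
temporal standard deviation to the temporal mean of a pixel's intensity
series across the registered frames — the package's core heterogeneity
measure.  Perfusion density (PD) is the ones:zeros pixel ratio of a
binarized frame; vessel density (VD) is the same ratio computed on the
1-px skeleton, so PD reflects vessel area while VD reflects only the
amount of centerline.
"""
from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np
from matplotlib import colormaps
from skimage.morphology import skeletonize

from .datatypes import (
    OD,
    TEMPORAL_SIDE_MAP,
    DensitySeries,
    PICoVMap,
    ProbabilityMap,
    QuadrantSummary,
)

__all__ = [
    "compute_picov_map",
    "summarize_picov",
    "colorize_picov",
    "compute_density_series",
]

#: pixels whose temporal mean is below this fraction of full scale are
#: excluded from PICoV: a near-zero denominator measures noise, not flow
MEAN_FLOOR = 0.01


def compute_picov_map(masked_stack: np.ndarray,
                      validity: Optional[np.ndarray] = None,
                      ddof: int = 1,
                      mean_floor: float = MEAN_FLOOR) -> PICoVMap:
    """Per-pixel temporal coefficient of variation over the frame axis.

    For each valid pixel, CV = sample SD (``ddof`` defaults to 1) divided
    by the temporal mean of its T-length intensity series.  Pixels whose
    mean falls at or below ``mean_floor`` are marked invalid rather than
    producing unstable ratios.
    """
    frames = np.asarray(masked_stack, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a T x H x W stack with T >= 2")
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0, ddof=ddof)
    valid = mean > mean_floor
    if validity is not None:
        valid &= np.asarray(validity).astype(bool)
    values = np.zeros_like(mean)
    values[valid] = sd[valid] / mean[valid]
    return PICoVMap(values=values, validity=valid)


def _quadrant_blocks(h: int, w: int) -> dict:
    """Equal half-split blocks as (row slice, col slice)."""
    return {
        "top_left": (slice(0, h // 2), slice(0, w // 2)),
        "top_right": (slice(0, h // 2), slice(w // 2, w)),
        "bottom_left": (slice(h // 2, h), slice(0, w // 2)),
        "bottom_right": (slice(h // 2, h), slice(w // 2, w)),
    }


def summarize_picov(pmap: PICoVMap, laterality: str = OD,
                    reduction: str = "mean",
                    temporal_side_map: dict = TEMPORAL_SIDE_MAP
                    ) -> tuple[float, QuadrantSummary]:
    """Eye-level PICoV scalar and the four 3 x 3 mm quadrant summaries.

    The eye-level value is the mean (or median via ``reduction``) of CV
    over valid pixels.  Quadrants are the equal half-split blocks of the
    fovea-centred scan; the image top is superior, and which lateral half
    is temporal depends on eye laterality through ``temporal_side_map``.
    An empty quadrant yields NaN (reported missing, never zero).
    """
    if reduction not in ("mean", "median"):
        raise ValueError("reduction must be 'mean' or 'median'")
    reduce = np.mean if reduction == "mean" else np.median
    vals, valid = pmap.values, pmap.validity
    if not valid.any():
        raise ValueError("no valid pixels in PICoV map")
    eye = float(reduce(vals[valid]))

    temporal_side = temporal_side_map[laterality]
    h, w = vals.shape
    blocks = _quadrant_blocks(h, w)
    if temporal_side == "left":
        names = {"ST": "top_left", "SN": "top_right",
                 "IT": "bottom_left", "IN": "bottom_right"}
    else:
        names = {"ST": "top_right", "SN": "top_left",
                 "IT": "bottom_right", "IN": "bottom_left"}
    q = {}
    counts = {}
    for quad, block in names.items():
        sl = blocks[block]
        v = valid[sl]
        counts[quad] = int(v.sum())
        q[quad] = float(reduce(vals[sl][v])) if v.any() else math.nan
    return eye, QuadrantSummary(picov_ST=q["ST"], picov_SN=q["SN"],
                                picov_IT=q["IT"], picov_IN=q["IN"],
                                counts=counts)


def colorize_picov(pmap: PICoVMap, cap: float = 0.4,
                   cmap_name: str = "jet") -> np.ndarray:
    """False-colour rendering of a PICoV map.

    CV values are capped at ``cap`` and remapped to [0, 1] for dynamic
    range, then passed through a blue (no variation) to red (high
    variation) colormap.  Invalid pixels render black.  Returns an
    H x W x 3 uint8 image.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    pos = np.clip(pmap.values, 0.0, cap) / cap
    rgb = colormaps[cmap_name](pos)[..., :3]
    rgb[~pmap.validity] = 0.0
    return (rgb * 255).round().astype(np.uint8)


def compute_density_series(frames: np.ndarray,
                           segmenter: Optional[Callable[[np.ndarray],
                                                        ProbabilityMap]],
                           validity: Optional[np.ndarray] = None,
                           threshold: float = 0.5,
                           pd_definition: str = "ones_to_zeros"
                           ) -> DensitySeries:
    """Per-frame perfusion density and vessel density.

    Each frame is binarized by thresholding its ``segmenter`` probability
    map at ``threshold``, restricted to ``validity``.  PD is the
    ones:zeros pixel ratio among valid pixels; VD the same ratio after
    skeletonizing the binary frame to 1-px centerlines.  Passing
    ``segmenter=None`` bypasses segmentation and thresholds the frame
    itself (for already-binary input).  Means and sample SDs are taken
    over the frames.

    ``pd_definition`` selects the ones:zeros ratio (default, the
    convention this package follows) or the ones:total fraction used by
    some commercial OCTA software; the choice is recorded in the output.
    """
    if pd_definition not in ("ones_to_zeros", "ones_to_total"):
        raise ValueError("pd_definition must be 'ones_to_zeros' or "
                         "'ones_to_total'")
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    t = frames.shape[0]
    if validity is None:
        validity = np.ones(frames.shape[1:], dtype=bool)
    else:
        validity = np.asarray(validity).astype(bool)
    n_valid = validity.sum()
    if n_valid == 0:
        raise ValueError("validity mask excludes every pixel")

    pd = np.empty(t)
    vd = np.empty(t)
    for k in range(t):
        if segmenter is None:
            binary = frames[k] >= threshold
        else:
            binary = segmenter(frames[k]).values >= threshold
        binary = binary & validity
        ones = int(binary[validity].sum())
        zeros = int(n_valid - ones)
        if pd_definition == "ones_to_zeros" and zeros == 0:
            raise ZeroDivisionError(
                f"frame {k}: no '0' pixels among valid region")
        skel = skeletonize(binary)
        s_ones = int(skel[validity].sum())
        s_zeros = int(n_valid - s_ones)
        if pd_definition == "ones_to_zeros":
            pd[k] = ones / zeros
            vd[k] = s_ones / s_zeros
        else:
            pd[k] = ones / n_valid
            vd[k] = s_ones / n_valid

    sd = (lambda x: float(x.std(ddof=1)) if t > 1 else 0.0)
    return DensitySeries(pd=pd, vd=vd,
                         mean_pd=float(pd.mean()), sd_pd=sd(pd),
                         mean_vd=float(vd.mean()), sd_vd=sd(vd),
                         pd_definition=pd_definition)
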