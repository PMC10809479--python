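"""Core data containers shared across the pipeline.

All images are 2-D float arrays with intensities in [0, 1]; stacks are
T x H x W with frame index first. Displacement fields follow the pull-back
convention: ``warped(p) = moving(p + u(p))`` where ``u`` is the per-pixel
(dy, dx) vector stored as an H x W x 2 array on the template grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

#: default field of view of a macular scan, millimetres
DEFAULT_FOV_MM = 6.0
#: default scale at 500 px over 6 mm
DEFAULT_UM_PER_PX = 12.0
#: vessels at least this wide (px) are treated as large SVC vessels
LARGE_VESSEL_THRESHOLD_PX = 6

SVC = "SVC"
DVC = "DVC"
LAYERS = (SVC, DVC)

OD = "OD"
OS = "OS"

#: which image side (``"left"``/``"right"``) is the temporal retina for
#: each laterality.  The scan is fovea-centred so temporal/nasal mirror
#: between eyes; the mapping is a convention, not a measurement.
TEMPORAL_SIDE_MAP = {OD: "left", OS: "right"}


@dataclass
class ImageStack:
    """T co-located en-face OCTA frames for one eye and layer."""

    frames: np.ndarray  # T x H x W float in [0, 1]
    eye_id: str = "eye"
    layer: str = SVC
    laterality: str = OD
    group: str = "control"
    signal_strength: Optional[np.ndarray] = None  # per-frame int 0..10
    scale_um_per_px: float = DEFAULT_UM_PER_PX

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("a stack needs at least 2 frames")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValueError("frame intensities must be finite and >= 0")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.signal_strength is None:
            self.signal_strength = np.full(self.n_frames, 10, dtype=int)
        else:
            self.signal_strength = np.asarray(self.signal_strength, dtype=int)
            if self.signal_strength.shape != (self.n_frames,):
                raise ValueError("signal_strength must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def copy_with(self, frames: np.ndarray, **meta) -> "ImageStack":
        kwargs = dict(
            eye_id=self.eye_id,
            layer=self.layer,
            laterality=self.laterality,
            group=self.group,
            signal_strength=None if frames.shape[0] != self.n_frames
            else self.signal_strength.copy(),
            scale_um_per_px=self.scale_um_per_px,
        )
        kwargs.update(meta)
        return ImageStack(frames=frames, **kwargs)


@dataclass
class DisplacementField:
    """Dense warp mapping template coordinates to moving-frame positions."""

    vectors: np.ndarray  # H x W x 2, (dy, dx) in px

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 2:
            raise ValueError("vectors must be H x W x 2")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field must be finite")

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "DisplacementField":
        return cls(np.zeros((*shape, 2)))

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


@dataclass
class RegisteredStack:
    """Frames warped onto a common template grid, plus their average."""

    frames: np.ndarray  # T x H x W
    template_index: int
    shifts: np.ndarray  # T x 2 (dy, dx)
    fields: list  # per-frame DisplacementField
    averaged: np.ndarray  # H x W
    validity: np.ndarray  # H x W bool, in-field for every frame
    meta: Optional[ImageStack] = None  # source stack (metadata carrier)


@dataclass
class ProbabilityMap:
    """Per-pixel vessel confidence in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class VesselMask:
    """Binarized vessel map together with its provenance."""

    values: np.ndarray  # bool H x W
    threshold: float = 0.5
    segmenter: str = "multiscale-vesselness"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)


@dataclass
class PICoVMap:
    """Per-pixel temporal coefficient of variation with a validity mask.

    Valid pixels are in-mask, in-field for every registered frame, above
    the mean-intensity floor, and outside removed projection artifacts.
    """

    values: np.ndarray  # H x W, >= 0 where valid
    validity: np.ndarray  # H x W bool


@dataclass
class QuadrantSummary:
    """Mean PICoV per 3 x 3 mm quadrant (ST/SN/IT/IN)."""

    picov_ST: float
    picov_SN: float
    picov_IT: float
    picov_IN: float
    counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "ST": self.picov_ST,
            "SN": self.picov_SN,
            "IT": self.picov_IT,
            "IN": self.picov_IN,
        }


@dataclass
class DensitySeries:
    """Per-frame perfusion density (PD) and vessel density (VD).

    PD is the ones:zeros pixel ratio of the binarized frame; VD the same
    ratio on the skeletonized frame.
    """

    pd: np.ndarray
    vd: np.ndarray
    mean_pd: float
    sd_pd: float
    mean_vd: float
    sd_vd: float
    pd_definition: str = "ones_to_zeros"


@dataclass
class VesselNetwork:
    """Synthetic branching vasculature: centerline graph + raster mask."""

    graph: nx.Graph  # nodes: (y, x); edges carry width_px, layer
    raster_mask: np.ndarray  # bool H x W
    label_map: np.ndarray  # int H x W, segment id + 1 (0 = background)
    segment_widths: np.ndarray  # per segment id, px
    layer: str = SVC
    fov_mm: float = DEFAULT_FOV_MM
    scale_um_per_px: float = DEFAULT_UM_PER_PX
    large_vessel_threshold_px: float = LARGE_VESSEL_THRESHOLD_PX

    @property
    def n_segments(self) -> int:
        return len(self.segment_widths)

    @property
    def large_segments(self) -> np.ndarray:
        return self.segment_widths >= self.large_vessel_threshold_px

    @property
    def vessel_fraction(self) -> float:
        return float(self.raster_mask.mean())


@dataclass
class PerfusionModel:
    """Temporal behaviour of each vessel segment.

    ``segment_cv`` is the programmed coefficient of variation of the
    per-segment multiplicative intensity factor (vasomotion strength);
    ``persistence_frames`` is how many consecutive frames share a factor
    draw (capillary shunting persists over tens of seconds, but the
    inter-frame interval is unknown, so the default is one frame).
    ``temporal_bias`` multiplies the CV of segments whose centroid lies in
    the temporal half of the field, emulating the temporal-macula excess of
    capillary dropout and flow heterogeneity.
    """

    segment_mean: np.ndarray  # per segment, intensity in (0, 1]
    segment_cv: np.ndarray  # per segment, >= 0
    persistence_frames: int = 1
    dropout_map: Optional[np.ndarray] = None  # bool H x W, non-perfused
    temporal_bias: float = 1.0
    temporal_side: str = "left"  # which image half gets the bias

    def __post_init__(self) -> None:
        self.segment_mean = np.asarray(self.segment_mean, dtype=np.float64)
        self.segment_cv = np.asarray(self.segment_cv, dtype=np.float64)
        if np.any(self.segment_cv < 0):
            raise ValueError("segment CVs must be >= 0")
        if self.persistence_frames < 1:
            raise ValueError("persistence_frames must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """Everything needed to invert/score a simulated corruption."""

    true_mask: np.ndarray  # bool H x W
    true_cv_map: np.ndarray  # float H x W, programmed per-pixel CV
    dropout_map: np.ndarray  # bool H x W
    true_shifts: Optional[np.ndarray] = None  # T x 2 (dy, dx)
    true_fields: Optional[list] = None  # per-frame DisplacementField
    large_vessel_map: Optional[np.ndarray] = None  # bool H x W
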