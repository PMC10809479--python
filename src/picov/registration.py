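"""Two-step registration of serially acquired en-face OCTA frames.

Each frame is aligned to a template frame by (1) lateral cross-correlation
translation in the fast- and slow-scan directions and (2) diffeomorphic
demons non-rigid refinement, then the registered stack is averaged to
obtain a high-SNR image for vessel segmentation.

Template selection is automated with a composite quality score (mean
pairwise normalized cross-correlation plus sharpness) but can be
overridden manually, mirroring how an operator would pick the frame with
the least motion artifact and best signal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import laplace, shift as nd_shift
from skimage.registration import phase_cross_correlation

from .datatypes import DisplacementField, ImageStack, RegisteredStack
from .synthetic import apply_field

__all__ = [
    "DemonsParams",
    "TranslationResult",
    "select_template",
    "register_translation",
    "register_demons",
    "register_stack",
]


@dataclass
class DemonsParams:
    """Diffeomorphic demons settings (per pyramid level, coarse to fine)."""

    iterations: Sequence[int] = (50, 25, 10)
    smoothing_sigma_px: float = 2.0
    #: shrink factors per level, coarse to fine; last must be 1
    shrink_factors: Sequence[int] = (4, 2, 1)
    intensity_difference_threshold: float = 0.001

    def __post_init__(self) -> None:
        if len(self.iterations) != len(self.shrink_factors):
            raise ValueError("iterations and shrink_factors need one entry "
                             "per pyramid level")
        if self.shrink_factors[-1] != 1:
            raise ValueError("the finest pyramid level must have shrink "
                             "factor 1")


def _normalize(img: np.ndarray) -> np.ndarray:
    s = img.std()
    return (img - img.mean()) / s if s > 0 else img - img.mean()


def select_template(stack: ImageStack, override: Optional[int] = None) -> int:
    """Pick the frame best suited as registration template.

    Score = mean zero-normalized cross-correlation against all other
    frames (favouring the frame closest to the stack consensus, i.e. the
    least motion-corrupted) plus a sharpness term (variance of the
    Laplacian, favouring high signal quality).  Ties break to the lowest
    index.
    """
    t = stack.n_frames
    if override is not None:
        if not 0 <= override < t:
            raise IndexError(f"template override {override} out of range 0..{t - 1}")
        return override
    frames = stack.frames
    z = np.stack([_normalize(f) for f in frames])
    npx = frames[0].size
    ncc = (z.reshape(t, -1) @ z.reshape(t, -1).T) / npx
    mean_ncc = (ncc.sum(axis=1) - np.diag(ncc)) / max(t - 1, 1)
    sharp = np.array([laplace(f).var() for f in frames])
    sharp_max = sharp.max()
    if sharp_max > 0:
        sharp = sharp / sharp_max
    score = mean_ncc + 0.25 * sharp
    # argmax takes the first maximum, giving the lowest-index tie-break
    return int(np.argmax(np.round(score, 12)))


@dataclass
class TranslationResult:
    shift: np.ndarray  # (dy, dx): displacement of moving relative to template
    image: np.ndarray  # moving resampled by -shift onto the template grid
    warning: Optional[str] = None


def register_translation(moving: np.ndarray, template: np.ndarray,
                         upsample_factor: int = 20) -> TranslationResult:
    """Recover the lateral shift of ``moving`` relative to ``template``.

    The returned ``shift`` is the translation that was applied to the
    template to produce the moving frame, i.e. ``moving ≈ translate(template,
    shift)``; the aligned image is ``moving`` resampled by ``-shift``.
    Subpixel precision via upsampled cross-correlation.
    """
    if moving.shape != template.shape:
        raise ValueError("moving and template must have the same shape")
    warning = None
    if not np.any(moving) or not np.any(template):
        return TranslationResult(np.zeros(2), moving.copy(),
                                 warning="all-zero image; returning zero shift")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reg_shift, _, _ = phase_cross_correlation(
            template, moving, upsample_factor=upsample_factor,
            normalization=None)
    # phase_cross_correlation returns the shift to apply to `moving` so it
    # matches `template`; our convention is the opposite sign
    shift = -np.asarray(reg_shift, dtype=float)
    aligned = nd_shift(moving, -shift, order=1, mode="constant", cval=0.0)
    return TranslationResult(shift, aligned, warning)


def _field_to_sitk(u: np.ndarray) -> sitk.Image:
    # sitk displacement fields are (x, y) vectors
    return sitk.GetImageFromArray(u[..., ::-1].astype(np.float64),
                                  isVector=True)


def _sitk_to_field(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img)[..., ::-1]


def _msd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def register_demons(moving: np.ndarray, template: np.ndarray,
                    params: Optional[DemonsParams] = None
                    ) -> tuple[DisplacementField, np.ndarray, bool]:
    """Non-rigid refinement via multiresolution diffeomorphic demons.

    Returns ``(field, warped, converged)`` where ``field`` maps template
    coordinates to moving-frame sample positions (pull-back convention)
    and ``warped`` is the moving image resampled onto the template grid.
    The field is Gaussian-regularized every iteration; updates are
    composed through the displacement-field exponential, so the warp is
    invertible for the amplitudes arising here.  If the mean squared
    intensity difference (MSD) increases across a full pyramid level the
    best field so far is returned with ``converged=False``.
    """
    if moving.shape != template.shape:
        raise ValueError("moving and template must have the same shape")
    params = params or DemonsParams()
    fixed = sitk.GetImageFromArray(template.astype(np.float64))
    mov = sitk.GetImageFromArray(moving.astype(np.float64))

    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetStandardDeviations(params.smoothing_sigma_px)
    demons.SetIntensityDifferenceThreshold(
        params.intensity_difference_threshold)

    best_u = np.zeros((*template.shape, 2))
    best_msd = _msd(moving, template)
    converged = True

    field_img = None
    for shrink, iters in zip(params.shrink_factors, params.iterations):
        if shrink > 1:
            f_lvl = sitk.Shrink(sitk.SmoothingRecursiveGaussian(
                fixed, shrink / 2.0), [shrink, shrink])
            m_lvl = sitk.Shrink(sitk.SmoothingRecursiveGaussian(
                mov, shrink / 2.0), [shrink, shrink])
        else:
            f_lvl, m_lvl = fixed, mov
        if field_img is None:
            field_img = sitk.Image(f_lvl.GetSize(), sitk.sitkVectorFloat64, 2)
            field_img.CopyInformation(f_lvl)
        else:
            field_img = sitk.Resample(field_img, f_lvl,
                                      sitk.Transform(),
                                      sitk.sitkLinear)
            field_img = sitk.Cast(field_img, sitk.sitkVectorFloat64)
        demons.SetNumberOfIterations(int(iters))
        field_img = demons.Execute(f_lvl, m_lvl, field_img)

        # score at full resolution
        full = sitk.Resample(field_img, fixed, sitk.Transform(),
                             sitk.sitkLinear)
        u = _sitk_to_field(sitk.Cast(full, sitk.sitkVectorFloat64))
        warped = apply_field(moving, u)
        cur = _msd(warped, template)
        if cur <= best_msd:
            best_msd = cur
            best_u = u
        else:
            converged = False
    warped = apply_field(moving, best_u)
    return DisplacementField(best_u), warped, converged


def register_stack(stack: ImageStack, template_index: Optional[int] = None,
                   params: Optional[DemonsParams] = None,
                   run_demons: bool = True) -> RegisteredStack:
    """Align every frame to the template and average the registered stack.

    The template frame is untouched.  Every other frame is translated
    (cross-correlation) and then non-rigidly refined (demons).  Pixels
    that fall outside the field of view of any warped frame are flagged
    invalid so downstream statistics can exclude them.
    """
    if template_index is None:
        template_index = select_template(stack)
    elif not 0 <= template_index < stack.n_frames:
        raise IndexError("template_index out of range")
    t, h, w = stack.frames.shape
    template = stack.frames[template_index]

    out = np.empty_like(stack.frames)
    shifts = np.zeros((t, 2))
    fields: list[DisplacementField] = []
    coverage = np.ones((h, w), dtype=bool)
    ones = np.ones((h, w))

    for k in range(t):
        if k == template_index:
            out[k] = template
            fields.append(DisplacementField.identity((h, w)))
            continue
        tr = register_translation(stack.frames[k], template)
        shifts[k] = tr.shift
        moving = tr.image
        if run_demons:
            field, warped, _ = register_demons(moving, template, params)
        else:
            field = DisplacementField.identity((h, w))
            warped = moving
        out[k] = warped
        # total field: translation then demons, composed on template grid
        total = field.vectors.copy()
        total[..., 0] += shifts[k, 0]
        total[..., 1] += shifts[k, 1]
        fields.append(DisplacementField(total))
        # in-field coverage of this frame's warp
        cov = apply_field(ones, total) > 0.999
        coverage &= cov

    averaged = out.mean(axis=0)
    return RegisteredStack(frames=out, template_index=template_index,
                           shifts=shifts, fields=fields, averaged=averaged,
                           validity=coverage, meta=stack)
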