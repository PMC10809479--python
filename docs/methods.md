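# Methods note

This note documents the model implemented by `picov`, the synthetic
data generator used to validate it, the parameter defaults and the
reasoning behind them, and the package's known limitations.  No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` actually compute.

## 1. The measurement model

An acquisition is a stack of T en-face OCTA frames of the same eye and
layer (superficial vascular complex, SVC, or deep vascular complex,
DVC), nominally T = 10.  OCTA intensity is flow-dependent, so a
capillary segment whose flow pauses between scans dims in some frames.
After registration onto a common template, the **pixel intensity
coefficient of variation** at pixel p is

    PICoV(p) = SD_t[I_t(p)] / mean_t[I_t(p)],

with the sample SD (ddof = 1).  Pixels are *valid* when they lie inside
the segmented vessel mask, stay inside the field of view in every
registered frame, survive projection-artifact excision, and have a
temporal mean above `mean_floor = 0.01` of full scale (a near-zero
denominator measures noise, not flow).  Eye-level and quadrant
summaries are means over valid pixels; quadrants are equal half-splits
of the fovea-centred scan with the image top superior, and the
temporal/nasal assignment follows laterality (temporal is the left
image half in OD, the right in OS).

Perfusion density (PD) is the ones:zeros pixel ratio of the binarized
vessel image; vessel density (VD) is the same ratio after
skeletonization to 1-px centerlines, so VD ≤ PD identically.  The
ones:total variant used by some commercial instruments is available via
`pd_definition="ones_to_total"` and recorded in every output.

## 2. The analysis chain

1. **Quality gate.** Frames below the signal-strength floor (default
   8/10) are dropped; in strict mode a shortfall below 10 clean frames
   is an error naming the offending frames.
2. **Template selection.** The frame maximizing mean zero-normalized
   cross-correlation against the others plus a sharpness term (variance
   of the Laplacian), i.e. the least motion-corrupted, sharpest frame.
3. **Translation.** Upsampled phase cross-correlation (1/20-px grid).
   Phase correlation is exact for circular integer shifts and accurate
   to well under half a pixel for band-limited subpixel shifts.
4. **Non-rigid residual.** Diffeomorphic demons in a 3-level pyramid
   (shrink 4/2/1, iterations 50/25/10, field smoothing σ = 2 px),
   keeping the best-MSD field seen.  Total displacement = demons field
   plus translation; fields follow the pull-back convention
   `warped(p) = moving(p + u(p))`.
5. **Segmentation.** The averaged registered image is background-
   flattened (subtraction of a σ = 25 px Gaussian), split with a
   three-class multi-Otsu threshold — background, capillaries,
   saturated large vessels; the lowest split keeps the bright arcade
   mode from absorbing the capillary class — softened through a
   logistic, and blended 0.7/0.3 with per-scale-normalized Sato
   tubularity (scales 1, 2, 4 px).  Binarization at 0.5.  A constant
   image yields an all-zero map.
6. **Projection-artifact removal.** SVC structures wider than 6 px
   (opening with a disk, +2 px margin) are excised from the DVC —
   removed from metric denominators, not merely zeroed.
7. **Metrics and statistics.** PICoV maps (false-coloured with CV
   capped at 0.4 for display), quadrant summaries, per-frame PD/VD;
   Kruskal–Wallis across severity groups with tie correction, Nemenyi
   post-hoc on the rank sums (studentized-range reference, df = ∞),
   Tukey HSD on quadrant means (pooled variance, df = N − k), both
   gated on a significant omnibus test at α = 0.05; Pearson
   correlations between PICoV and density metrics.

## 3. The synthetic generator

Networks grow by stochastic branching random walks until the vessel
pixel fraction reaches 0.35 ± 0.05 (PD ≈ 0.55 as a ones:zeros ratio,
a plausible macular value).  SVC networks add three wide arcade-like
vessels (7–9 px); DVC networks are a capillary mesh (1–3 px) only.
Each segment gets a mean reflectance (capillaries uniform in
0.35–0.55 of full scale; large vessels saturated at 1.0) and a temporal
CV: per-frame multiplicative factors drawn from a clipped normal
N(1, cv²), zero CV for large vessels whose flow never pauses in
practice.  Severity is modelled by the capillary CV ladder
0.10/0.14/0.18/0.22 across control / no-DR / mild / moderate-severe
groups of 7/7/8/7 eyes, with capillary dropout fractions
0/0.01/0.03/0.06 (disc-shaped, 75% biased to the temporal half) and a
temporal-half CV multiplier 1.0/1.15/1.3/1.5.

Rendering applies a PSF blur of σ = 0.7 px — at the default scale of
12 µm/px (6 × 6 mm over 500 px, with smaller grids representing scans
at proportionally coarser sampling) this corresponds to a transverse
optical resolution around 20 µm — then additive Gaussian noise
(σ = 0.02) plus signal-proportional speckle, clipped to [0, 1].
Motion corruption composes a rigid shift (up to ±3 px) with a smooth
elastic field (Gaussian-filtered white noise, σ = 20 px, amplitude
≤ 2 px); frame 0 stays clean as a natural template and every true
shift/field is recorded.  Projection artifacts add a blurred,
gain-scaled ghost of the large SVC vessels to every DVC frame.

**What the generator emulates:** flow-dependent capillary flicker with
controllable heterogeneity, saturated stable arcades, dropout, the
temporal-side excess, inter-scan motion, projection ghosts, speckle.
**What it does not:** real OCTA decorrelation statistics (intensities
are reflectance-like, not decorrelation values), the foveal avascular
zone, axial slab-segmentation errors, pulsatile bulk motion within a
frame, and instrument-specific preprocessing.  Validation claims are
therefore about pipeline correctness and sensitivity, not about
clinical effect sizes.

## 4. Parameter defaults and rationale

| Parameter | Default | Why |
|---|---|---|
| frames per stack | 10 | serial-acquisition protocol this analysis targets |
| segmentation threshold | 0.5 | probability-map midpoint; study constant |
| PICoV display cap | 0.4 | saturates the colour scale where CVs become noise-dominated |
| signal-strength floor | 8/10 | accepts only high-quality frames |
| `mean_floor` | 0.01 | excludes near-zero denominators |
| large-vessel width threshold | 6 px (≈ 70 µm) | separates arcades from capillaries at 12 µm/px |
| demons iterations / shrink | 50/25/10 at 4/2/1 | converges at these problem sizes; best-MSD guard |
| field smoothing σ | 2 px | regularizes to physically smooth warps |
| α | 0.05 | conventional; post-hocs gated on the omnibus |
| vessel fraction target | 0.35 ± 0.05 | yields PD in a plausible macular range |
| PSF σ | 0.7 px | ≈ 20 µm transverse resolution at 12 µm/px |
| noise σ | 0.02 | keeps single frames realistically grainy without burying capillaries |

Problem sizes in the validation battery (128–256 px grids, 20 cohort
replicates, 500 null cohorts) are package choices balancing statistical
resolution against a few minutes of single-CPU runtime.

## 5. Numerical choices

- Sample SD (ddof = 1) throughout; the 10-frame worked series of five
  0.1s and five 0.3s gives CV = √10⁄6 ≈ 0.527.
- Displacement fields are H × W × 2 (dy, dx) pull-back fields; the
  recovered field is compared against the numerically inverted injected
  field (fixed-point iteration) when measuring endpoint error.
- Registration quality in the validation battery is scored on an 8-px
  interior crop: warping pulls zeros in from outside the field of view,
  and no registration can restore that border band.
- The Nemenyi reference in the tests evaluates the studentized-range
  distribution through its integral form by numerical quadrature,
  sharing no code with the implementation; Tukey is checked against
  SciPy's independent implementation.
- All stochastic components consume `numpy` Generators seeded through
  `SeedSequence` fan-out, so cohorts are reproducible and extensible
  without perturbing existing eyes.

## 6. Limitations

- Synthetic validation bounds implementation error, not clinical
  validity; effect sizes on real cohorts will differ.
- The segmenter is tuned for the generator's contrast regime; real
  scans with strong vignetting or media opacity may need the pluggable
  segmenter interface.
- Demons registration assumes mostly in-plane motion; through-plane
  decorrelation appears as intensity change it cannot correct.
- PICoV conflates vasomotion with any residual misregistration;
  the motion round-trip check bounds this at the default motion
  amplitudes only.
- Quadrant statistics pool eyes; within-patient correlation between
  fellow eyes is not modelled.
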