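# picov

Perfusion heterogeneity analysis of serial en-face OCTA images.

## Scientific problem

Optical coherence tomography angiography (OCTA) renders retinal
capillaries from flow-based decorrelation contrast, so a capillary is
only as bright as the blood moving through it during acquisition.
Capillary flow is not steady: terminal arterioles and pre-capillary
sphincters contract periodically (vasomotion), making individual
capillary segments flicker between serially acquired scans of the same
eye.  In diabetic retinopathy this temporal heterogeneity of perfusion
increases with disease severity, and it does so before vessels are lost
outright — which makes it a candidate early biomarker that conventional
single-scan density metrics miss.

The quantity of interest is the **pixel intensity coefficient of
variation (PICoV)**: for each pixel, the sample standard deviation of
its intensity across ten registered en-face frames divided by its
temporal mean.  Supporting metrics are **perfusion density** (PD, the
ones:zeros pixel ratio of the binarized vessel image) and **vessel
density** (VD, the same ratio on the 1-px skeleton), quadrant summaries
(ST/SN/IT/IN, laterality-aware), and group statistics across disease
severity grades.

## What the package does

- **Synthetic OCTA generator** (`picov.synthetic`) — stochastic
  branching vascular networks (superficial complex with wide arcades,
  deep complex as a pure capillary mesh), a per-segment perfusion model
  with programmable temporal CV, capillary dropout and a temporal-half
  CV bias, frame rendering with PSF blur, additive and speckle noise,
  plus injectable rigid + elastic motion and projection artifacts.
  Every corruption records its exact ground truth, so each pipeline
  stage can be validated against known truth.
- **Registration** (`picov.registration`) — template selection, phase-
  correlation translation (subpixel), and multiscale diffeomorphic
  demons for residual non-rigid motion.
- **Segmentation** (`picov.segmentation`) — background flattening,
  multi-Otsu intensity scoring blended with multiscale Sato tubularity,
  binarization at 0.5, and excision of large superficial-vessel
  projection ghosts from the deep layer.
- **Metrics** (`picov.metrics`) — PICoV maps with validity tracking,
  false-colour rendering (capped at CV 0.4), laterality-aware quadrant
  summaries, per-frame PD/VD series.
- **Statistics** (`picov.stats`) — Kruskal–Wallis with tie correction,
  Nemenyi and Tukey HSD all-pairs post-hocs (gated on the omnibus
  test), Pearson correlations, and a one-call cohort report.
- **Pipeline + CLI** (`picov.pipeline`, `picov` command) — simulate or
  read stacks, register, segment, quantify, and write per-eye artifacts
  plus a cohort CSV and statistics report.

## Worked example

Simulate one deep-layer eye with a programmed capillary CV of 0.20,
corrupt it with motion, then run the analysis chain:

```python
from picov import (register_stack, segment_vessels, binarize_and_mask,
                   compute_picov_map, summarize_picov,
                   compute_density_series)
from picov.synthetic import (generate_vascular_network,
                             build_perfusion_model, simulate_stack,
                             inject_motion)

net = generate_vascular_network(seed=1, layer="DVC", size_px=192)
perf = build_perfusion_model(net, capillary_cv=0.20, seed=2)
stack, truth = simulate_stack(net, perf, n_frames=10,
                              noise_sigma=0.02, seed=3)
moved, _ = inject_motion(stack, max_shift_px=3.0,
                         elastic_amplitude_px=1.0, seed=4)

reg = register_stack(moved)
pmap = segment_vessels(reg.averaged)
mask, masked = binarize_and_mask(pmap, reg)
pic = compute_picov_map(masked, reg.validity & mask.values)
eye, quads = summarize_picov(pic, moved.laterality)
dens = compute_density_series(reg.frames, segment_vessels,
                              validity=reg.validity)

print(f"mean masked PICoV       : {eye:.3f}")
print(f"quadrants ST/SN/IT/IN   : "
      + "/".join(f"{v:.3f}" for v in quads.as_dict().values()))
print(f"mean PD (ones:zeros)    : {dens.mean_pd:.3f}")
print(f"mean VD (skeleton)      : {dens.mean_vd:.3f}")
```

Output:

```
mean masked PICoV       : 0.169
quadrants ST/SN/IT/IN   : 0.168/0.160/0.171/0.176
mean PD (ones:zeros)    : 0.580
mean VD (skeleton)      : 0.125
```

The measured PICoV (0.169) sits below the programmed per-segment CV
(0.20) because PSF blur mixes each capillary with its surroundings and
the temporal mean includes noise; the recovery stays within the ±20%
band that the acceptance battery enforces, and ranks programmed CV
levels perfectly.  A full cohort run is one call:

```bash
picov run --simulate --out results/demo --seed 1
```

which writes per-eye averaged/PICoV images, `cohort.csv`, and
`report.json` with the group statistics.

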