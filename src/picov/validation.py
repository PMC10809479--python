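"""End-to-end validation experiments on synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant
pipeline stages, and returns the measured quantities as a plain dict, so
the same computations back both the test suite and the reproducibility
script.  Problem sizes are chosen so the full battery runs in minutes on
one CPU; they are documented in the methods note.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.ndimage import shift as nd_shift
from scipy.stats import spearmanr

from .datatypes import DVC, OD, OS, SVC, ImageStack
from .metrics import compute_density_series, compute_picov_map, summarize_picov
from .registration import register_demons, register_stack, register_translation
from .segmentation import segment_vessels
from .stats import kruskal_wallis, nemenyi_posthoc, pearson_corr, tukey_posthoc
from .synthetic import (CohortConfig, apply_field, build_perfusion_model,
                        generate_cohort, generate_vascular_network,
                        inject_motion, simulate_stack)

__all__ = [
    "cv_oracle_check",
    "registration_recovery",
    "segmentation_fidelity",
    "picov_parameter_recovery",
    "severity_discrimination",
    "quadrant_gradient",
    "density_metrics",
    "statistical_layer",
    "GROUPS",
]

GROUPS = ("control", "noDR", "mild", "mod-severe")


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    return float(2 * (a & b).sum() / (a.sum() + b.sum()))


def _masked_mean_picov(frames: np.ndarray) -> float:
    mask = segment_vessels(frames.mean(axis=0)).values >= 0.5
    pic = compute_picov_map(frames * mask, mask)
    return float(pic.values[pic.validity].mean())


# --------------------------------------------------------------------------

def cv_oracle_check(seed: int = 0, n_series: int = 1000) -> dict:
    """Pixel-CV computation vs a direct closed-form oracle.

    Random 10-length series are laid out as a stack and the per-pixel CV
    compared against an elementwise SD/mean computation; the 5 x 0.1 /
    5 x 0.3 worked series has CV sqrt(10/9)/2 = 0.527.
    """
    rng = np.random.default_rng(seed)
    series = rng.uniform(0.05, 1.0, size=(10, n_series))
    stack = series.reshape(10, 1, n_series)
    pic = compute_picov_map(stack, mean_floor=0.0)
    oracle = series.std(axis=0, ddof=1) / series.mean(axis=0)
    worked = np.array([0.1] * 5 + [0.3] * 5).reshape(10, 1, 1)
    worked_cv = compute_picov_map(worked).values[0, 0]
    return {
        "max_abs_err": float(np.max(np.abs(pic.values[0] - oracle))),
        "worked_series_cv": float(worked_cv),
        "n": n_series,
    }


def registration_recovery(seed: int = 0, size: int = 256,
                          margin_px: int = 8) -> dict:
    """Translation and demons recovery on known synthetic corruptions.

    Integer shifts are applied circularly (the regime phase correlation
    is exact in); the demons MSD is scored on the interior, excluding a
    ``margin_px`` border band where warping pulls in out-of-field zeros
    that no registration can restore.
    """
    s = _subseeds(seed, 6)
    net = generate_vascular_network(s[0], SVC, size)
    perf = build_perfusion_model(net, 0.0, seed=s[1], cv_jitter=0.0)
    stack, _ = simulate_stack(net, perf, 2, 0.0, seed=s[2])
    raw = stack.frames[0]
    img = gaussian_filter(raw, 1.0)  # band-limit for subpixel accuracy

    rng = np.random.default_rng(s[3])
    int_errs = []
    for _ in range(5):
        shift = rng.integers(-5, 6, size=2)
        moving = np.roll(raw, shift, axis=(0, 1))
        rec = register_translation(moving, raw).shift
        int_errs.append(np.abs(rec - shift).max())
    sub_errs = []
    for _ in range(5):
        shift = rng.uniform(-3, 3, size=2)
        moving = nd_shift(img, shift, order=1)
        rec = register_translation(moving, img).shift
        sub_errs.append(np.abs(rec - shift).max())

    # known smooth warp, amplitude 3 px
    u = rng.standard_normal((size, size, 2))
    for c in range(2):
        u[..., c] = gaussian_filter(u[..., c], 20.0)
    u *= 3.0 / np.hypot(u[..., 0], u[..., 1]).max()
    warped = apply_field(img, u)
    m = margin_px
    pre = float(np.mean((warped - img)[m:-m, m:-m] ** 2))
    field, out, _ = register_demons(warped, img)
    post = float(np.mean((out - img)[m:-m, m:-m] ** 2))

    # endpoint error vs the numerically inverted true field
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    vi = np.zeros_like(u)
    for _ in range(10):
        uy = map_coordinates(u[..., 0], [yy + vi[..., 0], xx + vi[..., 1]],
                             order=1, mode="nearest")
        ux = map_coordinates(u[..., 1], [yy + vi[..., 0], xx + vi[..., 1]],
                             order=1, mode="nearest")
        vi = -np.stack([uy, ux], axis=-1)
    epe = np.hypot(*(field.vectors - vi).transpose(2, 0, 1))
    return {
        "integer_shift_max_err": float(np.max(int_errs)),
        "subpixel_shift_max_err": float(np.max(sub_errs)),
        "demons_msd_ratio": post / pre,
        "demons_mean_epe_px": float(epe[net.raster_mask].mean()),
        "n": size,
    }


def registration_motion_roundtrip(seed: int = 0, size: int = 192) -> dict:
    """Registered motion-corrupted stack vs its motion-free twin.

    Motion must not masquerade as perfusion heterogeneity: the mean
    masked PICoV after registration should match the no-motion stack.
    Also measures the mean residual alignment error against the recorded
    ground-truth fields.
    """
    s = _subseeds(seed, 4)
    net = generate_vascular_network(s[0], DVC, size)
    perf = build_perfusion_model(net, 0.15, seed=s[1])
    stack, gt = simulate_stack(net, perf, 10, 0.02, seed=s[2])
    base = _masked_mean_picov(stack.frames)
    moved, gtm = inject_motion(stack, 3.0, 2.0, 20.0, seed=s[3],
                               ground_truth=gt)
    reg = register_stack(moved, template_index=0)
    rec = _masked_mean_picov(reg.frames)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    errs = []
    for k in range(1, stack.n_frames):
        u = gtm.true_fields[k].vectors
        v = reg.fields[k].vectors
        uy = map_coordinates(u[..., 0], [yy + v[..., 0], xx + v[..., 1]],
                             order=1, mode="nearest")
        ux = map_coordinates(u[..., 1], [yy + v[..., 0], xx + v[..., 1]],
                             order=1, mode="nearest")
        e = np.hypot(v[..., 0] + uy, v[..., 1] + ux)
        errs.append(e[net.raster_mask].mean())
    return {
        "picov_no_motion": base,
        "picov_registered": rec,
        "picov_rel_err": abs(rec - base) / base,
        "alignment_mean_err_px": float(np.mean(errs)),
        "n": size,
    }


def segmentation_fidelity(seed: int = 0, size: int = 192,
                          noise_sweep=(0.0, 0.1, 0.2, 0.4),
                          n_networks: int = 2, n_seeds: int = 5) -> dict:
    """Dice vs ground truth on noiseless renders + noise degradation.

    Each Dice value is the mean over ``n_networks`` morphologies times
    ``n_seeds`` noise realizations so the ordering across noise levels
    reflects the noise effect rather than replication scatter.
    """
    s = _subseeds(seed, 4)
    out: dict = {"noise_sweep": list(noise_sweep), "n": size}
    for layer in (SVC, DVC):
        means = []
        for ns in noise_sweep:
            dices = []
            for j in range(n_networks):
                net = generate_vascular_network(s[0] + j, layer, size)
                perf = build_perfusion_model(net, 0.1, seed=s[2] + j)
                for k in range(n_seeds):
                    stack, gt = simulate_stack(net, perf, 10, ns,
                                               seed=s[3] + k)
                    mask = segment_vessels(stack.frames.mean(0)).values >= 0.5
                    dices.append(_dice(mask, gt.true_mask))
            means.append(float(np.mean(dices)))
        out[f"dice_noiseless_{layer}"] = means[0]
        out[f"dice_sweep_{layer}"] = means
        out[f"monotone_{layer}"] = bool(
            all(a >= b for a, b in zip(means, means[1:])))
    return out


def picov_parameter_recovery(seed: int = 0, size: int = 256,
                             levels=(0.05, 0.1, 0.2, 0.3),
                             n_seeds: int = 3) -> dict:
    """Programmed capillary CV ladder vs measured mean masked PICoV.

    Uses deep-layer stacks (pure capillary mesh) at low noise; the
    worst-case relative recovery error over all levels and seeds, and the
    Spearman rank correlation of measured vs programmed CV per seed.
    """
    rel_errs = []
    rhos = []
    for k in range(n_seeds):
        s = _subseeds(seed + k, 3)
        means = []
        for cv in levels:
            net = generate_vascular_network(s[0], DVC, size)
            perf = build_perfusion_model(net, cv, seed=s[1], cv_jitter=0.0,
                                         mean_range=(0.4, 0.55))
            stack, _ = simulate_stack(net, perf, 10, 0.01, seed=s[2])
            means.append(_masked_mean_picov(stack.frames))
        rel_errs.extend(abs(m - c) / c for m, c in zip(means, levels))
        rhos.append(float(spearmanr(means, levels).statistic))
    return {
        "max_rel_err": float(np.max(rel_errs)),
        "min_spearman_rho": float(np.min(rhos)),
        "levels": list(levels),
        "n": size,
    }


def _cohort_eye_picovs(config: CohortConfig, seed: int) -> dict:
    """Eye-level masked PICoV per layer per group for one cohort."""
    cohort = generate_cohort(config, seed=seed)
    out: dict = {layer: {g: [] for g in config.group_names}
                 for layer in config.layers}
    for rec in cohort:
        for layer, stack in rec.stacks.items():
            out[layer][rec.group].append(_masked_mean_picov(stack.frames))
    return out


def severity_discrimination(seed: int = 0, n_replicates: int = 20,
                            alpha: float = 0.05) -> dict:
    """Kruskal-Wallis severity separation over replicated cohorts.

    Default 7/7/8/7 cohorts with the 0.10/0.14/0.18/0.22 capillary CV
    ladder; reports the fraction of replicates with a significant
    omnibus test per layer and which Nemenyi pair is flagged (smallest
    adjusted p) most frequently.
    """
    config = CohortConfig()
    sig = {layer: 0 for layer in config.layers}
    pair_hits: dict = {}
    for rep in range(n_replicates):
        vals = _cohort_eye_picovs(config, seed=seed + rep)
        for layer in config.layers:
            groups = [vals[layer][g] for g in config.group_names]
            if kruskal_wallis(groups, alpha=alpha).significant:
                sig[layer] += 1
            pm = nemenyi_posthoc(groups, names=config.group_names).pairwise
            best = min(((pm.iloc[i, j], (pm.index[i], pm.columns[j]))
                        for i, j in combinations(range(len(groups)), 2)))
            pair_hits[best[1]] = pair_hits.get(best[1], 0) + 1
    top_pair = max(pair_hits, key=pair_hits.get)
    return {
        "kw_significant_fraction_SVC": sig[SVC] / n_replicates,
        "kw_significant_fraction_DVC": sig[DVC] / n_replicates,
        "top_nemenyi_pair": list(top_pair),
        "top_pair_fraction": pair_hits[top_pair] / (2 * n_replicates),
        "n": n_replicates,
    }


def quadrant_gradient(seed: int = 0, n_eyes: int = 24, size: int = 128,
                      bias: float = 1.5, alpha: float = 0.05) -> dict:
    """Temporal-half CV excess recovery in the quadrant summaries.

    Eyes are simulated with a programmed temporal:nasal capillary CV
    ratio; reports the fraction with temporal > nasal quadrant means and
    the pooled Tukey comparison across the four quadrants.
    """
    s = _subseeds(seed, 3)
    n_temporal_higher = 0
    quads = {q: [] for q in ("ST", "SN", "IT", "IN")}
    for i in range(n_eyes):
        lat = OD if i % 2 == 0 else OS
        side = "left" if lat == OD else "right"
        net = generate_vascular_network(s[0] + i, DVC, size)
        perf = build_perfusion_model(net, 0.15, seed=s[1] + i,
                                     temporal_bias=bias, temporal_side=side)
        stack, _ = simulate_stack(net, perf, 10, 0.02, seed=s[2] + i,
                                  laterality=lat)
        mask = segment_vessels(stack.frames.mean(0)).values >= 0.5
        pic = compute_picov_map(stack.frames * mask, mask)
        _, q = summarize_picov(pic, lat)
        d = q.as_dict()
        for name, val in d.items():
            quads[name].append(val)
        if (d["ST"] + d["IT"]) / 2 > (d["SN"] + d["IN"]) / 2:
            n_temporal_higher += 1
    tukey = tukey_posthoc([quads[q] for q in ("ST", "SN", "IT", "IN")],
                          names=("ST", "SN", "IT", "IN"))
    tn_pairs = [("ST", "SN"), ("ST", "IN"), ("IT", "SN"), ("IT", "IN")]
    n_sig = sum(tukey.pairwise.loc[a, b] < alpha for a, b in tn_pairs)
    return {
        "temporal_gt_nasal_fraction": n_temporal_higher / n_eyes,
        "significant_temporal_nasal_pairs": int(n_sig),
        "n": n_eyes,
    }


def density_metrics(seed: int = 0, size: int = 128, n_eyes: int = 12) -> dict:
    """PD/VD contracts and the PICoV-density correlation direction.

    The toy mask check uses a 4 x 4 frame with 4 ones (PD = 4/12); the
    VD <= PD subset property is checked on every frame of synthetic
    eyes spanning the severity range; the Pearson correlation between
    eye PICoV and mean PD is measured on a dropout-linked severity
    ladder, where capillary loss lowers density as heterogeneity rises.
    """
    toy = np.zeros((4, 4))
    toy[:2, :2] = 1.0
    dens = compute_density_series(toy, segmenter=None)
    toy_pd = dens.mean_pd

    sizes = (3, 3, 3, 3) if n_eyes == 12 else None
    config = CohortConfig(size_px=size,
                          group_sizes=sizes or CohortConfig().group_sizes)
    cohort = generate_cohort(config, seed=seed)
    violations = 0
    picovs, mean_pds = [], []
    for rec in cohort:
        stack = rec.stacks[DVC]
        mask_avg = segment_vessels(stack.frames.mean(0)).values >= 0.5
        pic = compute_picov_map(stack.frames * mask_avg, mask_avg)
        picovs.append(float(pic.values[pic.validity].mean()))
        dser = compute_density_series(stack.frames, segment_vessels)
        violations += int(np.sum(dser.vd > dser.pd))
        mean_pds.append(dser.mean_pd)
    r, p = pearson_corr(picovs, mean_pds)
    return {
        "toy_pd": float(toy_pd),
        "vd_gt_pd_violations": int(violations),
        "picov_mean_pd_pearson_r": r,
        "picov_mean_pd_pearson_p": p,
        "n": len(cohort),
    }


def statistical_layer(seed: int = 0, n_null: int = 500,
                      alpha: float = 0.05) -> dict:
    """Calibration and oracle agreement of the statistics module.

    Type-I error of the Kruskal-Wallis test over null cohorts (eye-level
    PICoV values drawn iid across the 7/7/8/7 design), plus agreement of
    the Nemenyi and Tukey implementations with independent references
    (numerically integrated studentized-range distribution; scipy's
    Tukey HSD) on fixed fixtures.
    """
    rng = np.random.default_rng(seed)
    sizes = (7, 7, 8, 7)
    hits = 0
    for _ in range(n_null):
        groups = [np.exp(rng.normal(np.log(0.15), 0.25, n)) for n in sizes]
        if kruskal_wallis(groups, alpha=alpha).significant:
            hits += 1

    fix = [rng.normal(i * 0.8, 1.0, 5) for i in range(3)]
    nem = nemenyi_posthoc(fix).pairwise.to_numpy()
    nem_oracle = _nemenyi_reference(fix)
    from scipy.stats import tukey_hsd as scipy_tukey
    tuk = tukey_posthoc(fix).pairwise.to_numpy()
    tuk_oracle = scipy_tukey(*fix).pvalue
    return {
        "kw_null_type1": hits / n_null,
        "nemenyi_oracle_max_abs_diff": float(np.max(np.abs(nem - nem_oracle))),
        "tukey_oracle_max_abs_diff": float(np.max(np.abs(tuk - tuk_oracle))),
        "n": n_null,
    }


def _nemenyi_reference(groups) -> np.ndarray:
    """Independently coded Nemenyi oracle.

    Uses a naive O(n^2) mid-rank routine and evaluates the studentized
    range survival function through its integral representation
    ``F(q) = k * int phi(z) [Phi(z) - Phi(z - q)]^(k-1) dz`` by numerical
    quadrature, sharing no code path with the implementation under test.
    """
    from scipy.integrate import quad
    from scipy.stats import norm

    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    sizes = [a.size for a in arrs]
    n = sum(sizes)
    pooled = np.concatenate(arrs)
    ranks = np.array([1 + np.sum(pooled < x) + 0.5 * (np.sum(pooled == x) - 1)
                      for x in pooled])
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)

    def sr_sf(q: float) -> float:
        f = lambda z: norm.pdf(z) * (norm.cdf(z) - norm.cdf(z - q)) ** (k - 1)
        return 1.0 - k * quad(f, -np.inf, np.inf)[0]

    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(tie * n * (n + 1) / 12.0
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            out[i, j] = out[j, i] = min(max(sr_sf(q), 0.0), 1.0)
    return out
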