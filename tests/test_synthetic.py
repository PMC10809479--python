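"""Generator contracts: determinism, morphology, perfusion statistics."""
import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from picov.datatypes import DVC, OD, OS, SVC
from picov.synthetic import (CohortConfig, apply_field, build_perfusion_model,
                             generate_cohort, generate_vascular_network,
                             inject_motion, inject_projection, simulate_stack)

SIZE = 96


class TestNetwork:
    def test_deterministic_for_seed(self):
        a = generate_vascular_network(3, SVC, SIZE)
        b = generate_vascular_network(3, SVC, SIZE)
        assert np.array_equal(a.label_map, b.label_map)
        assert np.array_equal(a.segment_widths, b.segment_widths)

    def test_different_seeds_differ(self):
        a = generate_vascular_network(3, SVC, SIZE)
        b = generate_vascular_network(4, SVC, SIZE)
        assert not np.array_equal(a.label_map, b.label_map)

    def test_vessel_fraction_in_band(self):
        for seed in (0, 1, 2):
            for layer in (SVC, DVC):
                net = generate_vascular_network(seed, layer, 128)
                assert 0.30 <= net.vessel_fraction <= 0.40

    def test_svc_has_large_vessels_dvc_does_not(self, svc_network,
                                                dvc_network):
        assert svc_network.large_segments.any()
        assert not dvc_network.large_segments.any()

    def test_label_map_consistent_with_mask(self, svc_network):
        assert np.array_equal(svc_network.label_map > 0,
                              svc_network.raster_mask)
        assert svc_network.label_map.max() == svc_network.n_segments

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_vascular_network(0, "plexus", SIZE)
        with pytest.raises(ValueError):
            generate_vascular_network(0, SVC, 16)


class TestSimulateStack:
    def test_stack_shape_and_range(self, dvc_stack):
        stack, _ = dvc_stack
        assert stack.frames.shape == (10, SIZE, SIZE)
        assert stack.frames.min() >= 0.0
        assert stack.frames.max() <= 1.0

    def test_deterministic_for_seed(self, dvc_network):
        perf = build_perfusion_model(dvc_network, 0.1, seed=5)
        a, _ = simulate_stack(dvc_network, perf, 4, 0.02, seed=9)
        b, _ = simulate_stack(dvc_network, perf, 4, 0.02, seed=9)
        assert np.array_equal(a.frames, b.frames)

    def test_zero_cv_zero_noise_frames_identical(self, dvc_network):
        perf = build_perfusion_model(dvc_network, 0.0, seed=5, cv_jitter=0.0)
        stack, _ = simulate_stack(dvc_network, perf, 5, 0.0, seed=9)
        for k in range(1, 5):
            assert np.array_equal(stack.frames[k], stack.frames[0])

    def test_empirical_cv_matches_programmed(self, dvc_network):
        # many frames, no blur/noise: per-pixel CV estimates the
        # programmed truncated-normal segment CV
        perf = build_perfusion_model(dvc_network, 0.20, seed=5,
                                     cv_jitter=0.0)
        stack, gt = simulate_stack(dvc_network, perf, 2000, 0.0, seed=9,
                                   psf_sigma_px=0.0)
        v = stack.frames[:, gt.true_mask]
        cv = v.std(axis=0, ddof=1) / v.mean(axis=0)
        assert abs(np.median(cv) - 0.20) < 0.02

    def test_large_vessels_are_temporally_stable(self, svc_network):
        perf = build_perfusion_model(svc_network, 0.20, seed=5)
        stack, gt = simulate_stack(svc_network, perf, 50, 0.0, seed=9,
                                   psf_sigma_px=0.0)
        large = gt.large_vessel_map
        assert large.any()
        v = stack.frames[:, large]
        assert np.ptp(v, axis=0).max() < 1e-12

    def test_dropout_pixels_dark(self, dvc_network):
        perf = build_perfusion_model(dvc_network, 0.1, seed=5,
                                     dropout_fraction=0.05)
        stack, gt = simulate_stack(dvc_network, perf, 4, 0.0, seed=9,
                                   psf_sigma_px=0.0)
        assert gt.dropout_map.any()
        assert stack.frames[:, gt.dropout_map].max() == 0.0

    def test_temporal_bias_raises_temporal_cv(self, dvc_network):
        perf = build_perfusion_model(dvc_network, 0.1, seed=5,
                                     cv_jitter=0.0, temporal_bias=2.0,
                                     temporal_side="left")
        _, gt = simulate_stack(dvc_network, perf, 2, 0.0, seed=9)
        half = SIZE // 2
        mask = gt.true_mask
        t = gt.true_cv_map[:, :half][mask[:, :half]]
        n = gt.true_cv_map[:, half:][mask[:, half:]]
        assert np.median(t) > 1.5 * np.median(n)

    def test_ground_truth_cv_map_supported_on_vessels(self, dvc_stack):
        _, gt = dvc_stack
        assert not gt.true_cv_map[~gt.true_mask].any()

    def test_rejects_bad_frame_count(self, dvc_network):
        perf = build_perfusion_model(dvc_network, 0.1, seed=5)
        with pytest.raises(ValueError):
            simulate_stack(dvc_network, perf, 1, 0.02, seed=9)


class TestMotion:
    def test_frame0_untouched(self, dvc_stack):
        stack, _ = dvc_stack
        moved, _ = inject_motion(stack, 3.0, 1.0, 20.0, seed=2)
        assert np.array_equal(moved.frames[0], stack.frames[0])

    def test_zero_amplitude_is_identity(self, dvc_stack):
        stack, _ = dvc_stack
        moved, gt = inject_motion(stack, 0.0, 0.0, 20.0, seed=2)
        assert np.array_equal(moved.frames, stack.frames)
        assert all(f.magnitude.max() == 0.0 for f in gt.true_fields)

    def test_recorded_fields_reproduce_frames(self, dvc_stack):
        stack, _ = dvc_stack
        moved, gt = inject_motion(stack, 2.0, 1.0, 20.0, seed=2)
        for k in range(1, stack.n_frames):
            rebuilt = apply_field(stack.frames[k], gt.true_fields[k].vectors)
            assert np.allclose(rebuilt, moved.frames[k], atol=1e-12)

    def test_shift_amplitude_bounded(self, dvc_stack):
        stack, _ = dvc_stack
        _, gt = inject_motion(stack, 3.0, 0.0, 20.0, seed=2)
        assert np.abs(gt.true_shifts).max() <= 3.0

    def test_elastic_amplitude_bounded(self, dvc_stack):
        stack, _ = dvc_stack
        _, gt = inject_motion(stack, 0.0, 1.5, 20.0, seed=2)
        assert max(f.magnitude.max() for f in gt.true_fields) <= 1.5 + 1e-9


class TestProjection:
    def test_ghost_raises_dvc_under_large_vessels(self, dvc_stack,
                                                  svc_network):
        stack, _ = dvc_stack
        ghosted = inject_projection(stack, svc_network, ghost_gain=0.3)
        large = np.zeros(svc_network.label_map.shape, dtype=bool)
        vessel = svc_network.label_map > 0
        large[vessel] = svc_network.large_segments[
            svc_network.label_map[vessel] - 1]
        assert ghosted.frames[:, large].mean() > stack.frames[:, large].mean()

    def test_zero_gain_is_identity(self, dvc_stack, svc_network):
        stack, _ = dvc_stack
        ghosted = inject_projection(stack, svc_network, ghost_gain=0.0)
        assert np.allclose(ghosted.frames, stack.frames)

    def test_capillary_only_svc_projects_nothing(self, dvc_stack,
                                                 dvc_network):
        stack, _ = dvc_stack
        ghosted = inject_projection(stack, dvc_network, ghost_gain=0.3)
        assert np.allclose(ghosted.frames, stack.frames)


class TestCohort:
    def test_default_design(self):
        cfg = CohortConfig()
        assert tuple(cfg.group_sizes) == (7, 7, 8, 7)
        assert len(cfg.capillary_cv) == 4

    def test_deterministic_and_structured(self):
        cfg = CohortConfig(group_sizes=(2, 2, 2, 2), size_px=64)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=5)
        assert len(a) == 8
        assert [r.eye_id for r in a] == [r.eye_id for r in b]
        assert np.array_equal(a[0].stacks[SVC].frames,
                              b[0].stacks[SVC].frames)
        assert {r.laterality for r in a} == {OD, OS}
        assert all(set(r.stacks) == {SVC, DVC} for r in a)

    def test_severity_raises_programmed_cv(self):
        cfg = CohortConfig(group_sizes=(2, 2, 2, 2), size_px=64)
        cohort = generate_cohort(cfg, seed=5)
        med = {}
        for rec in cohort:
            gt = rec.ground_truth[DVC]
            cv = gt.true_cv_map[gt.true_mask]
            med.setdefault(rec.group_index, []).append(np.median(cv))
        means = [np.mean(med[i]) for i in sorted(med)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_rejects_nonmonotone_cv_schedule(self):
        cfg = CohortConfig(capillary_cv=(0.2, 0.1, 0.3, 0.4))
        with pytest.raises(ValueError):
            cfg.validate()

    def test_rejects_tiny_groups(self):
        cfg = CohortConfig(group_sizes=(1, 7, 8, 7))
        with pytest.raises(ValueError):
            cfg.validate()


class TestApplyField:
    def test_identity_field(self, rng):
        img = rng.random((32, 32))
        out = apply_field(img, np.zeros((32, 32, 2)))
        assert np.allclose(out, img)

    def test_constant_field_is_translation(self, rng):
        img = rng.random((32, 32))
        u = np.zeros((32, 32, 2))
        u[..., 0] = 1.0
        out = apply_field(img, u)
        assert np.allclose(out[:-1], img[1:])

    def test_matches_direct_sampling(self, rng):
        img = rng.random((32, 32))
        u = rng.uniform(-1, 1, size=(32, 32, 2))
        yy, xx = np.mgrid[0:32, 0:32].astype(float)
        ref = map_coordinates(img, [yy + u[..., 0], xx + u[..., 1]],
                              order=1, mode="constant")
        assert np.allclose(apply_field(img, u), ref)
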