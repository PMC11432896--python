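"""Model-free DCE analysis: baselines, RE, drift correction, binning."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import lungdce as L
from lungdce.dce import (
    DEFAULT_THRESHOLDS,
    background_trace,
    bin_pixels,
    bin_volumes,
    corner_rois,
    low_enhancement_fraction,
)
from lungdce.recon import ImageSeries


def _series(frames, pixel=1.0, thick=1.0, times=None):
    frames = np.asarray(frames, dtype=np.float64)
    return ImageSeries(
        frames=frames,
        pixel_spacing_mm=pixel,
        slice_thickness_mm=thick,
        frame_mid_time=np.arange(frames.shape[0], dtype=float) if times is None else times,
    )


class TestBaseline:
    def test_constant_series(self):
        s = _series(np.full((60, 1, 4, 4), 3.25))
        np.testing.assert_allclose(L.compute_baseline(s), 3.25)

    def test_single_frame_range(self):
        frames = np.random.default_rng(0).uniform(1, 2, (5, 1, 3, 3))
        s = _series(frames)
        np.testing.assert_array_equal(L.compute_baseline(s, (1, 1)), frames[0])

    def test_too_few_frames_raises(self):
        s = _series(np.ones((10, 1, 2, 2)))
        with pytest.raises(ValueError):
            L.compute_baseline(s, (1, 50))

    def test_baseline_after_injection_rejected(self):
        s = _series(np.ones((60, 1, 2, 2)), times=np.arange(60) * 10.0)
        with pytest.raises(ValueError, match="injection"):
            L.compute_baseline(s, (1, 50), injection_time_s=100.0)

    def test_phantom_baseline_matches_truth(self, tiny_sim):
        spec, traj, k, gt = tiny_sim
        plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
        series = L.reconstruct_series(k, plan, zero_fill=1)
        s0 = L.compute_baseline(series, (1, 10), injection_time_s=spec.injection_time_s)
        par = gt.mask_for("parenchyma")
        assert s0[par].mean() == pytest.approx(
            spec.compartment_signal("parenchyma", 0.0), rel=0.05
        )


class TestRelativeEnhancement:
    def test_definition(self):
        s = _series(np.stack([np.full((1, 2, 2), 2.0), np.full((1, 2, 2), 4.0)]))
        re, valid = L.relative_enhancement(s, np.full((1, 2, 2), 2.0))
        np.testing.assert_allclose(re[0], 0.0)
        np.testing.assert_allclose(re[1], 1.0)
        assert valid.all()

    def test_zero_baseline_pixels_excluded(self):
        s = _series(np.ones((3, 1, 2, 2)))
        s0 = np.ones((1, 2, 2))
        s0[0, 0, 0] = 0.0
        re, valid = L.relative_enhancement(s, s0)
        assert not valid[0, 0, 0]
        np.testing.assert_array_equal(re[:, 0, 0, 0], 0.0)

    def test_phantom_vessel_peak_matches_spgr_oracle(self, tiny_sim):
        """Noise-free pixel RE at peak equals the closed-form course."""
        spec, traj, k, gt = tiny_sim
        plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
        series = L.reconstruct_series(k, plan, zero_fill=1)
        s0 = L.compute_baseline(series, (1, 10))
        re, _ = L.relative_enhancement(series, s0)
        ves = gt.mask_for("vessel")
        true_s0 = spec.compartment_signal("vessel", 0.0)
        f = int(np.argmax([re[i][ves].mean() for i in range(series.n_frames)]))
        p0, p1 = plan.frames[f]
        true_re = spec.compartment_signal("vessel", k.profile_time[p0:p1]).mean() / true_s0 - 1
        assert re[f][ves].mean() == pytest.approx(true_re, rel=0.06)


class TestBackground:
    def test_time_invariant_background_is_zero(self):
        s = _series(np.ones((60, 1, 16, 16)))
        np.testing.assert_allclose(L.background_trace(s, frame_range=(1, 50)), 0.0, atol=1e-12)

    def test_corner_roi_overlap_rejected(self):
        s = _series(np.ones((60, 1, 16, 16)))
        lung = np.ones((1, 16, 16), dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            L.background_trace(s, lung_mask=lung, frame_range=(1, 50), corner_size=4)

    def test_baseline_self_normalization(self):
        rng = np.random.default_rng(4)
        s = _series(rng.uniform(0.9, 1.1, (60, 1, 16, 16)))
        b = L.background_trace(s, frame_range=(1, 50), corner_size=4)
        assert abs(b[:50].mean()) < 1e-12

    def test_drift_tracking_noise_free(self):
        """b(t) follows a global per-frame k-space modulation m(t) exactly.

        A static phantom isolates the drift: the corner content then changes
        only through m, so the measured trace must reproduce m(t) - 1
        relative to the baseline mean.
        """
        from .conftest import tiny_phantom

        spec = tiny_phantom(noise_sd=0.0, drift_amplitude=0.0, duration_s=16.0)
        spec = dataclasses.replace(
            spec,
            compartments=[
                dataclasses.replace(c, enhancement=L.Enhancement())
                for c in spec.compartments
            ],
        )
        # 90-spoke-periodic angles: every frame sees identical spokes, so the
        # static corner content is constant and only m(t) moves the trace
        traj = L.build_trajectory(1800, 64, matrix_size=32, angle_increment=360.0 / 90)
        k, gt = L.simulate_kspace(spec, traj)
        plan = L.plan_sliding_window(k.n_profiles, 90, 90, k.meta.tr_eff_s)
        m_frame = 1.0 + 0.05 * np.sin(np.arange(plan.n_frames))
        data = k.data.copy()
        for (p0, p1), m in zip(plan.frames, m_frame):
            data[p0:p1] *= m
        series = L.reconstruct_series(dataclasses.replace(k, data=data), plan, zero_fill=1)
        b = background_trace(series, frame_range=(1, 10), corner_size=4)
        b_pred = m_frame / m_frame[:10].mean() - 1.0
        np.testing.assert_allclose(b, b_pred, atol=1e-9)


class TestCorrectBackground:
    def test_zero_drift_identity(self):
        re = np.random.default_rng(0).normal(size=(5, 1, 3, 3))
        np.testing.assert_array_equal(L.correct_background(re, np.zeros(5)), re)

    def test_re_equal_b_cancels(self):
        b = np.linspace(0, 0.5, 5)
        re = np.broadcast_to(b[:, None, None, None], (5, 1, 2, 2)).copy()
        np.testing.assert_allclose(L.correct_background(re, b), 0.0, atol=1e-15)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.correct_background(np.zeros((5, 1, 2, 2)), np.zeros(4))

    def test_divide_mode_exact_for_multiplicative_drift(self, tiny_sim):
        """Divide-mode correction removes a pure multiplicative drift exactly.

        A per-frame global modulation (amplitude 5%) is applied to the
        noise-free enhancing phantom; corrected curves must match the
        drift-free curves within 1e-3.
        """
        spec, traj, kc, gt = tiny_sim
        plan = L.plan_sliding_window(kc.n_profiles, 90, 90, kc.meta.tr_eff_s)
        m_frame = 1.0 + 0.05 * np.sin(0.7 * np.arange(plan.n_frames))
        data = kc.data.copy()
        for (p0, p1), m in zip(plan.frames, m_frame):
            data[p0:p1] *= m
        kd = dataclasses.replace(kc, data=data)
        roi = L.LungROI(gt.lung_mask, spec.pixel_spacing_mm, spec.slice_thickness_mm)

        curves = {}
        for name, k in (("drift", kd), ("clean", kc)):
            series = L.reconstruct_series(k, plan, zero_fill=1)
            s0 = L.compute_baseline(series, (1, 10))
            re, _ = L.relative_enhancement(series, s0)
            if name == "drift":
                b = m_frame / m_frame[:10].mean() - 1.0
            else:
                b = np.zeros(plan.n_frames)
            re_corr = L.correct_background(re, b, mode="divide")
            curves[name] = L.mean_lung_curve(re_corr, roi)
        np.testing.assert_allclose(curves["drift"], curves["clean"], atol=1e-3)


class TestBinning:
    @pytest.mark.parametrize(
        "peak, expected",
        [(0.5, 0), (1.0, 1), (2.5, 2), (3.9, 3), (5.0, 4), (8.0, 5), (11.9, 5), (12.0, 6), (40.0, 6)],
    )
    def test_threshold_edges(self, peak, expected):
        re = np.full((2, 1, 1, 1), peak)
        assert bin_pixels(re, np.array([True, True]))[0, 0, 0] == expected

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            bin_pixels(np.zeros((3, 1, 2, 2)), np.zeros(3, dtype=bool))

    @settings(deadline=None, max_examples=40)
    @given(
        hnp.arrays(
            dtype=np.float64,
            shape=st.tuples(
                st.integers(2, 6), st.integers(1, 2), st.integers(2, 5), st.integers(2, 5)
            ),
            elements=st.floats(-1, 20, allow_nan=False),
        )
    )
    def test_matches_per_pixel_oracle(self, re):
        """Vectorized binning equals an explicit per-pixel reclassification."""
        window = np.ones(re.shape[0], dtype=bool)
        got = bin_pixels(re, window)
        for z in range(re.shape[1]):
            for r in range(re.shape[2]):
                for c in range(re.shape[3]):
                    m = re[:, z, r, c].max()
                    if m < 1:
                        cls = 0
                    elif m < 2:
                        cls = 1
                    elif m < 3:
                        cls = 2
                    elif m < 4:
                        cls = 3
                    elif m < 8:
                        cls = 4
                    elif m < 12:
                        cls = 5
                    else:
                        cls = 6
                    assert got[z, r, c] == cls

    def test_bin_volumes_partition_lung(self):
        rng = np.random.default_rng(8)
        mask = rng.uniform(size=(2, 8, 8)) > 0.4
        roi = L.LungROI(mask, 0.302, 1.208)
        bmap = rng.integers(0, 7, size=(2, 8, 8)).astype(np.int8)
        vols = bin_volumes(bmap, roi)
        assert sum(vols.values()) == pytest.approx(L.lung_volume(roi), abs=1e-12)

    def test_all_pixels_one_class(self):
        mask = np.ones((1, 4, 4), dtype=bool)
        roi = L.LungROI(mask, 1.0, 1.0)
        vols = bin_volumes(np.full((1, 4, 4), 3, dtype=np.int8), roi)
        assert vols[3] == pytest.approx(L.lung_volume(roi))
        assert sum(v for c, v in vols.items() if c != 3) == 0

    def test_low_enhancement_fraction_arithmetic(self):
        # low = classes 0-2 (upper edges <= RE 3)
        vols = {0: 1.0, 1: 1.8, 2: 2.0, 3: 0.5, 4: 0.7, 5: 0.3, 6: 0.2}
        assert low_enhancement_fraction(vols, 6.5) == pytest.approx(4.8 / 6.5)


class TestCurvesAndVolume:
    def test_single_pixel_roi_curve(self):
        frames = np.random.default_rng(1).uniform(1, 2, (6, 1, 3, 3))
        mask = np.zeros((1, 3, 3), dtype=bool)
        mask[0, 1, 2] = True
        roi = L.LungROI(mask, 1.0, 1.0)
        np.testing.assert_array_equal(L.mean_lung_curve(frames, roi), frames[:, 0, 1, 2])

    def test_group_average_identical_animals_sem_zero(self):
        c = np.linspace(0, 1, 10)
        mean, sem = L.group_average([c, c, c])
        np.testing.assert_allclose(mean, c)
        np.testing.assert_allclose(sem, 0.0, atol=1e-15)

    def test_group_average_frame_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            L.group_average([np.zeros(5), np.zeros(6)])

    def test_lung_volume_hand_arithmetic(self):
        """1000 voxels at 0.302 x 0.302 x 1.208 mm = 0.1102 ml."""
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.reshape(-1)[:1000] = True
        roi = L.LungROI(mask, 0.302, 1.208)
        assert L.lung_volume(roi) == pytest.approx(1000 * 0.302**2 * 1.208 / 1000, rel=1e-12)
        assert L.lung_volume(roi) == pytest.approx(0.1102, abs=5e-5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            L.LungROI(np.zeros((1, 2, 2), dtype=bool), 1.0, 1.0)


class TestAnalyzeSeries:
    def test_full_analysis_on_tiny_phantom(self, tiny_sim):
        spec, traj, k, gt = tiny_sim
        plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
        series = L.reconstruct_series(k, plan, zero_fill=1)
        roi = L.LungROI(gt.lung_mask, spec.pixel_spacing_mm, spec.slice_thickness_mm)
        res = L.analyze_series(
            series,
            roi,
            baseline_frames=(1, 10),
            injection_time_s=spec.injection_time_s,
            post_window_s=8.0,
            corner_size=4,
        )
        assert res.lung_volume_ml == pytest.approx(gt.lung_volume_ml)
        assert sum(res.bin_volumes_ml.values()) == pytest.approx(res.lung_volume_ml)
        assert res.n_excluded == 0
        # enhancement is visible: mean curve rises after injection
        pre = res.mean_curve[res.frame_mid_time < spec.injection_time_s].max()
        post = res.mean_curve[res.frame_mid_time > spec.injection_time_s].max()
        assert post > pre + 0.5

    def test_ratio_mode_shifts_by_one(self, tiny_sim):
        spec, traj, k, gt = tiny_sim
        plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
        series = L.reconstruct_series(k, plan, zero_fill=1)
        roi = L.LungROI(gt.lung_mask, spec.pixel_spacing_mm, spec.slice_thickness_mm)
        kw = dict(baseline_frames=(1, 10), injection_time_s=spec.injection_time_s,
                  post_window_s=8.0, corner_size=4)
        delta = L.analyze_series(series, roi, re_mode="delta", **kw)
        ratio = L.analyze_series(series, roi, re_mode="ratio", **kw)
        np.testing.assert_allclose(ratio.mean_curve, delta.mean_curve + 1.0, atol=1e-12)


def test_day7_washout_curve_above_control():
    """Day-7 group mean RE stays above control during the washout phase.

    Small (matrix 32, 2-slice) simulations of both presets; the inflamed
    lesion's slow washout keeps the day-7 lung-mean enhancement elevated.
    """
    curves = {}
    inj = 420.0 * 2 / 38
    for name in ("control", "bleo_d7"):
        spec = L.desk_preset(name, matrix_size=32, n_slices=2, duration_s=30.0, seed=9)
        n_prof = int(spec.duration_s / (spec.tr_eff_ms / 1000.0))
        traj = L.build_trajectory(n_prof, 32, matrix_size=32)
        k, gt = L.simulate_kspace(spec, traj)
        plan = L.plan_sliding_window(k.n_profiles, 90, 60, k.meta.tr_eff_s)
        series = L.reconstruct_series(k, plan, zero_fill=1)
        roi = L.LungROI(gt.lung_mask, spec.pixel_spacing_mm, spec.slice_thickness_mm)
        res = L.analyze_series(series, roi, injection_time_s=inj, post_window_s=8.0)
        curves[name] = (res.frame_mid_time, res.mean_curve)
    t, c7 = curves["bleo_d7"]
    _, cc = curves["control"]
    washout = t > inj + 3.0  # after the vascular first pass
    assert np.all(c7[washout] > cc[washout])


def test_corner_rois_geometry():
    m = corner_rois((2, 32, 32), size=8)
    assert m.sum() == 2 * 4 * 64
    assert m[0, 0, 0] and m[1, -1, -1] and not m[0, 16, 16]


def test_default_thresholds_are_study_values():
    assert DEFAULT_THRESHOLDS == (1.0, 2.0, 3.0, 4.0, 8.0, 12.0)
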