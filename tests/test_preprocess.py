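"""Preprocessing: detrending, motion regression, framewise displacement,
smoothing, peak-sample extraction, averaging, ROI normalization, first-level
GLM and peri-stimulus time courses."""

import numpy as np
import pandas as pd
import pytest

from painpattern import (Mask, SyntheticConfig, VolumeSeries,
                         average_samples, detrend_zscore, double_gamma_hrf,
                         extract_peak_samples, extract_timecourses,
                         gaussian_smooth, generate_dataset, glm_betas,
                         regress_out_motion, roi_normalize, summarize_motion)
from painpattern.preprocess import (PatternSample, framewise_displacement,
                                    peak_volume_index)


def series_from_flat(flat, tr=1.0, shape=None):
    flat = np.asarray(flat, dtype=float)
    if shape is None:
        shape = (flat.shape[0], 1, 1)
    return VolumeSeries(flat.reshape(*shape, flat.shape[-1]), np.eye(4), tr)


def events_frame(onsets, modality="pain"):
    return pd.DataFrame({"onset_s": onsets, "modality": modality,
                         "level": None, "rating": 5.0, "run": 0})


class TestDetrendZscore:
    def test_linear_ramp_becomes_zero(self):
        t = np.arange(20.0)
        flat = np.vstack([3 + 0.5 * t, -1 - 2 * t, np.full(20, 7.0)])
        out = detrend_zscore(series_from_flat(flat))
        assert np.allclose(out.data, 0.0)

    def test_mean_zero_sd_one(self, rng):
        flat = rng.normal(size=(10, 50))
        out = detrend_zscore(series_from_flat(flat)).data.reshape(10, 50)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1), 1, atol=1e-12)

    def test_matches_regression_oracle(self):
        t = np.arange(40.0)
        y = np.sin(0.3 * t) + 0.17 * t + 2.0
        out = detrend_zscore(series_from_flat(y[None, :])).data.ravel()
        X = np.column_stack([np.ones_like(t), t])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(out, resid / resid.std(), atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend_zscore(series_from_flat(np.ones((1, 2))))


class TestMotionRegression:
    @pytest.mark.filterwarnings("ignore:dropping collinear")
    def test_zero_motion_only_demeans(self, rng):
        flat = rng.normal(size=(4, 30)) + 5.0
        out = regress_out_motion(series_from_flat(flat), np.zeros((30, 6)))
        got = out.data.reshape(4, 30)
        assert np.allclose(got, flat - flat.mean(axis=1, keepdims=True))

    def test_perfect_fit_gives_zero_residuals(self, rng):
        motion = rng.normal(size=(30, 6))
        flat = np.vstack([motion[:, 2], 3 * motion[:, 0] - motion[:, 5]])
        out = regress_out_motion(series_from_flat(flat), motion)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_motion(self, rng):
        motion = rng.normal(size=(40, 6))
        flat = rng.normal(size=(6, 40))
        resid = regress_out_motion(series_from_flat(flat), motion)
        dots = resid.data.reshape(6, 40) @ motion
        assert np.all(np.abs(dots) < 1e-8)

    def test_collinear_columns_dropped_with_warning(self, rng):
        motion = rng.normal(size=(30, 6))
        motion[:, 5] = 2 * motion[:, 0]
        flat = rng.normal(size=(2, 30))
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_out_motion(series_from_flat(flat), motion)
        dots = out.data.reshape(2, 30) @ motion[:, :5]
        assert np.all(np.abs(dots) < 1e-8)


class TestMotionSummary:
    def test_zero_motion_zero_fd(self):
        ev = events_frame([9.0])
        assert summarize_motion(np.zeros((20, 6)), ev, "pain", tr=3.0) == 0.0

    def test_single_step_hand_value(self):
        # onset 9 s, TR 3 s -> window volumes {3, 4, 5}; x jumps 1 mm at vol 4
        motion = np.zeros((20, 6))
        motion[4:, 0] = 1.0
        fd = framewise_displacement(motion)
        assert fd[4] == 1.0 and fd.sum() == 1.0
        got = summarize_motion(motion, events_frame([9.0]), "pain", tr=3.0,
                               window_volumes=3)
        assert got == pytest.approx(1.0 / 3.0)

    def test_rotation_radius_scaling(self):
        motion = np.zeros((5, 6))
        motion[1:, 3] = 0.01  # 0.01 rad step -> 0.5 mm at 50 mm radius
        assert framewise_displacement(motion)[1] == pytest.approx(0.5)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            summarize_motion(np.zeros((10, 6)), events_frame([3.0]), "touch",
                             tr=3.0)


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        s = series_from_flat(rng.normal(size=(8, 5)), shape=(2, 2, 2))
        assert gaussian_smooth(s, 0.0) is s

    def test_volume_mean_preserved(self, rng):
        data = rng.normal(size=(8, 8, 8, 3))
        s = VolumeSeries(data, np.diag([2.0, 2, 2, 1]), 1.0)
        out = gaussian_smooth(s, 8.0)
        for v in range(3):
            assert out.data[..., v].mean() == pytest.approx(
                data[..., v].mean(), abs=1e-6)

    def test_delta_matches_direct_convolution(self):
        data = np.zeros((15, 15, 15, 1))
        data[7, 7, 7, 0] = 1.0
        vox = 2.0
        s = VolumeSeries(data, np.diag([vox, vox, vox, 1]), 1.0)
        fwhm = 6.0
        out = gaussian_smooth(s, fwhm).data[..., 0]
        sigma = fwhm / 2.3548 / vox
        ax = np.arange(15) - 7.0
        g1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
        g1 /= g1.sum()
        expected = np.einsum("i,j,k->ijk", g1, g1, g1)
        assert np.allclose(out, expected, atol=1e-6)


class TestPeakExtraction:
    def test_volume_indexing_convention(self):
        assert peak_volume_index(10.0, 3.0, 2) == 5
        assert peak_volume_index(2.0, 0.8, 8) == 10

    def test_out_of_range_event_skipped(self, rng):
        s = series_from_flat(rng.normal(size=(4, 6)), shape=(4, 1, 1))
        mask = Mask(np.ones((4, 1, 1), dtype=bool))
        with pytest.warns(UserWarning, match="outside run"):
            samples = extract_peak_samples(s, events_frame([2.0, 30.0]), mask, 2)
        assert len(samples) == 1

    def test_noise_free_recovery_of_injected_pattern(self):
        cfg = SyntheticConfig(
            design="event_related_4mod", n_subjects=2, n_runs=1,
            stimuli_per_run_per_modality=4, grid_shape=(10, 10, 10),
            modality_pattern_amplitude={"pain": 3.0, "touch": 0.0,
                                        "audition": 0.0, "vision": 0.0},
            noise_sd=0.0, subject_pattern_jitter_sd=0.0, seed=11)
        ds = generate_dataset(cfg)
        truth = ds["truth"]
        run = ds["subjects"][0].runs[0]
        pain_ev = run.events[run.events["modality"] == "pain"]
        samples = extract_peak_samples(run.series, pain_ev,
                                       truth.roi_mask, 2)
        mean_sample = np.mean([s.values for s in samples], axis=0)
        pattern = truth.modality_patterns["pain"][truth.roi_mask.indices()]
        r = np.corrcoef(mean_sample, pattern)[0, 1]
        assert r >= 0.95


class TestAveraging:
    def test_single_group_identity_and_cancellation(self, rng):
        v = rng.normal(size=8)
        s1 = PatternSample(v, meta={"modality": "pain", "run": 0})
        s2 = PatternSample(-v, meta={"modality": "pain", "run": 1})
        only = average_samples([s1], by=("modality",))
        assert np.allclose(only[0].values, v)
        both = average_samples([s1, s2], by=("modality",))
        assert np.allclose(both[0].values, 0.0)

    def test_two_stage_average_equals_grand_mean(self, rng):
        # equal trials per run: per-run then cross-run mean == grand mean
        samples = []
        for run in range(4):
            for _ in range(8):
                samples.append(PatternSample(rng.normal(size=6),
                                             meta={"modality": "pain",
                                                   "run": run}))
        per_run = average_samples(samples, by=("modality", "run"))
        final = average_samples(per_run, by=("modality",))[0].values
        grand = np.mean([s.values for s in samples], axis=0)
        assert np.allclose(final, grand, atol=1e-12)

    def test_mixed_lengths_rejected(self, rng):
        a = PatternSample(rng.normal(size=5), meta={"modality": "pain"})
        b = PatternSample(rng.normal(size=6), meta={"modality": "pain"})
        with pytest.raises(ValueError):
            average_samples([a, b])


class TestRoiNormalize:
    def test_mean_zero_sd_one_and_idempotent(self, rng):
        s = PatternSample(rng.normal(2.0, 3.0, size=50), meta={})
        n1 = roi_normalize(s)
        assert abs(n1.values.mean()) < 1e-9
        assert abs(n1.values.std() - 1) < 1e-9
        assert n1.normalized
        n2 = roi_normalize(n1)
        assert np.allclose(n1.values, n2.values, atol=1e-9)

    def test_affine_invariance(self, rng):
        v = rng.normal(size=30)
        a = roi_normalize(PatternSample(v, meta={}))
        b = roi_normalize(PatternSample(2.5 * v - 7.0, meta={}))
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            roi_normalize(PatternSample(np.full(10, 3.0), meta={}))


class TestGLM:
    def _noise_free_run(self, amp=4.0):
        cfg = SyntheticConfig(
            design="event_related_4mod", n_subjects=2, n_runs=1,
            stimuli_per_run_per_modality=3, grid_shape=(10, 10, 10),
            modality_pattern_amplitude={"pain": amp, "touch": 0.0,
                                        "audition": 0.0, "vision": 0.0},
            noise_sd=0.0, subject_pattern_jitter_sd=0.0, seed=5)
        ds = generate_dataset(cfg)
        return ds, ds["subjects"][0].runs[0]

    def test_noise_free_amplitude_recovery(self):
        amp = 4.0
        ds, run = self._noise_free_run(amp)
        betas = glm_betas(run.series, run.events, run.motion)
        pattern = ds["truth"].modality_patterns["pain"] > 0
        recovered = betas["pain"][pattern].mean()
        assert recovered == pytest.approx(amp, rel=0.01)
        assert np.allclose(betas["touch"][pattern], 0.0, atol=1e-8)

    def test_zero_signal_zero_noise_gives_zero_betas(self):
        cfg = SyntheticConfig(
            design="event_related_4mod", n_subjects=2, n_runs=1,
            stimuli_per_run_per_modality=3, grid_shape=(8, 8, 8),
            modality_pattern_amplitude=0.0, shared_intensity_amplitude=0.0,
            noise_sd=0.0, subject_pattern_jitter_sd=0.0, seed=5)
        run = generate_dataset(cfg)["subjects"][0].runs[0]
        betas = glm_betas(run.series, run.events, run.motion)
        for b in betas.values():
            assert np.allclose(b, 0.0, atol=1e-8)

    def test_betas_invariant_to_baseline_and_drift(self):
        _, run = self._noise_free_run()
        b0 = glm_betas(run.series, run.events, run.motion)
        t = np.arange(run.series.n_volumes) * run.series.tr
        shifted = VolumeSeries(run.series.data + 100.0 + 0.01 * t,
                               run.series.affine, run.series.tr)
        b1 = glm_betas(shifted, run.events, run.motion)
        for c in b0:
            assert np.allclose(b0[c], b1[c], atol=1e-6)

    def test_rank_deficiency_names_columns(self, rng):
        _, run = self._noise_free_run()
        motion = np.asarray(run.motion).copy()
        motion[:, 1] = motion[:, 0]
        with pytest.raises(ValueError, match="motion"):
            glm_betas(run.series, run.events, motion)


class TestTimecourses:
    def test_window_lengths(self, rng):
        flat = rng.normal(size=(8, 80))
        s = series_from_flat(flat, tr=1.0, shape=(2, 2, 2))
        mask = Mask(np.ones((2, 2, 2), dtype=bool))
        ev = events_frame([10.0, 30.0, 50.0])
        tc5 = extract_timecourses(s, ev, mask, window=(-1, 5))
        assert len(tc5) == 7
        assert sorted(tc5["rel_volume"]) == list(range(-1, 6))
        tc15 = extract_timecourses(s, ev, mask, window=(-1, 15))
        assert len(tc15) == 17

    def test_constant_series_flat_course(self):
        s = series_from_flat(np.full((4, 40), 6.5), shape=(4, 1, 1))
        mask = Mask(np.ones((4, 1, 1), dtype=bool))
        tc = extract_timecourses(s, events_frame([10.0, 20.0]), mask,
                                 window=(-1, 5))
        assert np.allclose(tc["mean"], 6.5)
        assert np.allclose(tc["sd"], 0.0)
        assert (tc["n_trials"] == 2).all()

    def test_no_includable_events_rejected(self):
        s = series_from_flat(np.zeros((1, 10)), shape=(1, 1, 1))
        mask = Mask(np.ones((1, 1, 1), dtype=bool))
        with pytest.raises(ValueError):
            extract_timecourses(s, events_frame([9.5]), mask, window=(-1, 5))


def test_hrf_shape():
    t = np.linspace(0, 30, 301)
    h = double_gamma_hrf(t)
    assert h.max() == pytest.approx(1.0, abs=1e-6)
    assert 4.0 <= t[h.argmax()] <= 6.0
    assert np.all(double_gamma_hrf(np.array([-5.0, -0.1])) == 0)
    assert h[t > 10].min() < 0  # undershoot present
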