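"""Preprocessing chain: volume discarding, smoothing, detrending, band-pass,
motion regressors, FD, QC, nuisance regression and scrubbing."""

import numpy as np
import pytest

from gfcpipe.core import Bold4D, MotionTrace
from gfcpipe.preproc import (
    PreprocConfig,
    bandpass,
    detrend_linear,
    discard_initial,
    framewise_displacement,
    friston24,
    nuisance_regress,
    NuisanceDesign,
    preprocess_subject,
    qc_exclude,
    scrub,
    smooth_gaussian,
    tissue_mean_signal,
)
from gfcpipe.simdata import SimConfig, generate_cohort


def _bold(data, voxel=3.0, tr=2.0):
    return Bold4D(data=data, voxel_size_mm=voxel, tr_s=tr)


class TestDiscard:
    def test_removes_exactly_n_leading_volumes(self, rng):
        bold = _bold(rng.normal(size=(4, 4, 4, 250)))
        out = discard_initial(bold, 10)
        assert out.n_volumes == 240
        np.testing.assert_array_equal(out.data[..., 0], bold.data[..., 10])

    def test_zero_discard_is_identity(self, rng):
        bold = _bold(rng.normal(size=(3, 3, 3, 20)))
        np.testing.assert_array_equal(discard_initial(bold, 0).data, bold.data)

    def test_too_short_series_rejected(self, rng):
        bold = _bold(rng.normal(size=(3, 3, 3, 10)))
        with pytest.raises(ValueError, match="too short"):
            discard_initial(bold, 10)


class TestSmooth:
    def test_zero_fwhm_is_identity(self, rng):
        bold = _bold(rng.normal(size=(5, 5, 5, 4)))
        np.testing.assert_array_equal(smooth_gaussian(bold, 0.0).data, bold.data)

    def test_impulse_mass_conserved_and_symmetric(self):
        data = np.zeros((11, 11, 11, 1))
        data[5, 5, 5, 0] = 1.0
        out = smooth_gaussian(_bold(data), fwhm_mm=4.0).data[..., 0]
        assert abs(out.sum() - 1.0) < 1e-6
        np.testing.assert_allclose(out, out[::-1], atol=1e-12)  # mirror symmetry
        assert out[5, 5, 5] == out.max()
        assert out[5, 5, 5] > out[4, 5, 5] > out[3, 5, 5]  # monotone decay

    def test_constant_volume_unchanged(self):
        data = np.full((6, 6, 6, 2), 7.5)
        np.testing.assert_allclose(smooth_gaussian(_bold(data), 4.0).data, data, atol=1e-10)


class TestDetrend:
    def test_exact_line_removed(self):
        t = np.arange(50)
        series = 2.0 + 3.0 * t
        np.testing.assert_allclose(detrend_linear(series), 0.0, atol=1e-9)

    def test_residual_orthogonal_to_trend(self, rng):
        ts = rng.normal(size=(20, 80))
        out = detrend_linear(ts)
        t = np.arange(80, dtype=float)
        assert np.abs(out.sum(axis=-1)).max() < 1e-10
        assert np.abs(out @ (t - t.mean())).max() < 1e-8

    def test_passband_sine_amplitude_preserved(self):
        t = np.arange(200) * 2.0  # TR = 2 s
        series = np.sin(2 * np.pi * 0.05 * t)
        out = detrend_linear(series)
        amp_in = np.abs(np.fft.rfft(series))
        amp_out = np.abs(np.fft.rfft(out))
        k = amp_in.argmax()
        assert abs(amp_out[k] / amp_in[k] - 1.0) < 0.02


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,check",
        [(0.05, lambda r: r >= 0.95), (0.2, lambda r: r <= 0.05)],
    )
    def test_sinusoid_amplitude_ratio(self, freq, check):
        t = np.arange(240) * 2.0
        series = np.sin(2 * np.pi * freq * t)
        out = bandpass(series, tr_s=2.0)
        spec_in = np.abs(np.fft.rfft(series))
        spec_out = np.abs(np.fft.rfft(out))
        k = spec_in.argmax()
        assert check(spec_out[k] / spec_in[k])

    def test_zero_series_stays_zero(self):
        np.testing.assert_array_equal(bandpass(np.zeros(100), 2.0), np.zeros(100))

    def test_zero_phase_no_time_shift(self):
        t = np.arange(240) * 2.0
        series = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(series, tr_s=2.0)
        lags = np.arange(-5, 6)
        xc = [np.dot(np.roll(out, lag), series) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(50), tr_s=2.0, low_hz=0.01, high_hz=0.3)


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        design = friston24(MotionTrace(params=np.zeros((30, 6))))
        assert design.columns.shape == (30, 24)
        np.testing.assert_array_equal(design.columns, 0.0)

    def test_lag_and_square_definitions(self):
        T = 10
        params = np.zeros((T, 6))
        params[:, 2] = np.arange(T)  # p(t) = t for one parameter
        cols = friston24(MotionTrace(params=params)).columns
        t = np.arange(T, dtype=float)
        np.testing.assert_array_equal(cols[:, 2], t)
        np.testing.assert_array_equal(cols[:, 6 + 2], np.r_[0.0, t[:-1]])
        np.testing.assert_array_equal(cols[:, 12 + 2], t**2)
        np.testing.assert_array_equal(cols[0, 6:12], 0.0)


class TestFramewiseDisplacement:
    def test_constant_motion_gives_zero_fd(self):
        fd = framewise_displacement(MotionTrace(params=np.ones((20, 6))))
        np.testing.assert_array_equal(fd.fd, 0.0)
        assert fd.mean_fd == 0.0

    def test_hand_computed_step(self):
        params = np.zeros((3, 6))
        params[1] = [0.1, 0.1, 0.1, 0.001, 0.001, 0.001]
        params[2] = params[1]
        fd = framewise_displacement(MotionTrace(params=params), head_radius_mm=50.0)
        assert fd.fd[0] == 0.0
        assert abs(fd.fd[1] - 0.45) < 1e-12  # 0.3 mm + 50 * 0.003 rad
        assert fd.fd[2] == 0.0

    def test_fd_is_linear_in_motion(self, rng):
        params = rng.normal(size=(15, 6))
        fd1 = framewise_displacement(MotionTrace(params=params)).fd
        fd2 = framewise_displacement(MotionTrace(params=2 * params)).fd
        np.testing.assert_allclose(fd2, 2 * fd1, rtol=1e-12)


class TestQcExclude:
    @pytest.mark.parametrize(
        "trans,rot_deg,expect",
        [
            (2.1, 0.0, True),  # exceeds 2 mm
            (2.0, 2.0, False),  # exactly at the limits: kept (strict inequality)
            (0.0, 0.0, False),
            (0.0, 2.5, True),
        ],
    )
    def test_two_mm_two_degree_rule(self, trans, rot_deg, expect):
        params = np.zeros((10, 6))
        params[5, 0] = trans
        params[7, 4] = np.radians(rot_deg)
        assert qc_exclude(MotionTrace(params=params)) is expect


class TestNuisanceRegress:
    def test_design_column_fully_removed(self, rng):
        col = rng.normal(size=40)
        design = NuisanceDesign(columns=col[:, None], labels=["c"])
        ts = np.vstack([col, 2.5 * col])
        np.testing.assert_allclose(nuisance_regress(ts, design), 0.0, atol=1e-10)

    def test_zero_design_demeans(self, rng):
        ts = rng.normal(size=(5, 30)) + 10.0
        design = NuisanceDesign(columns=np.zeros((30, 4)), labels=list("abcd"))
        out = nuisance_regress(ts, design)
        np.testing.assert_allclose(out, ts - ts.mean(axis=1, keepdims=True), atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        ts = rng.normal(size=(30, 100))
        cols = rng.normal(size=(100, 8))
        design = NuisanceDesign(columns=cols, labels=[f"n{i}" for i in range(8)])
        resid = nuisance_regress(ts, design)
        assert np.abs(resid @ cols).max() < 1e-8

    def test_collinear_columns_named(self, rng):
        col = rng.normal(size=50)
        design = NuisanceDesign(columns=np.column_stack([col, col]), labels=["a", "dup"])
        with pytest.raises(ValueError, match="dup"):
            nuisance_regress(rng.normal(size=(3, 50)), design)


class TestScrub:
    def test_high_fd_frames_censored(self):
        from gfcpipe.preproc import FdSeries

        fd = FdSeries(fd=np.array([0.0, 0.1, 0.25, 0.15]), mean_fd=0.125, head_radius_mm=50)
        ts = np.arange(8).reshape(2, 4).astype(float)
        out, mask = scrub(ts, fd, threshold_mm=0.2, min_volumes=1)
        np.testing.assert_array_equal(mask.kept, [0, 1, 3])
        np.testing.assert_array_equal(out, ts[:, [0, 1, 3]])

    def test_boundary_fd_exactly_at_threshold_kept(self):
        from gfcpipe.preproc import FdSeries

        fd = FdSeries(fd=np.array([0.0, 0.2, 0.3]), mean_fd=0.17, head_radius_mm=50)
        _, mask = scrub(np.zeros((1, 3)), fd, threshold_mm=0.2, min_volumes=1)
        np.testing.assert_array_equal(mask.kept, [0, 1])

    def test_clean_series_untouched_and_flagging(self):
        from gfcpipe.preproc import FdSeries

        fd = FdSeries(fd=np.zeros(10), mean_fd=0.0, head_radius_mm=50)
        ts = np.random.default_rng(0).normal(size=(2, 10))
        out, mask = scrub(ts, fd, min_volumes=5)
        np.testing.assert_array_equal(out, ts)
        assert not mask.insufficient
        with pytest.warns(UserWarning, match="flagged"):
            _, mask = scrub(ts, fd, min_volumes=50)
        assert mask.insufficient


class TestTissueMeanSignal:
    def test_single_voxel_mask_returns_that_series(self, rng):
        data = rng.normal(size=(3, 3, 3, 12))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 2, 0] = True
        np.testing.assert_array_equal(
            tissue_mean_signal(_bold(data), mask), data[1, 2, 0]
        )

    def test_two_voxel_mask_averages(self, rng):
        data = rng.normal(size=(2, 2, 2, 5))
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        np.testing.assert_allclose(
            tissue_mean_signal(_bold(data), mask),
            (data[0, 0, 0] + data[1, 1, 1]) / 2,
        )

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            tissue_mean_signal(_bold(rng.normal(size=(2, 2, 2, 5))), np.zeros((2, 2, 2), bool))


def test_full_chain_preserves_planted_latent():
    """A band-limited planted signal survives the whole chain nearly intact."""
    cfg = SimConfig(
        n_patients=1, n_controls=1, n_volumes=160, noise_sd=0.1, n_latents=1,
        motion_spike_rate=0.0, drift_sd=0.3, seed=31,
    )
    subjects, truth = generate_cohort(cfg)
    subject = subjects[1]  # control: full baseline coupling everywhere
    wm = truth.wm_prob > 0.8
    csf = truth.csf_prob > 0.8
    pconf = PreprocConfig(min_volumes=40)
    still = MotionTrace(params=np.zeros((cfg.n_volumes, 6)))  # no-motion condition
    res = preprocess_subject(subject.bold, still, wm, csf, pconf)
    assert not res.excluded and not res.censor.insufficient
    gm = truth.gm_prob > 0.2
    clean_mean = res.clean.data[gm].mean(axis=0)
    latent = truth.global_latents[subject.id][pconf.n_discard:][res.censor.kept]
    r = np.corrcoef(clean_mean, latent)[0, 1]
    assert r >= 0.9
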