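import numpy as np
import pytest

from oscipp.errors import (
    BeatDetectionError,
    DerivativeError,
    FitError,
    OscillogramError,
)
from oscipp.oscillometry import (
    BeatSeries,
    DiscreteOscillogram,
    OscillogramFit,
    build_oscillogram,
    compute_hr,
    compute_pp,
    compute_rhogh,
    detect_beats,
    estimate,
    fit_oscillogram,
    oscillogram_model,
    smooth_oscillogram,
)
from oscipp.signal_sim import SimConfig, simulate_session


def grid_pp_oracle(fit: OscillogramFit, n: int = 10_000) -> float:
    """Independent derivative-extrema search: finite differences of the
    model values on a dense grid (no analytic slope)."""
    pad = 8.0 * max(fit.w1, fit.w2)
    x = np.linspace(fit.c1 - pad, fit.c2 + pad, n)
    y = oscillogram_model(x, *fit.params)
    d = np.diff(y) / np.diff(x)
    xm = 0.5 * (x[:-1] + x[1:])
    return float(xm[np.argmin(d)] - xm[np.argmax(d)])


class TestDetectBeats:
    def test_pure_sinusoid(self):
        rate = 100.0
        t = np.arange(int(30 * rate)) / rate
        ppg = 1.0 * np.sin(2 * np.pi * 1.0 * t)  # peak-to-peak 2.0
        beats = detect_beats(ppg, rate)
        assert not beats.no_oscillations
        assert abs(len(beats) - 30) <= 1
        np.testing.assert_allclose(beats.pa, 2.0, rtol=0.1)
        np.testing.assert_allclose(beats.intervals_s, 1.0, atol=0.05)

    def test_simulator_beat_count_matches_ground_truth(self):
        cfg = SimConfig(noise_sd_ppg=0.001, seed=7)
        session, truth = simulate_session(cfg)
        beats = detect_beats(session.ppg, cfg.ppg_rate_hz)
        assert abs(len(beats) - len(truth.beat_times_s)) <= 1

    def test_constant_signal_flags_no_oscillations(self):
        beats = detect_beats(np.full(3000, 5.0), 100.0)
        assert beats.no_oscillations
        assert len(beats) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(BeatDetectionError):
            detect_beats(np.zeros(100), 100.0)

    def test_amplitudes_positive(self):
        session, _ = simulate_session(SimConfig(noise_sd_ppg=0.01, seed=3))
        beats = detect_beats(session.ppg, 30.0)
        assert np.all(beats.pa > 0)
        assert np.all(beats.intervals_s > 0)
        assert len(beats.intervals_s) == len(beats) - 1


class TestComputeRhogh:
    def test_typical_arm_swing(self):
        # rho*g*L for L = 0.577 m is the ±45 mmHg hydrostatic swing
        assert compute_rhogh(1.0, 0.577) == pytest.approx(45.0, abs=0.01)
        assert compute_rhogh(-1.0, 0.577) == pytest.approx(-45.0, abs=0.01)

    def test_heart_level_is_zero(self):
        assert compute_rhogh(0.0, 0.577) == 0.0

    def test_clipping(self):
        assert compute_rhogh(1.7, 0.577) == compute_rhogh(1.0, 0.577)

    def test_vectorized(self):
        out = compute_rhogh(np.array([1.0, 0.0, -1.0]), 0.577)
        np.testing.assert_allclose(out, [45.0, 0.0, -45.0], atol=0.01)

    def test_bad_arm_length(self):
        with pytest.raises(ValueError):
            compute_rhogh(1.0, 0.0)
        with pytest.raises(ValueError):
            compute_rhogh(1.0, -0.5)


def _beats(times, pa, spans=None):
    times = np.asarray(times, dtype=float)
    pa = np.asarray(pa, dtype=float)
    if spans is None:
        spans = np.column_stack([times - 0.4, times + 0.4])
    return BeatSeries(beat_times_s=times, pa=pa,
                      intervals_s=np.diff(times), spans_s=np.asarray(spans))


class TestBuildOscillogram:
    def test_normalization_to_unity(self):
        t = np.arange(5, dtype=float) + 1
        beats = _beats(t, [1, 2, 4, 2, 1])
        t_r = np.linspace(0, 10, 101)
        osc = build_oscillogram(beats, t_r, np.linspace(45, -45, 101))
        assert osc.pa_norm.max() == 1.0
        assert sorted(osc.pa_norm.tolist()) == [0.25, 0.25, 0.5, 0.5, 1.0]

    def test_mean_rhogh_of_linear_ramp(self):
        # beat spanning t in [1, 2] s with rhogh falling 45 -> 44 over it
        beats = _beats([1.5] * 5, [1, 2, 3, 2, 1],
                       spans=[[1.0, 2.0]] * 5)
        beats.intervals_s = np.full(4, 0.1)
        t_r = np.array([0.0, 1.0, 2.0, 3.0])
        rhogh = np.array([46.0, 45.0, 44.0, 43.0])
        osc = build_oscillogram(beats, t_r, rhogh)
        np.testing.assert_allclose(osc.rhogh, 44.5, rtol=1e-12)

    def test_too_few_beats(self):
        beats = _beats([1, 2, 3], [1, 2, 1])
        with pytest.raises(OscillogramError):
            build_oscillogram(beats, np.linspace(0, 5, 10), np.linspace(45, 40, 10))

    def test_rhogh_must_cover_spans(self):
        beats = _beats([1, 2, 3, 4, 5], [1, 2, 3, 2, 1])
        with pytest.raises(OscillogramError):
            build_oscillogram(beats, np.linspace(2, 4, 10), np.linspace(10, 0, 10))

    def test_sorted_descending_rhogh(self, clean_session):
        session, _ = clean_session
        beats = detect_beats(session.ppg, 30.0)
        rhogh = compute_rhogh(session.accel_z, session.arm_length_m)
        osc = build_oscillogram(beats, session.t_accel, rhogh)
        assert np.all(np.diff(osc.rhogh) <= 0)

    def test_pairing_matches_ground_truth(self, clean_session):
        session, truth = clean_session
        beats = detect_beats(session.ppg, 30.0)
        rhogh = compute_rhogh(session.accel_z, session.arm_length_m)
        osc = build_oscillogram(beats, session.t_accel, rhogh)
        # oracle: ground-truth rhogh at each beat's span midpoint
        mids = beats.spans_s.mean(axis=1)
        expected = np.interp(mids, truth.rhogh_t_s, truth.rhogh_mmHg)
        expected = expected[np.argsort(-expected, kind="stable")]
        np.testing.assert_allclose(osc.rhogh, expected, atol=0.5)


class TestSmoothOscillogram:
    def test_constant_unchanged(self):
        osc = DiscreteOscillogram(np.linspace(45, -45, 9), np.full(9, 0.7))
        out = smooth_oscillogram(osc)
        np.testing.assert_allclose(out.pa_norm, 0.7)

    def test_impulse_center_value(self):
        osc = DiscreteOscillogram(np.linspace(4, 0, 5), [0, 0, 1, 0, 0])
        out = smooth_oscillogram(osc)
        assert out.pa_norm[2] == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.random(23)
        osc = DiscreteOscillogram(np.linspace(45, -45, 23), y)
        out = smooth_oscillogram(osc)
        # direct loop oracle with shrinking symmetric windows
        for i in range(23):
            k = min(2, i, 22 - i)
            assert out.pa_norm[i] == pytest.approx(np.mean(y[i - k:i + k + 1]))

    def test_rhogh_axis_unchanged(self):
        x = np.linspace(45, -45, 11)
        out = smooth_oscillogram(DiscreteOscillogram(x, np.random.default_rng(1).random(11)))
        np.testing.assert_array_equal(out.rhogh, x)

    def test_too_few_points(self):
        with pytest.raises(OscillogramError):
            smooth_oscillogram(DiscreteOscillogram([1, 2, 3], [1, 2, 3]))


class TestFitOscillogram:
    def _model_osc(self, amp=1.0, c1=-20, c2=20, w1=4, w2=4, n=40, noise=0.0, seed=0):
        x = np.linspace(45, -45, n)
        y = oscillogram_model(x, amp, c1, c2, w1, w2)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, size=n)
        return DiscreteOscillogram(x, y)

    def test_self_consistency(self):
        osc = self._model_osc()
        fit = fit_oscillogram(osc)
        assert fit.rms_residual < 1e-6
        assert fit.c1 == pytest.approx(-20, abs=0.01)
        assert fit.c2 == pytest.approx(20, abs=0.01)
        assert fit.w1 == pytest.approx(4, abs=0.01)
        assert fit.w2 == pytest.approx(4, abs=0.01)

    def test_fitted_maximum_inside_data_range(self, clean_session):
        session, _ = clean_session
        beats = detect_beats(session.ppg, 30.0)
        rhogh = compute_rhogh(session.accel_z, session.arm_length_m)
        osc = smooth_oscillogram(build_oscillogram(beats, session.t_accel, rhogh))
        fit = fit_oscillogram(osc)
        grid = np.linspace(osc.rhogh.min() - 30, osc.rhogh.max() + 30, 5001)
        x_peak = grid[np.argmax(oscillogram_model(grid, *fit.params))]
        assert osc.rhogh.min() <= x_peak <= osc.rhogh.max()

    def test_noise_robustness_of_width(self):
        clean_fit = fit_oscillogram(self._model_osc())
        noisy_fit = fit_oscillogram(self._model_osc(noise=0.02, seed=4))
        gap_clean = clean_fit.c2 - clean_fit.c1
        gap_noisy = noisy_fit.c2 - noisy_fit.c1
        assert abs(gap_noisy - gap_clean) / gap_clean < 0.10

    def test_monotone_data_rejected(self):
        x = np.linspace(45, -45, 20)
        y = np.linspace(0.1, 1.0, 20)
        with pytest.raises(FitError):
            fit_oscillogram(DiscreteOscillogram(x, y))

    def test_monotone_override(self):
        x = np.linspace(45, -45, 20)
        y = oscillogram_model(x, 1.0, -60, 20, 4, 4)  # ascending limb off-range
        fit = fit_oscillogram(DiscreteOscillogram(x, y), require_interior_peak=False)
        assert fit.c2 == pytest.approx(20, abs=1.0)


class TestComputePP:
    def test_boxcar_limit(self):
        # steep sigmoids: slope extrema collapse onto the centers
        fit = OscillogramFit(amp=1.0, c1=-15.0, c2=15.0, w1=0.05, w2=0.05,
                             rms_residual=0.0)
        assert compute_pp(fit) == pytest.approx(30.0, abs=0.05)

    def test_matches_grid_oracle_on_random_fits(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            w1, w2 = rng.uniform(1, 10, size=2)
            c1 = rng.uniform(-40, 0)
            c2 = c1 + max(rng.uniform(10, 80), 3 * max(w1, w2))
            fit = OscillogramFit(amp=rng.uniform(0.5, 2.0), c1=c1, c2=c2,
                                 w1=w1, w2=w2, rms_residual=0.0)
            assert abs(compute_pp(fit) - grid_pp_oracle(fit)) < 0.1

    def test_positive_result(self):
        fit = OscillogramFit(amp=1.0, c1=-20, c2=20, w1=5, w2=5, rms_residual=0.0)
        assert compute_pp(fit) > 0

    def test_degenerate_fit_rejected_by_type(self):
        with pytest.raises(FitError):
            OscillogramFit(amp=1.0, c1=20, c2=-20, w1=5, w2=5, rms_residual=0.0)
        with pytest.raises(FitError):
            OscillogramFit(amp=1.0, c1=-20, c2=20, w1=-5, w2=5, rms_residual=0.0)


class TestComputeHR:
    def test_one_second_intervals(self):
        beats = _beats(np.arange(10, dtype=float), np.ones(10))
        assert compute_hr(beats) == pytest.approx(60.0)

    def test_half_second_intervals(self):
        beats = _beats(np.arange(10) * 0.5, np.ones(10))
        assert compute_hr(beats) == pytest.approx(120.0)

    def test_median_robust_to_artifact(self):
        # one 5 s dropout artifact among ~1 s intervals leaves HR at 60
        times = np.cumsum([0.0, 0.9, 1.0, 1.0, 1.1, 5.0])
        beats = _beats(times, np.ones(6))
        assert compute_hr(beats) == pytest.approx(60.0)

    def test_too_few_beats(self):
        with pytest.raises(BeatDetectionError):
            compute_hr(_beats([1.0], [1.0]))


class TestEstimate:
    def test_recovers_pp_within_2mmhg(self):
        cfg = SimConfig(sp_heart=120, dp_heart=80, seed=21)
        session, _ = simulate_session(cfg)
        result = estimate(session)
        assert result.validity.overall
        assert result.pp_mmHg == pytest.approx(40.0, abs=2.0)
        assert result.hr_bpm == pytest.approx(70.0, rel=0.05)

    def test_incomplete_session_yields_no_pp(self):
        session, _ = simulate_session(SimConfig(contact_pressure_mmHg=20.0, seed=2))
        result = estimate(session)
        assert not result.validity.completeness_ok
        assert not result.validity.overall
        assert result.pp_mmHg is None

    def test_deterministic(self):
        cfg = SimConfig(noise_sd_ppg=0.01, seed=33)
        session, _ = simulate_session(cfg)
        r1 = estimate(session)
        r2 = estimate(session)
        assert r1.pp_mmHg == r2.pp_mmHg
        assert r1.hr_bpm == r2.hr_bpm


class TestPipelineInvariances:
    """PP must not depend on the unknown contact pressure (a pure shift of
    the pressure axis) nor on the PPG gain (a pure amplitude scale)."""

    def _fit_pp(self, osc):
        return compute_pp(fit_oscillogram(smooth_oscillogram(osc)))

    def _session_osc(self):
        session, _ = simulate_session(SimConfig(seed=5))
        beats = detect_beats(session.ppg, 30.0)
        rhogh = compute_rhogh(session.accel_z, session.arm_length_m)
        return build_oscillogram(beats, session.t_accel, rhogh)

    def test_shift_invariance(self):
        osc = self._session_osc()
        pp0 = self._fit_pp(osc)
        shifted = DiscreteOscillogram(osc.rhogh + 17.3, osc.pa_norm)
        assert self._fit_pp(shifted) == pytest.approx(pp0, abs=0.05)

    def test_amplitude_scale_invariance(self):
        session, _ = simulate_session(SimConfig(seed=5))
        beats = detect_beats(session.ppg * 3.7, 30.0)
        rhogh = compute_rhogh(session.accel_z, session.arm_length_m)
        osc = build_oscillogram(beats, session.t_accel, rhogh)
        assert self._fit_pp(osc) == pytest.approx(self._fit_pp(self._session_osc()),
                                                  abs=0.05)
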