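import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from okrsphere.simulate import default_truth, simulate_trace
from okrsphere.stimulus import StimulusSpec, stimulus_position_amplitude
from okrsphere.traces import (
    EyeTrace,
    IsiSegmentation,
    PiecewiseSinusoidModel,
    bode_point,
    detect_saccades,
    fit_piecewise_sinusoid,
    okr_gain,
    qc_trial,
)


def make_trace(angle_fn, duration=100.0, rate=60.0, **kw):
    t = np.arange(0.0, duration, 1.0 / rate)
    return EyeTrace(t=t, angle=angle_fn(t), **kw)


class TestSaccadeDetection:
    def test_slow_sinusoid_has_no_saccades(self):
        # amplitude 2 deg at 0.1 Hz peaks at 1.26 deg/s, far below threshold
        tr = make_trace(lambda t: 2.0 * np.sin(2 * np.pi * 0.1 * t))
        seg = detect_saccades(tr, vel_threshold=50.0)
        assert seg.n_saccades == 0
        assert len(seg.isis) == 1

    def test_step_resets_are_found_at_the_right_times(self):
        times = [12.3, 24.7, 39.9]

        def angle(t):
            a = np.zeros_like(t)
            for ts in times:
                a += 8.0 * (t >= ts)
            return a

        tr = make_trace(angle, duration=60.0)
        seg = detect_saccades(tr)
        assert seg.n_saccades == 3
        for (a, b), ts in zip(seg.saccade_intervals, times):
            # onset within +/-2 samples of the step, before padding
            assert a <= ts <= b
            assert abs((a + 0.1) - ts) <= 2 / 60 + 1e-9

    def test_constant_trace_single_isi(self):
        tr = make_trace(lambda t: np.full_like(t, 3.0), duration=10.0)
        seg = detect_saccades(tr)
        assert seg.n_saccades == 0
        assert seg.isis == [(0, tr.t.size)]

    def test_short_trace_rejected(self):
        tr = make_trace(lambda t: t, duration=1.0)
        with pytest.raises(ValueError):
            detect_saccades(tr)
        with pytest.raises(ValueError):
            detect_saccades(EyeTrace(t=np.array([]), angle=np.array([])))


class TestPiecewiseSinusoidFit:
    def test_exact_recovery_single_isi(self):
        tr = make_trace(lambda t: -2.0 * np.cos(0.6283 * t))
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        assert fit.c1 == pytest.approx(2.0, abs=1e-6)
        assert fit.c2 == pytest.approx(0.6283, abs=1e-6)
        assert abs(fit.c3) < 1e-6
        assert fit.offsets == pytest.approx([0.0], abs=1e-6)

    def test_exact_recovery_with_offsets(self):
        offsets = [0.0, 5.0, -3.0]
        bounds = [(0, 1800), (1800, 3600), (3600, 6000)]

        def angle(t):
            a = -2.0 * np.cos(0.6283 * t)
            a[1800:3600] += 5.0
            a[3600:] += -3.0
            return a

        tr = make_trace(angle)
        seg = IsiSegmentation(saccade_intervals=[], isis=bounds)
        fit = fit_piecewise_sinusoid(tr, seg, f_init=0.1)
        assert fit.c1 == pytest.approx(2.0, abs=1e-6)
        assert fit.offsets == pytest.approx(offsets, abs=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        c1=st.floats(0.1, 10.0),
        f=st.floats(0.085, 0.115),
        c3=st.floats(-math.pi + 1e-3, math.pi - 1e-3),
        off=st.floats(-20.0, 20.0),
    )
    def test_exact_recovery_property(self, c1, f, c3, off):
        c2 = 2 * math.pi * f
        tr = make_trace(lambda t: -c1 * np.cos(c2 * t + c3) + off, duration=40.0)
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        assert fit.c1 == pytest.approx(c1, abs=1e-6)
        assert fit.c2 == pytest.approx(c2, abs=1e-6)
        # phase equality modulo 2*pi
        assert math.cos(fit.c3 - c3) == pytest.approx(1.0, abs=1e-9)
        assert fit.offsets == pytest.approx([off], abs=1e-6)

    def test_amplitude_sign_normalised(self):
        tr = make_trace(lambda t: 2.0 * np.cos(0.6283 * t))  # flipped sign
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        assert fit.c1 > 0
        assert abs(abs(fit.c3) - math.pi) < 1e-6

    def test_gain_unbiased_under_noise(self):
        # sd 0.2 deg on amplitude 2 deg: mean recovered c1 within 5%
        rng = np.random.default_rng(5)
        est = []
        for _ in range(100):
            tr = make_trace(
                lambda t: -2.0 * np.cos(0.6283 * t)
                + rng.normal(0, 0.2, t.size),
                duration=50.0,
            )
            est.append(fit_piecewise_sinusoid(tr, f_init=0.1).c1)
        assert np.mean(est) == pytest.approx(2.0, rel=0.05)

    def test_saccade_removal_invariance(self):
        # adding quick-phase resets must not move the amplitude estimate
        spec = StimulusSpec()
        truth0 = default_truth(sigma_e=0.0, saccade_rate=0.0)
        truth1 = default_truth(sigma_e=0.0, saccade_rate=0.3)
        rng = np.random.default_rng(2)
        clean = simulate_trace(0.25, spec, truth0, rng)
        c1_clean = fit_piecewise_sinusoid(clean, f_init=0.1).c1
        sacc = simulate_trace(0.25, spec, truth1, rng)
        seg = detect_saccades(sacc)
        c1_sacc = fit_piecewise_sinusoid(sacc, seg, f_init=0.1).c1
        assert abs(c1_sacc - c1_clean) < 1e-3

    def test_degenerate_isi_set_rejected(self):
        tr = make_trace(lambda t: np.sin(t), duration=10.0)
        with pytest.raises(ValueError):
            PiecewiseSinusoidModel(tr, IsiSegmentation([], []))


class TestGainAndBode:
    def test_gain_definition(self, default_spec):
        a_s = stimulus_position_amplitude(default_spec)
        tr = make_trace(lambda t: -a_s * np.cos(2 * np.pi * 0.1 * t))
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        rec = okr_gain(fit, default_spec)
        assert rec.gain == pytest.approx(1.0, abs=1e-6)

    def test_gain_example_values(self, default_spec):
        tr = make_trace(lambda t: -1.989 * np.cos(2 * np.pi * 0.1 * t))
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        assert okr_gain(fit, default_spec).gain == pytest.approx(0.100, abs=1e-3)

    def test_gain_scale_equivariance(self, default_spec):
        lam = 3.7
        tr1 = make_trace(lambda t: -2.0 * np.cos(2 * np.pi * 0.1 * t))
        tr2 = make_trace(lambda t: -2.0 * lam * np.cos(2 * np.pi * 0.1 * t))
        g1 = okr_gain(fit_piecewise_sinusoid(tr1, f_init=0.1), default_spec).gain
        g2 = okr_gain(fit_piecewise_sinusoid(tr2, f_init=0.1), default_spec).gain
        assert g2 == pytest.approx(lam * g1, rel=1e-9)

    def test_bode_identity_and_quarter_period_lag(self, default_spec):
        a_s = stimulus_position_amplitude(default_spec)
        tr = make_trace(lambda t: -a_s * np.cos(2 * np.pi * 0.1 * t))
        mag, phase = bode_point(fit_piecewise_sinusoid(tr, f_init=0.1), default_spec)
        assert (mag, phase) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-6))
        lag = 2.5  # quarter of the 10 s envelope period
        tr = make_trace(lambda t: -a_s * np.cos(2 * np.pi * 0.1 * (t - lag)))
        _, phase = bode_point(fit_piecewise_sinusoid(tr, f_init=0.1), default_spec)
        assert phase == pytest.approx(-90.0, abs=1e-3)

    def test_bode_first_order_lag_matches_analytic(self, default_spec):
        # first-order low-pass with time constant tau: phase = -atan(w*tau)
        tau = 1.2
        w = 2 * np.pi * 0.1
        expected = -math.degrees(math.atan(w * tau))
        gain_analytic = 1.0 / math.sqrt(1 + (w * tau) ** 2)
        a_s = stimulus_position_amplitude(default_spec)
        tr = make_trace(
            lambda t: -a_s
            * gain_analytic
            * np.cos(w * t + math.atan(w * tau) * -1)
        )
        mag, phase = bode_point(fit_piecewise_sinusoid(tr, f_init=0.1), default_spec)
        assert phase == pytest.approx(expected, abs=2.0)
        assert mag == pytest.approx(gain_analytic, abs=1e-6)


class TestQc:
    def test_clean_trace_accepted(self):
        tr = make_trace(lambda t: -2.0 * np.cos(0.6283 * t))
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        ok, reason = qc_trial(fit, tr)
        assert ok and reason == ""

    def test_drift_rejected(self):
        tr = make_trace(lambda t: -2.0 * np.cos(0.6283 * t) + 0.5 * t)
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        ok, reason = qc_trial(fit, tr)
        assert not ok and reason == "drift"

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(9)
        tr = make_trace(lambda t: rng.normal(0, 1.0, t.size))
        fit = fit_piecewise_sinusoid(tr, f_init=0.1)
        ok, reason = qc_trial(fit, tr)
        assert not ok and reason == "low_r2"
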