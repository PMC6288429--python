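"""Trace analytics on synthetic inputs with closed-form answers: decay
fitting, APD90, EAD counting and beat classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hfmicro.protocols import (
    BeatMetrics, ClampProtocol, classify_beats, compute_apd90,
    fit_exponential_decay,
)


class TestDecayFit:
    @settings(deadline=None, max_examples=30)
    @given(tau=st.floats(5.0, 400.0), amp=st.floats(0.5, 10.0),
           off=st.floats(-1.0, 0.0))
    def test_recovers_known_exponential(self, tau, amp, off):
        """Noise-free mono-exponential recovered to better than 0.1%."""
        t = np.arange(0.0, 500.0, 0.1)
        current = -amp * np.exp(-t / tau) + off
        fit = fit_exponential_decay(t, current)
        assert fit.tau_ms == pytest.approx(tau, rel=1e-3)
        assert not fit.flagged

    def test_window_starts_at_95_percent_of_peak(self):
        # rising-then-decaying current; the fit must ignore the rise
        t = np.arange(0.0, 500.0, 0.1)
        current = -(1 - np.exp(-t / 3.0)) * np.exp(-t / 50.0)
        fit = fit_exponential_decay(t, current)
        assert fit.tau_ms == pytest.approx(50.0, rel=0.1)

    def test_nonmonotone_trace_is_flagged_not_rejected(self):
        t = np.arange(0.0, 500.0, 0.1)
        current = -np.exp(-t / 40.0) - 0.5 * np.exp(-((t - 300) / 30.0) ** 2)
        fit = fit_exponential_decay(t, current)
        assert fit.flagged
        assert fit.rms_residual > 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            fit_exponential_decay(np.array([0.0, 0.1]), np.array([-1.0, -0.9]))


class TestApd90:
    def test_triangular_ap_closed_form(self):
        """Triangle AP: peak +40 at t=1, linear to -85 at t=251.
        90% repolarization level = 40 - 0.9*125 = -72.5, crossed at
        t = 1 + 250*(40-(-72.5))/125 = 226; upstroke at t=1."""
        t = np.arange(0.0, 400.0, 0.1)
        v = np.full_like(t, -85.0)
        rise = (t >= 0.5) & (t <= 1.0)
        v[rise] = -85.0 + (t[rise] - 0.5) / 0.5 * 125.0
        fall = (t > 1.0) & (t <= 251.0)
        v[fall] = 40.0 - (t[fall] - 1.0) / 250.0 * 125.0
        apd, t_up, _ = compute_apd90(t, v, stim_time=0.0)
        assert apd == pytest.approx(225.0, abs=0.5)

    def test_sampling_interval_halving_invariance(self):
        """APD90 changes by < 0.5 ms when the sampling interval halves."""
        def trace(dt):
            t = np.arange(0.0, 600.0, dt)
            v = -85.0 + 125.0 * np.exp(-((t - 5) / 150.0) ** 2) * (t > 1)
            v[t <= 1] = -85.0 + t[t <= 1] * 10
            return t, v
        apds = []
        for dt in (0.2, 0.1):
            t, v = trace(dt)
            apd, _, _ = compute_apd90(t, v)
            apds.append(apd)
        assert abs(apds[0] - apds[1]) < 0.5

    def test_no_repolarization_returns_nan(self):
        t = np.arange(0.0, 1000.0, 0.1)
        v = np.where(t < 2, -85.0 + t * 60, 35.0 - 0.01 * t)  # stays high
        apd, _, _ = compute_apd90(t, v)
        assert np.isnan(apd)


def _ap_with_bump(bump_mv=0.0, bump_at=150.0):
    """Synthetic AP: fast upstroke, smooth repolarization, optional plateau
    bump of known prominence."""
    t = np.arange(0.0, 500.0, 0.1)
    v = np.full_like(t, -85.0)
    up = t <= 2.0
    v[up] = -85.0 + t[up] / 2.0 * 125.0
    rep = t > 2.0
    v[rep] = -85.0 + 125.0 * np.exp(-(t[rep] - 2.0) / 120.0)
    if bump_mv:
        v += bump_mv * np.exp(-((t - bump_at) / 10.0) ** 2)
    return t, v


class TestEadDetection:
    def test_monotone_repolarization_counts_zero(self):
        t, v = _ap_with_bump(0.0)
        beats = classify_beats(t, v, np.array([0.0]))
        assert beats[0].ead_count == 0
        assert beats[0].classification == "normal"

    def test_injected_10mv_bump_counts_one_ead(self):
        t, v = _ap_with_bump(10.0, bump_at=200.0)
        beats = classify_beats(t, v, np.array([0.0]))
        assert beats[0].ead_count == 1
        assert beats[0].classification == "EAD"

    def test_subthreshold_bump_ignored(self):
        t, v = _ap_with_bump(0.5, bump_at=200.0)
        beats = classify_beats(t, v, np.array([0.0]))
        assert beats[0].ead_count == 0

    def test_notch_dome_morphology_is_not_an_ead(self):
        """A (notch, dome) pair at high potentials is normal morphology."""
        t, v = _ap_with_bump(0.0)
        notch = (t > 5) & (t < 25)
        v[notch] -= 6.0 * np.sin((t[notch] - 5) / 20 * np.pi)  # dip at +V
        beats = classify_beats(t, v, np.array([0.0]))
        assert beats[0].ead_count == 0

    def test_oscillatory_beat_has_no_finite_apd(self):
        t = np.arange(0.0, 2000.0, 0.1)
        v = np.where(t < 2, -85.0 + t * 60, 0.0 + 5 * np.sin(t / 30.0))
        beats = classify_beats(t, v, np.array([0.0, 1000.0]))
        assert beats[0].classification == "oscillatory"
        assert np.isnan(beats[0].apd90_ms)

    def test_metrics_invariant_enforced(self):
        with pytest.raises(ValueError, match="oscillatory"):
            BeatMetrics(apd90_ms=200.0, upstroke_time_ms=1.0, ead_count=0,
                        classification="oscillatory")


class TestClampProtocol:
    def test_holding_below_step_enforced(self):
        with pytest.raises(ValueError, match="holding"):
            ClampProtocol(holding_mv=-6.7, step_mv=-96.7)
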