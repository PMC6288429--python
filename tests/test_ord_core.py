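"""Baseline model core: reduction to the published formulation, fixed-point
stability, gate boundedness, Ca conservation and solver convergence."""

import numpy as np
import pytest

from hfmicro import core, model
from hfmicro import ord_reference as ref
from hfmicro.core import MembraneState, StimulusProtocol, total_calcium


def test_reduction_derivatives_match_reference():
    """With remodeling off, the extended RHS equals the flat baseline
    transcription at machine precision, over a spread of states."""
    p = core.baseline_params()
    y = core.initial_state()
    # states visited along a paced beat probe very different regimes
    prot = StimulusProtocol(recorded_beats=1)
    t, states = model.run_beat(y, p, prot, sample_dt=1.0)
    for k in range(0, len(t), 100):
        s = states[k]
        dy_ext = core.rhs_ext(s, p)
        dy_ref = ref.rhs_baseline(s[:41], 0.0)
        np.testing.assert_allclose(dy_ext[:41], dy_ref, rtol=0, atol=1e-12)


def test_reduction_trace_matches_reference():
    """Voltage traces of the reduced model and the baseline agree within
    solver tolerance over two paced beats (identical sample grids)."""
    from scipy.integrate import odeint
    p = core.baseline_params()
    prot = StimulusProtocol()

    def f(y, t, ist):
        return ref.rhs_baseline(y, ist)

    y_ext = core.initial_state()
    y_ref = ref.INITIAL_STATE.copy()
    for beat in range(2):
        t, states = model.run_beat(y_ext, p, prot, t0=beat * 1000.0,
                                   sample_dt=1.0)
        y_ext = states[-1]
        # reference on the exact same segment grids
        i_split = int(np.argmin(np.abs(t - (beat * 1000.0 + 0.5))))
        s1 = odeint(f, y_ref, t[:i_split + 1], args=(-80.0,), rtol=1e-6,
                    atol=1e-8, mxstep=100000)
        s2 = odeint(f, s1[-1], t[i_split:], args=(0.0,), rtol=1e-6,
                    atol=1e-8, mxstep=100000)
        y_ref = s2[-1]
        v_ref = np.concatenate([s1[:-1, 0], s2[:, 0]])
        assert np.max(np.abs(states[:, 0] - v_ref)) < 0.1


def test_resting_fixed_point(rest_state):
    """All derivatives vanish at the relaxed rest state, and 10 s of
    unstimulated integration stays within 1 mV of rest."""
    p = core.baseline_params()
    dy = core.rhs_ext(rest_state, p)
    # voltage and concentrations move negligibly at rest
    assert abs(dy[0]) < 1e-4            # mV/ms
    _, states = model.run_free(rest_state, p, 10000.0)
    assert abs(states[-1][0] - rest_state[0]) < 1.0


@pytest.mark.parametrize("edge,expected_sign", [(0.0, 1.0), (1.0, -1.0)])
def test_gates_cannot_leave_unit_interval(rest_state, edge, expected_sign):
    """A gate pinned to 0 (1) has non-negative (non-positive) derivative, so
    trajectories cannot leave [0, 1]."""
    p = core.baseline_params()
    p[core.P_WD] = 0.3
    p[core.P_WA] = 0.7
    p[core.P_SL_ACTIVE] = 1.0
    for name in core.GATE_NAMES:
        y = rest_state.copy()
        y[core._IDX[name]] = edge
        dy = core.rhs_ext(y, p)
        assert expected_sign * dy[core._IDX[name]] >= -1e-12, name


def test_compute_rhs_rejects_nonfinite_state():
    y = core.initial_state()
    y[core._IDX["cai"]] = np.nan
    with pytest.raises(ValueError, match="cai"):
        core.compute_rhs(y, 0.0, 0.0, core.baseline_params())


def test_membrane_state_invariant_messages():
    ms = MembraneState()
    ms.m = 1.5
    with pytest.raises(ValueError, match="gate m"):
        ms.validate()
    ms = MembraneState()
    ms.ki = -1.0
    with pytest.raises(ValueError, match="concentration ki"):
        ms.validate()


def test_calcium_conservation_with_zeroed_sarcolemmal_fluxes(rest_state):
    """With every sarcolemmal Ca flux zeroed, total cell Ca (free +
    buffered, volume-weighted, all compartments) is constant over 10 s of
    pacing."""
    p = core.baseline_params()
    # a remodeled configuration exercises every compartment incl. casl
    p[core.P_WA] = 0.5
    p[core.P_WD] = 0.5
    p[core.P_FTT] = 0.6
    p[core.P_SL_ACTIVE] = 1.0
    p[core.P_ZERO_CA] = 1.0
    y = rest_state.copy()
    total0 = total_calcium(y, p)
    prot = StimulusProtocol()
    for _ in range(10):
        _, states = model.run_beat(y, p, prot)
        y = states[-1]
    total1 = total_calcium(y, p)
    assert abs(total1 - total0) / total0 < 1e-6


def test_apd90_converges_with_solver_tolerance(case_pacing):
    """Halving the solver tolerances changes a paced beat's APD90 by less
    than 0.5 ms."""
    from hfmicro.protocols import compute_apd90
    res = case_pacing(1, False, recorded_beats=3)
    y0 = res.trace.meta["params"], res.trace.meta["final_state"]
    p, y = y0[0], y0[1].copy()
    prot = StimulusProtocol(recorded_beats=1)
    apds = []
    for factor in (1.0, 0.5):
        old_rtol, old_atol = model.RTOL, model.ATOL
        model.RTOL, model.ATOL = old_rtol * factor, old_atol * factor
        try:
            t, states = model.run_beat(y.copy(), p, prot, sample_dt=0.1)
        finally:
            model.RTOL, model.ATOL = old_rtol, old_atol
        apd, _, _ = compute_apd90(t, states[:, 0])
        apds.append(apd)
    assert abs(apds[0] - apds[1]) < 0.5


def test_steady_state_criterion_is_stable(case_pacing):
    """Pacing 30 beats beyond the steady-state criterion moves APD90 by
    less than 1 ms."""
    from hfmicro.protocols import compute_apd90
    res = case_pacing(1, False, recorded_beats=3)
    p = res.trace.meta["params"]
    y = res.trace.meta["final_state"].copy()
    prot = StimulusProtocol(recorded_beats=1)
    t, states = model.run_beat(y.copy(), p, prot, sample_dt=0.1)
    apd_before, _, _ = compute_apd90(t, states[:, 0])
    for _ in range(30):
        _, states = model.run_beat(y, p, prot)
        y = states[-1]
    t, states = model.run_beat(y, p, prot, sample_dt=0.1)
    apd_after, _, _ = compute_apd90(t, states[:, 0])
    assert abs(apd_after - apd_before) < 1.0
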