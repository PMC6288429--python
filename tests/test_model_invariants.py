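"""Mechanistic invariants of the remodeled cell that have algebraic or
short-simulation checks: LTCC population linearity, monotonicity in
f_B2AR, sub-sarcolemmal compartment fluxes and component kinetics."""

import numpy as np
import pytest

from hfmicro import core, model
from hfmicro.core import OBS_IDX
from hfmicro.microdomain import RemodelingParams, SubgroupFractions
from hfmicro.phospho import PhosphoConfig


def _obs(y, p, name):
    return core.observables_ext(y, p)[OBS_IDX[name]]


def _depolarized_state(rest_state):
    """A mid-plateau-like state exercising both Ca pools."""
    y = rest_state.copy()
    y[0] = -6.7
    y[core._IDX["d"]] = 0.5
    y[core._IDX["dp"]] = 0.6
    y[core._IDX["cass"]] = 5e-4
    y[core._IDX["casl"]] = 3e-4
    return y


def test_ltcc_current_linear_in_subgroup_weights(rest_state):
    """At a fixed state, total LTCC current is linear in the subgroup
    weight vector (convex combinations map to convex combinations)."""
    y = _depolarized_state(rest_state)
    cfg = PhosphoConfig(stimulated=True)

    def current(weights):
        f = SubgroupFractions(*weights)
        p = model.build_params(RemodelingParams(0.5, 0.5, 0.5, True), cfg,
                               fractions=f)
        return _obs(y, p, "ICaL_total")

    w1 = (0.4, 0.1, 0.1, 0.2, 0.1, 0.1)
    w2 = (0.0, 0.3, 0.3, 0.0, 0.2, 0.2)
    for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
        mix = tuple(lam * a + (1 - lam) * b for a, b in zip(w1, w2))
        assert current(mix) == pytest.approx(
            lam * current(w1) + (1 - lam) * current(w2), rel=1e-9)


def test_peak_ical_nondecreasing_in_f_b2ar(rest_state):
    """More beta2AR-associated channels never decrease the instantaneous
    LTCC current magnitude under stimulation (fixed state)."""
    y = _depolarized_state(rest_state)
    cfg = PhosphoConfig(stimulated=True)
    mags = []
    for fb in np.linspace(0, 1, 11):
        p = model.build_params(RemodelingParams(1.0, fb, 1.0, True), cfg)
        mags.append(-_obs(y, p, "ICaL_total"))
    assert np.all(np.diff(mags) >= -1e-12)


def test_decreasing_f_pde_never_decreases_peak_ical(rest_state):
    """At f_TT = 1, f_B2AR = 1 under stimulation, removing PDE control can
    only increase the current (fixed state)."""
    y = _depolarized_state(rest_state)
    cfg = PhosphoConfig(stimulated=True)
    mags = []
    for fp in np.linspace(1, 0, 11):
        p = model.build_params(RemodelingParams(1.0, 1.0, fp, True), cfg)
        mags.append(-_obs(y, p, "ICaL_total"))
    assert np.all(np.diff(mags) >= -1e-12)


def test_subsarcolemmal_pure_diffusion_relaxation(rest_state):
    """With all surface fluxes zero, casl relaxes toward cai with the
    configured diffusion time constant (modulo buffering)."""
    p = model.build_params(RemodelingParams(0.5, 1.0, 1.0), PhosphoConfig())
    p[core.P_ZERO_CA] = 1.0          # no NCX/LTCC fluxes into the shell
    p[core.P_WD] = 0.0
    p[core.P_WA] = 1.0
    y = rest_state.copy()
    cai = y[core._IDX["cai"]]
    y[core._IDX["casl"]] = cai * 3.0
    dy = core.rhs_ext(y, p)
    casl = y[core._IDX["casl"]]
    # unbuffered flux balance: dcasl / B = -(casl - cai) / tau
    BSR = 0.047 * 0.00087 / (0.00087 + casl) ** 2
    BSL = 1.124 * 0.0087 / (0.0087 + casl) ** 2
    B = 1.0 / (1.0 + BSR + BSL)
    expected = -B * (casl - cai) / p[core.P_TAU_CASL]
    assert dy[core._IDX["casl"]] == pytest.approx(expected, rel=1e-9)


def test_surface_influx_accumulates_ca_in_the_shell(rest_state):
    """A depolarized state with surface LTCC current drives casl above
    cai (Ca accumulation near the channel mouth)."""
    p = model.build_params(RemodelingParams(0.0, 1.0, 1.0), PhosphoConfig())
    y = _depolarized_state(rest_state)
    y[core._IDX["casl"]] = y[core._IDX["cai"]]
    p2 = p.copy()
    p2[core.P_CLAMP] = 1.0
    _, states = model.run_free(y, p2, 20.0)
    assert states[-1][core._IDX["casl"]] > states[-1][core._IDX["cai"]]


def test_surface_component_outlives_ttubular_in_clamp(case_clamp):
    """Redistributed (surface) LTCC current decays more slowly than the
    dyadic (T-tubular) current: its late-window fraction is larger."""
    def late_fraction(trace, comp):
        I = trace[comp]
        peak = np.max(-I)
        late = np.mean(-I[-500:])     # last 50 ms of the step
        return late / peak

    for stim in (False, True):
        res1 = case_clamp(1, stim)    # T-tubular dominant
        res4 = case_clamp(4, stim)    # surface dominant
        assert late_fraction(res4.trace, "ICaL_sl") \
            > late_fraction(res1.trace, "ICaL_tt")


def test_orphaned_release_weaker_than_coupled(case_pacing):
    """Full de-tubulation weakens SR release: peak RyR flux in the
    de-tubulated cell is below the intact cell's, and the half-coupled
    cell lies between them."""
    from hfmicro.protocols import run_pacing_experiment
    peaks = {}
    for ft in (1.0, 0.5, 0.0):
        res = run_pacing_experiment(
            RemodelingParams(ft, 1.0, 1.0, False), PhosphoConfig(),
            recorded_beats=1, conditioning_beats=60, record=("v", "Jrel"))
        peaks[ft] = float(np.max(res.trace["Jrel"]))
    assert peaks[0.0] < peaks[1.0]
    assert peaks[0.0] <= peaks[0.5] <= peaks[1.0] * 1.05


def test_ncx_exactly_baseline_when_intact(rest_state):
    """At f_TT = 1 the NCX current equals the baseline formulation."""
    from hfmicro import ord_reference as ref
    p = core.baseline_params()
    y = _depolarized_state(rest_state)
    dy_ref = ref.rhs_baseline(y[:41], 0.0)
    dy_ext = core.rhs_ext(y, p)
    np.testing.assert_allclose(dy_ext[:41], dy_ref, atol=1e-12)
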