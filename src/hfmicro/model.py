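"""Model assembly and numerical integration.

Combines the remodeling state (:mod:`hfmicro.microdomain`), phosphorylation
settings (:mod:`hfmicro.phospho`) and cell geometry into the flat parameter
pack consumed by the jit-compiled right-hand side, and provides the
low-level time stepping used by the experimental protocols: stimulated
beats, free-running relaxation and voltage-clamp segments.

The integrator is LSODA (adaptive, stiffness-switching) with relative
tolerance 1e-6 and absolute tolerance 1e-8; every discontinuous event
(stimulus on/off, clamp step) starts a fresh solver segment so the adaptive
stepper never straddles a discontinuity.  Analysis traces are sampled at
0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from . import core
from .core import (
    CellGeometry, StimulusProtocol, N_OBS, OBS_IDX, OBS_NAMES,
    observables_ext, rhs_ext,
)
from .microdomain import (
    RemodelingParams, SubgroupFractions, SUBGROUP_INFO, SUBGROUPS,
    compute_subgroup_fractions,
)
from .phospho import PhosphoConfig, load_target_effects, pka_fraction

RTOL = 1e-6
ATOL = 1e-8
SAMPLE_DT = 0.1          # ms, analysis trace sampling
STEADY_STATE_RTOL = 1e-4  # per-beat relative state change at beat starts


class SimulationError(RuntimeError):
    """Solver failure; carries the last valid time in ``last_time_ms``."""

    def __init__(self, message: str, last_time_ms: float):
        super().__init__(f"{message} (last valid time {last_time_ms:.3f} ms)")
        self.last_time_ms = last_time_ms


def build_params(remodeling: RemodelingParams,
                 config: PhosphoConfig | None = None,
                 fractions: SubgroupFractions | None = None,
                 geometry: CellGeometry | None = None,
                 tau_casl_ms: float = 0.177,
                 a_rel_orphan: float = 4.0,
                 k_orphan_mM: float = 9.0e-4,
                 effects: dict | None = None) -> np.ndarray:
    """Assemble the flat parameter pack for the jitted right-hand side.

    ``fractions`` overrides the product-form subgroup weights (used by the
    case presets); all other arguments carry their config defaults.
    """
    config = config or PhosphoConfig(stimulated=remodeling.stimulated)
    if fractions is None:
        fractions = compute_subgroup_fractions(remodeling)
    geometry = geometry or CellGeometry()
    table = effects if effects is not None else load_target_effects()
    tgt = table["targets"]

    p = core.baseline_params()
    w = fractions.as_array()
    for k in range(6):
        p[core.P_WA + k] = w[k]
    for k, name in enumerate(SUBGROUPS):
        _, cls = SUBGROUP_INFO[name]
        p[core.P_PA + k] = pka_fraction(config, cls)
    p[core.P_CAMK_SL] = config.camk_fraction
    p[core.P_LTCC_AMP] = config.ltcc_amp_factor
    p[core.P_DSHIFT] = config.pka_activation_shift_mv
    p[core.P_TARGETS] = config.target_fraction
    p[core.P_IKS_MULT] = tgt["IKs"]["effects"]["conductance"]
    p[core.P_INA_MULT] = tgt["INa"]["effects"]["conductance"]
    p[core.P_INAK_KNAI_MULT] = tgt["INaK"]["effects"]["knai"]
    p[core.P_IKB_MULT] = tgt["IKur"]["effects"]["conductance"]
    p[core.P_RYR_MULT] = tgt["RyR"]["effects"]["release_gain"]
    p[core.P_PLB_KM_MULT] = tgt["PLB"]["effects"]["serca_km"]
    p[core.P_TNI_KM_MULT] = tgt["TnI"]["effects"]["trpn_km"]
    p[core.P_FTT] = remodeling.f_TT
    p[core.P_TAU_CASL] = tau_casl_ms
    p[core.P_VSL_FRAC] = geometry.v_sl_frac
    p[core.P_AREL_ORPH] = a_rel_orphan
    p[core.P_KORPH] = k_orphan_mM
    # the sub-sarcolemmal pool is distinguished from bulk myoplasm only
    # when something occupies the surface membrane
    p[core.P_SL_ACTIVE] = 1.0 if (fractions.surface > 0
                                  or remodeling.f_TT < 1.0) else 0.0
    return p


def _rhs_odeint(y, t, p):
    return rhs_ext(y, p)


def integrate_segment(y0: np.ndarray, p: np.ndarray,
                      t_grid: np.ndarray) -> np.ndarray:
    """Integrate one smooth segment, returning states at ``t_grid``."""
    out, info = odeint(_rhs_odeint, y0, t_grid, args=(p,), rtol=RTOL,
                       atol=ATOL, mxstep=500000, full_output=True,
                       tfirst=False)
    if info["message"] != "Integration successful.":
        last = t_grid[0] + float(info["tcur"][-1]) if len(info["tcur"]) \
            else t_grid[0]
        raise SimulationError(info["message"], last)
    if not np.all(np.isfinite(out[-1])):
        raise SimulationError("non-finite state", float(t_grid[-1]))
    return out


@dataclass
class TraceResult:
    """Uniformly sampled traces of recorded quantities.

    ``time_ms`` is global simulation time; ``data`` maps quantity name to a
    vector aligned with ``time_ms``.  ``stim_times_ms`` marks stimulus
    onsets inside the recorded window.
    """

    time_ms: np.ndarray
    data: dict
    stim_times_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    @property
    def quantities(self):
        return tuple(self.data)


def _observe(states: np.ndarray, p: np.ndarray) -> np.ndarray:
    obs = np.empty((states.shape[0], N_OBS))
    for k in range(states.shape[0]):
        obs[k] = observables_ext(states[k], p)
    return obs


def _trace_from_states(t, states, p, record):
    obs = _observe(states, p)
    data = {}
    for name in record:
        if name in OBS_IDX:
            data[name] = obs[:, OBS_IDX[name]]
        elif name in core._IDX:
            data[name] = states[:, core._IDX[name]]
        else:
            raise KeyError(f"unknown observable {name!r}; known: "
                           f"{OBS_NAMES + core.EXT_STATE_NAMES}")
    return data


DEFAULT_RECORD = ("v", "ICaL_total", "ICaL_tt", "ICaL_sl", "INaCa", "Jrel",
                  "cai")


def run_beat(y: np.ndarray, p: np.ndarray, protocol: StimulusProtocol,
             t0: float = 0.0, sample_dt: float | None = None):
    """One paced cycle; returns (t, states) sampled at ``sample_dt`` or, if
    None, only segment endpoints (cheap conditioning mode)."""
    dur, cl = protocol.duration_ms, protocol.cycle_length_ms
    p_on = p.copy()
    p_on[core.P_IST] = protocol.amplitude
    if sample_dt is None:
        grid1 = np.array([t0, t0 + dur])
        grid2 = np.array([t0 + dur, t0 + cl])
    else:
        grid1 = t0 + np.arange(0.0, dur + 0.5 * sample_dt, sample_dt)
        if len(grid1) < 2 or grid1[-1] < t0 + dur - 1e-9:
            grid1 = np.append(grid1, t0 + dur)
        grid2 = t0 + np.arange(dur, cl + 0.5 * sample_dt, sample_dt)
        if grid2[-1] < t0 + cl - 1e-9:
            grid2 = np.append(grid2, t0 + cl)
    s1 = integrate_segment(y, p_on, grid1)
    s2 = integrate_segment(s1[-1], p, grid2)
    t = np.concatenate([grid1[:-1], grid2])
    states = np.vstack([s1[:-1], s2])
    return t, states


def pace_to_steady_state(y: np.ndarray, p: np.ndarray,
                         protocol: StimulusProtocol):
    """Condition by pacing until the beat-start state stops changing.

    Relative change below :data:`STEADY_STATE_RTOL` (max over states, with
    the solver's absolute tolerance as floor), capped at
    ``protocol.conditioning_beats``.  Returns (state, beats_run, converged).
    """
    y = y.copy()
    for beat in range(protocol.conditioning_beats):
        _, states = run_beat(y, p, protocol)
        y_new = states[-1]
        delta = np.max(np.abs(y_new - y) / (np.abs(y) + 1e-4))
        y = y_new
        if delta < STEADY_STATE_RTOL:
            return y, beat + 1, True
    return y, protocol.conditioning_beats, False


def run_paced(remodeling: RemodelingParams,
              config: PhosphoConfig | None = None,
              fractions: SubgroupFractions | None = None,
              protocol: StimulusProtocol | None = None,
              record=DEFAULT_RECORD,
              initial: np.ndarray | None = None,
              sample_dt: float = SAMPLE_DT,
              **pack_kwargs) -> TraceResult:
    """Conditioning to steady state followed by recorded beats."""
    protocol = protocol or StimulusProtocol()
    p = build_params(remodeling, config, fractions, **pack_kwargs)
    y = core.initial_state() if initial is None else initial.copy()
    y, n_cond, converged = pace_to_steady_state(y, p, protocol)

    t_parts, s_parts, stim_times = [], [], []
    t0 = 0.0
    for _ in range(protocol.recorded_beats):
        stim_times.append(t0)
        t, states = run_beat(y, p, protocol, t0=t0, sample_dt=sample_dt)
        t_parts.append(t[:-1])
        s_parts.append(states[:-1])
        y = states[-1]
        t0 += protocol.cycle_length_ms
    t_parts.append(np.array([t0]))
    s_parts.append(y[None, :])
    t_all = np.concatenate(t_parts)
    states_all = np.vstack(s_parts)
    data = _trace_from_states(t_all, states_all, p, record)
    return TraceResult(
        time_ms=t_all, data=data, stim_times_ms=np.asarray(stim_times),
        meta={"conditioning_beats": n_cond, "converged": converged,
              "protocol": protocol, "params": p, "final_state": y},
    )


def relax_clamped(y: np.ndarray, p: np.ndarray, v_hold: float,
                  chunk_ms: float = 10000.0, max_ms: float = 1.0e6,
                  rtol: float = 1e-6) -> np.ndarray:
    """Hold the membrane at ``v_hold`` until the state stops changing."""
    pc = p.copy()
    pc[core.P_CLAMP] = 1.0
    y = y.copy()
    y[0] = v_hold
    t = 0.0
    while t < max_ms:
        states = integrate_segment(y, pc, np.array([0.0, chunk_ms]))
        y_new = states[-1]
        delta = np.max(np.abs(y_new - y) / (np.abs(y) + 1e-4))
        y = y_new
        t += chunk_ms
        if delta < rtol:
            break
    return y


def run_clamp(remodeling: RemodelingParams,
              config: PhosphoConfig | None = None,
              fractions: SubgroupFractions | None = None,
              v_hold: float = -96.7, v_step: float = -6.7,
              step_ms: float = 500.0, record=DEFAULT_RECORD,
              sample_dt: float = SAMPLE_DT,
              **pack_kwargs) -> TraceResult:
    """Voltage-clamp protocol: hold to steady state, step, record."""
    if not v_hold < v_step:
        raise ValueError("holding potential must be below step potential")
    p = build_params(remodeling, config, fractions, **pack_kwargs)
    y = relax_clamped(core.initial_state(), p, v_hold)
    pc = p.copy()
    pc[core.P_CLAMP] = 1.0
    y[0] = v_step
    grid = np.arange(0.0, step_ms + 0.5 * sample_dt, sample_dt)
    states = integrate_segment(y, pc, grid)
    data = _trace_from_states(grid, states, pc, record)
    return TraceResult(time_ms=grid, data=data,
                       meta={"v_hold": v_hold, "v_step": v_step,
                             "params": pc, "final_state": states[-1]})


def run_free(y: np.ndarray, p: np.ndarray, duration_ms: float,
             sample_dt: float | None = None):
    """Unstimulated integration (rest stability / conservation checks)."""
    if sample_dt is None:
        grid = np.array([0.0, duration_ms])
    else:
        grid = np.arange(0.0, duration_ms + 0.5 * sample_dt, sample_dt)
    states = integrate_segment(y, p, grid)
    return grid, states
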