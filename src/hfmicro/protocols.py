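"""Experimental protocols and trace metrics.

Implements the two protocols the model family is interrogated with, plus the
analysis that turns raw traces into summary numbers:

* **Voltage clamp** — hold at −96.7 mV to steady state, step to −6.7 mV and
  record the LTCC current; the decay of the T-tubular and surface-membrane
  components is summarized by mono-exponential time constants τ1 and τ2.
* **Pacing** — condition at a 1000-ms cycle length to steady state, record
  3 (APD analysis) or 15 (EAD analysis) beats; per-beat APD90, EAD count and
  a normal / EAD / oscillatory classification.
* **Parameter sweep** — the full (f_TT × f_PDE) grid at fixed f_B2AR levels,
  emitting a tidy table of mean APD90 and classification per grid point.

APD90 is measured from the time of maximal upstroke velocity to 90%
repolarization (diastolic reference taken just before the stimulus); EADs
are secondary depolarizations during repolarization, detected as a local
minimum followed by a local maximum with ≥1 mV prominence on a 1-ms-smoothed
trace, with take-off potentials restricted to the plateau window so the
normal notch–dome morphology is not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import core, model
from .core import StimulusProtocol
from .microdomain import RemodelingParams, case_definition
from .phospho import PhosphoConfig

#: EAD detection defaults
EAD_PROMINENCE_MV = 1.0
EAD_SMOOTH_MS = 1.0
EAD_TAKEOFF_MIN_MV = -70.0   # floor: below this a deflection is not an EAD
EAD_TAKEOFF_MAX_MV = 10.0    # dome/notch morphology sits above this
POLARIZED_DIASTOLE_MV = -70.0


@dataclass(frozen=True)
class ClampProtocol:
    """Voltage-clamp step protocol."""

    holding_mv: float = -96.7
    step_mv: float = -6.7
    step_ms: float = 500.0
    hold_rtol: float = 1e-6      # steady-state criterion at the hold

    def __post_init__(self):
        if not self.holding_mv < self.step_mv:
            raise ValueError("holding potential must be below step potential")
        if self.step_ms <= 0:
            raise ValueError("step duration must be positive")


@dataclass(frozen=True)
class DecayFit:
    """Mono-exponential decay summary ``A*exp(-t/tau) + C``."""

    tau_ms: float
    amplitude: float
    offset: float
    rms_residual: float
    flagged: bool = False        # non-monotone / ill-conditioned decay

    def __post_init__(self):
        if not self.tau_ms > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class BeatMetrics:
    """Per-beat summary."""

    apd90_ms: float              # NaN when the beat never repolarizes
    upstroke_time_ms: float
    ead_count: int
    classification: str          # normal | EAD | oscillatory

    def __post_init__(self):
        if self.classification not in ("normal", "EAD", "oscillatory"):
            raise ValueError(f"bad classification {self.classification!r}")
        if self.classification == "oscillatory" and np.isfinite(self.apd90_ms):
            raise ValueError("oscillatory beats carry no finite APD90")


def fit_exponential_decay(t: np.ndarray, current: np.ndarray,
                          window_fraction: float = 0.95) -> DecayFit:
    """Least-squares mono-exponential (plus offset) fit of a decaying inward
    current.

    The window runs from the point where the post-peak magnitude has fallen
    to ``window_fraction`` of the peak, to the end of the trace.  Decays
    slower than the window are extrapolated; a fit whose residual exceeds 5%
    of the amplitude, or whose windowed trace is non-monotone by more than
    the amplitude, is flagged rather than rejected.
    """
    t = np.asarray(t, float)
    current = np.asarray(current, float)
    mag = -current                          # inward currents are negative
    ipk = int(np.argmax(mag))
    target = window_fraction * mag[ipk]
    after = np.where(mag[ipk:] <= target)[0]
    i0 = ipk + (int(after[0]) if len(after) else 0)
    tt = t[i0:] - t[i0]
    y = current[i0:]
    if len(tt) < 4:
        raise ValueError("decay window too short to fit")

    def expo(x, a, tau, c):
        return a * np.exp(-x / tau) + c

    a0 = y[0] - y[-1]
    tau0 = max(tt[-1] / 5.0, 1.0)
    popt, _ = curve_fit(expo, tt, y, p0=[a0, tau0, y[-1]],
                        bounds=([-np.inf, 1e-3, -np.inf],
                                [np.inf, 1e7, np.inf]), maxfev=100000)
    resid = y - expo(tt, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    amp = abs(popt[0])
    monotone_violation = float(np.max(mag[i0:] - np.maximum.accumulate(
        mag[i0:][::-1])[::-1]))
    flagged = bool(amp > 0 and (rms > 0.05 * max(amp, 1e-12)
                                or monotone_violation > amp))
    return DecayFit(tau_ms=float(popt[1]), amplitude=float(popt[0]),
                    offset=float(popt[2]), rms_residual=rms, flagged=flagged)


def compute_apd90(t: np.ndarray, v: np.ndarray, stim_time: float = 0.0,
                  diastolic_mv: float | None = None):
    """APD90 of one beat.

    Returns ``(apd90, upstroke_time, v90_level)``; ``apd90`` is NaN when the
    trace never crosses 90% repolarization (feeds the oscillatory
    classification).  ``diastolic_mv`` overrides the diastolic reference
    (used when the preceding beat left the cell depolarized).
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    pre = t <= stim_time
    if diastolic_mv is None:
        diastolic_mv = float(v[pre][-1]) if np.any(pre) else float(v[0])
    dv = np.gradient(v, t)
    after = t >= stim_time
    iup = int(np.argmax(np.where(after, dv, -np.inf)))
    ipk = iup + int(np.argmax(v[iup:]))
    vpeak = float(v[ipk])
    v90 = vpeak - 0.9 * (vpeak - diastolic_mv)
    below = np.where(v[ipk:] < v90)[0]
    if len(below) == 0:
        return float("nan"), float(t[iup]), v90
    ic = ipk + int(below[0])
    # linear interpolation of the crossing
    if ic > 0 and v[ic - 1] != v[ic]:
        frac = (v[ic - 1] - v90) / (v[ic - 1] - v[ic])
        t90 = t[ic - 1] + frac * (t[ic] - t[ic - 1])
    else:
        t90 = t[ic]
    return float(t90 - t[iup]), float(t[iup]), v90


def _count_eads(t: np.ndarray, v: np.ndarray,
                prominence_mv: float = EAD_PROMINENCE_MV,
                smooth_ms: float = EAD_SMOOTH_MS) -> int:
    """Local-minimum-then-local-maximum pairs during repolarization."""
    if len(v) < 5:
        return 0
    dt = float(np.median(np.diff(t)))
    k = max(1, int(round(smooth_ms / dt)))
    sm = np.convolve(v, np.ones(k) / k, mode="same") if k > 1 else v
    eads = 0
    vmin = None
    for i in range(1, len(sm) - 1):
        if sm[i] < sm[i - 1] and sm[i] <= sm[i + 1]:
            vmin = sm[i]
        elif sm[i] > sm[i - 1] and sm[i] >= sm[i + 1] and vmin is not None:
            if (sm[i] - vmin > prominence_mv
                    and EAD_TAKEOFF_MIN_MV <= vmin <= EAD_TAKEOFF_MAX_MV):
                eads += 1
            vmin = None
    return eads


def classify_beats(t: np.ndarray, v: np.ndarray,
                   stim_times: np.ndarray) -> list[BeatMetrics]:
    """Per-beat APD90, EAD count and classification.

    A beat is *oscillatory* when the membrane never reaches 90%
    repolarization before the next stimulus.  The diastolic reference of a
    beat whose cell is still depolarized at the stimulus (e.g. following an
    oscillatory beat) is carried over from the last polarized diastole.
    """
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    stim_times = np.asarray(stim_times, float)
    out = []
    last_polarized = None
    for k, t_stim in enumerate(stim_times):
        t_end = stim_times[k + 1] if k + 1 < len(stim_times) else t[-1]
        mask = (t >= t_stim) & (t <= t_end)
        tb, vb = t[mask], v[mask]
        if len(tb) < 5:
            continue
        dia = float(vb[0])
        if dia > POLARIZED_DIASTOLE_MV and last_polarized is not None:
            dia = last_polarized
        elif dia <= POLARIZED_DIASTOLE_MV:
            last_polarized = dia
        apd, t_up, v90 = compute_apd90(tb, vb, stim_time=t_stim,
                                       diastolic_mv=dia)
        if np.isnan(apd):
            out.append(BeatMetrics(apd90_ms=float("nan"),
                                   upstroke_time_ms=t_up, ead_count=0,
                                   classification="oscillatory"))
            continue
        # EAD search window: from the AP peak to 90% repolarization
        iup = int(np.argmin(np.abs(tb - t_up)))
        ipk = iup + int(np.argmax(vb[iup:]))
        i90 = ipk + int(np.argmax(vb[ipk:] < v90))
        eads = _count_eads(tb[ipk:i90 + 1], vb[ipk:i90 + 1])
        out.append(BeatMetrics(
            apd90_ms=apd, upstroke_time_ms=t_up, ead_count=eads,
            classification="EAD" if eads > 0 else "normal"))
    return out


@dataclass
class ClampResult:
    trace: model.TraceResult
    fit_ttubular: DecayFit      # tau1
    fit_surface: DecayFit       # tau2

    @property
    def tau1_ms(self) -> float:
        return self.fit_ttubular.tau_ms

    @property
    def tau2_ms(self) -> float:
        return self.fit_surface.tau_ms


def run_voltage_clamp(remodeling: RemodelingParams,
                      config: PhosphoConfig | None = None,
                      fractions=None,
                      protocol: ClampProtocol | None = None,
                      **pack_kwargs) -> ClampResult:
    """Clamp protocol with per-component decay fits.

    τ1 summarizes the T-tubular LTCC component, τ2 the surface-membrane
    component; each is fitted separately (single exponential plus offset).
    """
    protocol = protocol or ClampProtocol()
    trace = model.run_clamp(
        remodeling, config, fractions, v_hold=protocol.holding_mv,
        v_step=protocol.step_mv, step_ms=protocol.step_ms,
        record=("ICaL_tt", "ICaL_sl", "ICaL_total", "cass", "casl", "cai"),
        **pack_kwargs)
    fits = []
    for comp in ("ICaL_tt", "ICaL_sl"):
        current = trace[comp]
        if np.max(np.abs(current)) < 1e-12:
            # component absent in this configuration: flagged placeholder
            fits.append(DecayFit(tau_ms=1.0, amplitude=0.0, offset=0.0,
                                 rms_residual=0.0, flagged=True))
        else:
            fits.append(fit_exponential_decay(trace.time_ms, current))
    return ClampResult(trace=trace, fit_ttubular=fits[0],
                       fit_surface=fits[1])


@dataclass
class PacingResult:
    trace: model.TraceResult
    beats: list

    @property
    def mean_apd90_ms(self) -> float:
        """Mean APD90 over recorded beats, oscillatory beats excluded."""
        apds = [b.apd90_ms for b in self.beats if np.isfinite(b.apd90_ms)]
        return float(np.mean(apds)) if apds else float("nan")

    @property
    def classification(self) -> str:
        """Cell-level class: oscillatory > EAD > normal precedence."""
        classes = [b.classification for b in self.beats]
        if "oscillatory" in classes:
            return "oscillatory"
        if "EAD" in classes:
            return "EAD"
        return "normal"

    @property
    def total_eads(self) -> int:
        return int(sum(b.ead_count for b in self.beats))


def run_pacing_experiment(remodeling: RemodelingParams,
                          config: PhosphoConfig | None = None,
                          fractions=None,
                          recorded_beats: int = 3,
                          conditioning_beats: int = 1000,
                          record=model.DEFAULT_RECORD,
                          **pack_kwargs) -> PacingResult:
    """Steady-state pacing followed by recorded beats with metrics."""
    protocol = StimulusProtocol(recorded_beats=recorded_beats,
                                conditioning_beats=conditioning_beats)
    rec = tuple(record) if "v" in record else ("v",) + tuple(record)
    trace = model.run_paced(remodeling, config, fractions, protocol=protocol,
                            record=rec, **pack_kwargs)
    beats = classify_beats(trace.time_ms, trace["v"], trace.stim_times_ms)
    return PacingResult(trace=trace, beats=beats)


def run_case_experiment(case_id: int, stimulated: bool,
                        recorded_beats: int = 3,
                        **kwargs) -> PacingResult:
    """Pacing experiment for one of the six canonical cases."""
    case = case_definition(case_id, stimulated=stimulated)
    return run_pacing_experiment(case.params,
                                 PhosphoConfig(stimulated=stimulated),
                                 fractions=case.fractions,
                                 recorded_beats=recorded_beats, **kwargs)


# ------------------------------------------------------------------
# parameter sweep
# ------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tidy sweep table: one row per (f_B2AR, f_TT, f_PDE) grid point."""

    table: pd.DataFrame
    stimulated: bool

    def heatmap(self, f_b2ar: float) -> pd.DataFrame:
        """Mean-APD90 pivot (rows f_TT, columns f_PDE) at one f_B2AR."""
        sub = self.table[np.isclose(self.table["f_B2AR"], f_b2ar)]
        return sub.pivot(index="f_TT", columns="f_PDE",
                         values="mean_apd90_ms")


def sweep_heatmap(f_b2ar_levels=(0.0, 0.25, 0.5, 0.75, 1.0),
                  stimulated: bool = True,
                  f_tt_values=None, f_pde_values=None,
                  recorded_beats: int = 15,
                  conditioning_beats: int = 1000,
                  **pack_kwargs) -> SweepResult:
    """Deterministic (f_TT × f_PDE) sweep at fixed f_B2AR levels.

    Each grid point runs the steady-state 15-beat pacing protocol and
    contributes mean APD90 (oscillatory beats excluded), EAD count and
    classification.  Individual failures are recorded as classification
    ``"error"`` and the sweep continues.
    """
    if f_tt_values is None:
        f_tt_values = np.round(np.linspace(0.0, 1.0, 11), 10)
    if f_pde_values is None:
        f_pde_values = np.round(np.linspace(0.0, 1.0, 11), 10)
    rows = []
    for fb in f_b2ar_levels:
        for ft in f_tt_values:
            for fp in f_pde_values:
                params = RemodelingParams(f_TT=float(ft), f_B2AR=float(fb),
                                          f_PDE=float(fp),
                                          stimulated=stimulated)
                try:
                    res = run_pacing_experiment(
                        params, PhosphoConfig(stimulated=stimulated),
                        recorded_beats=recorded_beats,
                        conditioning_beats=conditioning_beats,
                        record=("v",), **pack_kwargs)
                    rows.append(dict(
                        f_B2AR=float(fb), f_TT=float(ft), f_PDE=float(fp),
                        mean_apd90_ms=res.mean_apd90_ms,
                        n_eads=res.total_eads,
                        n_oscillatory_beats=sum(
                            b.classification == "oscillatory"
                            for b in res.beats),
                        classification=res.classification))
                except model.SimulationError as err:
                    rows.append(dict(
                        f_B2AR=float(fb), f_TT=float(ft), f_PDE=float(fp),
                        mean_apd90_ms=float("nan"), n_eads=0,
                        n_oscillatory_beats=0, classification="error",
                        error=str(err)))
    table = pd.DataFrame(rows)
    return SweepResult(table=table, stimulated=stimulated)
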