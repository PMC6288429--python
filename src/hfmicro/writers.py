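"""Output writers: tidy trace/metric/sweep tables with provenance headers.

Every file opens with ``#``-prefixed provenance lines carrying the package
version, solver tolerances and the full default-expanded configuration, so
a run can be reproduced from any of its outputs.  Outputs contain no
timestamps: identical configurations produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .model import ATOL, RTOL, TraceResult


def provenance_lines(config: RunConfig) -> list[str]:
    blob = json.dumps(config.to_mapping(), sort_keys=True)
    return [
        f"# hfmicro {__version__}",
        f"# solver: LSODA rtol={RTOL} atol={ATOL}",
        f"# config: {blob}",
    ]


def preflight(path: str | Path) -> Path:
    """Fail before any simulation if the output location is unwritable."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    probe = path.parent / (path.name + ".preflight")
    try:
        probe.write_text("")
    except OSError as err:
        raise OSError(f"output path not writable: {path}: {err}") from err
    finally:
        if probe.exists():
            probe.unlink()
    return path


def _write_frame(df: pd.DataFrame, path: Path, config: RunConfig) -> Path:
    header = "\n".join(provenance_lines(config))
    body = df.to_csv(index=False, float_format="%.10g", lineterminator="\n")
    path.write_text(header + "\n" + body)
    return path


def write_trace(trace: TraceResult, path: str | Path,
                config: RunConfig) -> Path:
    """Tidy long-format trace CSV: time_ms, quantity, value."""
    path = preflight(path)
    frames = []
    for name in trace.quantities:
        frames.append(pd.DataFrame({
            "time_ms": trace.time_ms, "quantity": name,
            "value": trace[name]}))
    df = pd.concat(frames, ignore_index=True)
    return _write_frame(df, path, config)


def write_beat_metrics(beats, path: str | Path, config: RunConfig) -> Path:
    """Per-beat metrics CSV (header-only when no beats)."""
    path = preflight(path)
    rows = [dict(beat=k, apd90_ms=b.apd90_ms,
                 upstroke_time_ms=b.upstroke_time_ms,
                 ead_count=b.ead_count, classification=b.classification)
            for k, b in enumerate(beats)]
    df = pd.DataFrame(rows, columns=["beat", "apd90_ms", "upstroke_time_ms",
                                     "ead_count", "classification"])
    return _write_frame(df, path, config)


def write_decay_fits(fits: dict, path: str | Path, config: RunConfig) -> Path:
    """Decay-fit table: component, tau_ms, amplitude, offset, residual."""
    path = preflight(path)
    rows = [dict(component=name, tau_ms=f.tau_ms, amplitude=f.amplitude,
                 offset=f.offset, rms_residual=f.rms_residual,
                 flagged=f.flagged) for name, f in fits.items()]
    df = pd.DataFrame(rows, columns=["component", "tau_ms", "amplitude",
                                     "offset", "rms_residual", "flagged"])
    return _write_frame(df, path, config)


def write_sweep(sweep, csv_path: str | Path, json_path: str | Path,
                config: RunConfig) -> tuple:
    """Sweep table as CSV (tidy rows) and JSON (records + provenance)."""
    csv_path = preflight(csv_path)
    json_path = preflight(json_path)
    cols = ["f_B2AR", "f_TT", "f_PDE", "mean_apd90_ms", "n_eads",
            "n_oscillatory_beats", "classification"]
    table = sweep.table.reindex(columns=cols + [c for c in sweep.table.columns
                                                if c not in cols])
    _write_frame(table, csv_path, config)
    payload = {
        "provenance": {"version": __version__,
                       "config": config.to_mapping()},
        "stimulated": bool(sweep.stimulated),
        "rows": json.loads(table.to_json(orient="records")),
    }
    Path(json_path).write_text(json.dumps(payload, sort_keys=True, indent=1))
    return csv_path, json_path
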