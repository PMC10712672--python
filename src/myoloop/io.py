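"""Plain-text I/O: EMG/drive traces (CSV), trial logs (CSV), manifests (JSON).

EMG traces are stored as two-column CSV (``time_s, emg_mV``) or one column
with the sampling rate in a JSON sidecar (``<name>.json`` holding
``{"fs": ...}``); drive signals likewise (``time_s, drive``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .controller import LoopRecord
from .emg import DriveSignal, EMGTrace, InvalidInputError
from .task import TrialResult

__all__ = [
    "read_emg_csv",
    "write_emg_csv",
    "write_drive_csv",
    "read_drive_csv",
    "trial_results_frame",
    "write_trial_log",
    "read_trial_log",
    "write_loop_trace",
    "write_manifest",
]


def write_emg_csv(trace: EMGTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.t, "emg_mV": trace.samples})
    df.to_csv(path, index=False)


def read_emg_csv(path: str | Path, fs: float | None = None) -> EMGTrace:
    """Read an EMG trace; infers fs from the time column, a sidecar, or the
    explicit argument (in that order of preference for 1-column files)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(float)
        samples = df.iloc[:, 1].to_numpy(float)
        if t.size < 2:
            raise InvalidInputError("need >= 2 samples to infer fs")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise InvalidInputError("time column is not uniformly sampled")
        return EMGTrace(samples, 1.0 / dt[0])
    samples = df.iloc[:, 0].to_numpy(float)
    if fs is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            fs = json.loads(sidecar.read_text()).get("fs")
    if fs is None:
        raise InvalidInputError(
            "single-column trace needs fs via argument or JSON sidecar"
        )
    return EMGTrace(samples, fs)


def write_drive_csv(drive: DriveSignal, path: str | Path) -> None:
    t = np.arange(drive.values.size) / drive.fs
    pd.DataFrame({"time_s": t, "drive": drive.values}).to_csv(path, index=False)


def read_drive_csv(path: str | Path) -> DriveSignal:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    return DriveSignal(df["drive"].to_numpy(float), fs)


def trial_results_frame(
    results: Sequence[TrialResult], condition: str | None = None
) -> pd.DataFrame:
    """Tabulate trial outcomes (one row per trial, force traces omitted)."""
    rows = [
        {
            "trial": i,
            "id_bits": r.id_bits,
            "outcome": r.outcome,
            "mt_s": r.mt,
            "ct_s": r.ct,
            "peak_force_N": r.peak_force,
        }
        for i, r in enumerate(results)
    ]
    df = pd.DataFrame(rows)
    if condition is not None:
        df.insert(0, "condition", condition)
    return df


def write_trial_log(results: Sequence[TrialResult], path: str | Path,
                    condition: str | None = None) -> None:
    trial_results_frame(results, condition).to_csv(path, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_loop_trace(records: Sequence[LoopRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def write_manifest(path: str | Path, **fields) -> None:
    """Write a reproducibility manifest (seeds, config, versions)."""
    import myoloop

    manifest = {"myoloop_version": myoloop.__version__, **fields}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
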