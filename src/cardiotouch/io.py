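"""File interchange: two-column signal files (text or HDF5) and TSV event
tables with schema validation."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import BeatSeries, EcgSignal
from .errors import DataError

__all__ = [
    "read_signal",
    "write_signal",
    "read_beats",
    "write_beats",
    "read_trials",
    "write_trials",
]

log = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant", "condition", "level", "onset_ms", "offset_ms",
                 "correct"]
BEAT_COLUMNS = ["r_time", "t_peak", "t_end", "qc_flag"]

#: Hard-fail threshold for malformed rows in event tables.
MAX_BAD_ROW_FRACTION = 0.01


def write_signal(path, signal: EcgSignal) -> None:
    """Write a signal as (time_ms, value) columns — plain text or HDF5 by
    file extension (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=signal.times)
            f.create_dataset("value", data=signal.samples)
            f.attrs["sampling_rate"] = signal.sampling_rate
    else:
        np.savetxt(path, np.column_stack([signal.times, signal.samples]),
                   fmt="%.6f", header="time_ms\tvalue", delimiter="\t")


def read_signal(path) -> EcgSignal:
    path = Path(path)
    if not path.exists():
        raise DataError(f"signal file not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            t = np.asarray(f["time_ms"])
            v = np.asarray(f["value"])
    else:
        arr = np.loadtxt(path, delimiter="\t")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise DataError(f"{path}: expected two columns (time_ms, value)")
        t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise DataError(f"{path}: time column must be uniformly sampled")
    return EcgSignal(v, sampling_rate=1000.0 / float(dt[0]), t0=float(t[0]))


def write_beats(path, beats: BeatSeries) -> None:
    beats.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_beats(path) -> BeatSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    return BeatSeries.from_frame(df)


def write_trials(path, trials: pd.DataFrame) -> None:
    cols = [c for c in TRIAL_COLUMNS + ["excluded", "reason"]
            if c in trials.columns]
    trials[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial event table.

    Rows with impossible values (negative onset, offset <= onset, level
    outside 0..7) are rejected and reported with their row numbers; the
    read hard-fails when more than 1% of rows are bad.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: schema error, missing column(s) {missing}")
    bad = (
        (df["onset_ms"] < 0)
        | (df["offset_ms"] <= df["onset_ms"])
        | ~df["level"].astype(float).isin(range(8))
    )
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based, after header
        log.warning("%s: rejected %d malformed row(s) at line(s) %s",
                    path, int(bad.sum()), rows[:20])
        if bad.mean() > MAX_BAD_ROW_FRACTION:
            raise DataError(
                f"{path}: {bad.sum()} of {len(df)} rows malformed "
                f"(> {MAX_BAD_ROW_FRACTION:.0%}); first bad lines: {rows[:20]}")
        df = df[~bad].reset_index(drop=True)
    if "excluded" not in df.columns:
        df["excluded"] = False
        df["reason"] = ""
    df["reason"] = df["reason"].fillna("").astype(str)
    return df
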