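"""Cardiac-phase assignment: continuous angles, systole/diastole windows,
and interbeat intervals around touch onset.

Conventions
-----------
* Cycles are half-open ``[R_i, R_{i+1})``; the angle of an event at time t
  in cycle i is ``360 * (t - R_i) / (R_{i+1} - R_i)``, so 0 degrees is the
  R-peak opening the cycle.
* The systole window is ``[R, T_end)``; the diastole window is the
  equal-length interval ``[R_next - (T_end - R), R_next)`` at the end of
  the cycle, equating event probability between the two windows.  The gap
  between them is 'unassigned'.
* In the IBI decomposition, diastole means the full remainder of the cycle
  after electrical systole (not the equal-length window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import circular_mean
from .ecg import BeatSeries
from .errors import ConfigError, DataError

__all__ = [
    "PhaseAssignment",
    "IbiContext",
    "phase_of_event",
    "mean_hold_phase",
    "build_phase_windows",
    "classify_event",
    "ibi_context",
    "phase_table",
    "ibi_context_table",
]

log = logging.getLogger(__name__)

#: Sampling grid (ms) for circular averaging over a stationary hold.
HOLD_GRID_MS = 1.0

IBI_POSITIONS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class PhaseAssignment:
    """An event's position in its cardiac cycle."""

    event_time: float
    cycle_index: int
    angle: float           # degrees in [0, 360)
    window: str            # systole | diastole | unassigned


@dataclass(frozen=True)
class IbiContext:
    """IBIs and systole/diastole sub-lengths at beat positions -2..+2
    relative to the cycle containing touch onset."""

    positions: tuple
    ibi: tuple             # ms per position
    systole: tuple         # electrical systole length per position
    diastole: tuple        # ibi - systole per position


def _cycle_index(t: float, beats: BeatSeries) -> int:
    r = beats.r_times
    if not (r[0] <= t < r[-1]):
        raise DataError(f"event at {t} ms outside beat coverage "
                        f"[{r[0]}, {r[-1]})")
    return int(np.searchsorted(r, t, side="right") - 1)


def phase_of_event(t: float, beats: BeatSeries) -> PhaseAssignment:
    """Continuous cardiac-cycle angle of an event (no window label)."""
    i = _cycle_index(t, beats)
    r, r_next = beats.r_times[i], beats.r_times[i + 1]
    angle = 360.0 * (t - r) / (r_next - r)
    return PhaseAssignment(event_time=float(t), cycle_index=i,
                           angle=float(angle), window="unassigned")


def _angles_on_grid(onset: float, offset: float, beats: BeatSeries,
                    step: float) -> np.ndarray:
    grid = np.arange(onset, offset + step / 2.0, step)
    r = beats.r_times
    idx = np.searchsorted(r, grid, side="right") - 1
    return 360.0 * (grid - r[idx]) / (r[idx + 1] - r[idx])


def mean_hold_phase(onset: float, offset: float, beats: BeatSeries,
                    step: float = HOLD_GRID_MS):
    """Circular mean angle of a stationary hold sampled on a 1 ms grid.

    Returns ``(mean_angle, resultant)``; the angle is NaN (flagged
    undefined) when the hold covers the cycle so uniformly that the
    resultant length is negligible.
    """
    if offset <= onset:
        raise ConfigError("mean_hold_phase: offset must exceed onset")
    _cycle_index(onset, beats)
    _cycle_index(offset, beats)  # both ends must be covered
    angles = _angles_on_grid(onset, offset, beats, step)
    mean, resultant = circular_mean(angles)
    if resultant < 1e-9:
        log.debug("hold [%s, %s]: resultant ~ 0, mean undefined", onset, offset)
        return float("nan"), resultant
    return mean, resultant


def build_phase_windows(r_time: float, t_end: float, next_r: float):
    """Equal-length systole and diastole windows for one beat.

    Returns ``((sys_lo, sys_hi), (dia_lo, dia_hi))`` with
    ``sys = [R, T_end)`` and ``dia = [next_R - (T_end - R), next_R)``.
    Raises :class:`DataError` when the windows would overlap.
    """
    syslen = t_end - r_time
    if syslen <= 0:
        raise DataError("build_phase_windows: T-end must follow the R-peak")
    if t_end >= next_r - syslen:
        raise DataError("build_phase_windows: cycle too short for "
                        "non-overlapping equal windows")
    return (r_time, t_end), (next_r - syslen, next_r)


def classify_event(t: float, beats: BeatSeries) -> PhaseAssignment:
    """Angle plus systole/diastole/unassigned window label for an event."""
    pa = phase_of_event(t, beats)
    i = pa.cycle_index
    if not beats.qc_pass[i]:
        return pa  # window stays unassigned on QC-failed beats
    try:
        (sys_lo, sys_hi), (dia_lo, dia_hi) = build_phase_windows(
            beats.r_times[i], beats.t_ends[i], beats.r_times[i + 1])
    except DataError:
        return pa
    if sys_lo <= t < sys_hi:
        window = "systole"
    elif dia_lo <= t < dia_hi:
        window = "diastole"
    else:
        window = "unassigned"
    return PhaseAssignment(pa.event_time, i, pa.angle, window)


def ibi_context(onset: float, beats: BeatSeries) -> IbiContext:
    """IBIs at beat positions -2..+2 around the cycle containing ``onset``.

    Needs two full cycles before and after the onset cycle; raises
    :class:`DataError` near recording edges (the trial is then dropped from
    this analysis only).
    """
    i = _cycle_index(onset, beats)
    if i < 2 or i + 3 > len(beats) - 1:
        raise DataError("ibi_context: insufficient beats around onset")
    ibi, syst, dia = [], [], []
    for p in IBI_POSITIONS:
        j = i + p
        length = beats.r_times[j + 1] - beats.r_times[j]
        s = beats.t_ends[j] - beats.r_times[j]
        ibi.append(float(length))
        syst.append(float(s))
        dia.append(float(length - s))
    return IbiContext(positions=IBI_POSITIONS, ibi=tuple(ibi),
                      systole=tuple(syst), diastole=tuple(dia))


def phase_table(trials: pd.DataFrame, beats: BeatSeries) -> pd.DataFrame:
    """Tidy per-trial phase table for one participant's retained trials.

    Columns: trial index, event angles (onset/hold_mean/offset) and window
    labels (onset/offset).  Trials outside beat coverage get NaN angles and
    are logged.
    """
    rows = []
    for idx, row in trials[~trials["excluded"]].iterrows():
        rec = {"trial": idx, "participant": row["participant"],
               "condition": row["condition"], "level": row["level"],
               "correct": row["correct"],
               "hold_ms": row["offset_ms"] - row["onset_ms"]}
        try:
            on = classify_event(row["onset_ms"], beats)
            off = classify_event(row["offset_ms"], beats)
            hold_angle, hold_res = mean_hold_phase(row["onset_ms"],
                                                   row["offset_ms"], beats)
            rec.update(onset_angle=on.angle, onset_window=on.window,
                       offset_angle=off.angle, offset_window=off.window,
                       hold_angle=hold_angle, hold_resultant=hold_res)
        except DataError as exc:
            log.debug("trial %s dropped from phase table: %s", idx, exc)
            rec.update(onset_angle=np.nan, onset_window="unassigned",
                       offset_angle=np.nan, offset_window="unassigned",
                       hold_angle=np.nan, hold_resultant=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)


def ibi_context_table(trials: pd.DataFrame, beats: BeatSeries) -> pd.DataFrame:
    """Long-format IBI context for one participant's retained trials:
    one row per trial x beat position."""
    rows = []
    for idx, row in trials[~trials["excluded"]].iterrows():
        try:
            ctx = ibi_context(row["onset_ms"], beats)
        except DataError as exc:
            log.debug("trial %s dropped from IBI analysis: %s", idx, exc)
            continue
        for p, ib, s, d in zip(ctx.positions, ctx.ibi, ctx.systole,
                               ctx.diastole):
            rows.append((row["participant"], row["condition"], idx, p, ib, s, d))
    return pd.DataFrame(rows, columns=["participant", "condition", "trial",
                                       "position", "ibi", "systole",
                                       "diastole"])
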