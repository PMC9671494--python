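"""Touch trials: pulse-channel parsing, exclusion rules, behavioural summaries.

The canonical trial table is a pandas DataFrame with columns::

    participant, condition, level, onset_ms, offset_ms, correct,
    excluded, reason

``level`` is 1..7 for the gratings condition and 0 for the flat control
stimulus (whose ``correct`` is NaN).  ``hold`` is always
``offset_ms - onset_ms``.

Exclusion reasons, applied in order (first match wins):
``multiple_contacts``, ``response_before_release``, ``too_short``,
``too_long``, ``outlier_sd``, ``bad_beat``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .ecg import BeatSeries, EcgSignal
from .errors import ConfigError, DataError

__all__ = [
    "EXCLUSION_REASONS",
    "parse_pulse_channel",
    "apply_exclusions",
    "include_participant",
    "behaviour_summary",
]

log = logging.getLogger(__name__)

EXCLUSION_REASONS = ("multiple_contacts", "response_before_release",
                     "too_short", "too_long", "outlier_sd", "bad_beat")

#: Hold-duration bounds (ms) and outlier multiplier from the study design.
MIN_HOLD_MS, MAX_HOLD_MS, SD_MULTIPLIER = 100.0, 5000.0, 3.0

#: Gap (ms) under which separate pulse runs count as consecutive contacts.
MERGE_GAP_MS = 150.0


def parse_pulse_channel(pulse: EcgSignal, amplitude_map: dict,
                        tolerance: float | None = None,
                        merge_gap: float = MERGE_GAP_MS,
                        participant: int = 0,
                        condition: str | None = None) -> pd.DataFrame:
    """Segment a touch pulse channel into trials.

    A trial spans each maximal run where the pulse departs from zero; the
    stimulus level is decoded from the plateau amplitude (nearest level
    within ``tolerance``, default half the smallest spacing between mapped
    amplitudes).  Runs separated by less than ``merge_gap`` ms merge into a
    single multi-contact event flagged ``multiple_contacts``.
    """
    amps = np.asarray(list(amplitude_map.values()), dtype=float)
    levels = np.asarray(list(amplitude_map.keys()))
    if np.unique(amps).size != amps.size:
        raise ConfigError("amplitude_map: must be injective over levels")
    if tolerance is None:
        tolerance = (np.min(np.diff(np.sort(amps))) / 2.0
                     if amps.size > 1 else np.inf)

    x = pulse.samples
    on = np.abs(x) > 1e-9
    if not on.any():
        return _empty_trials()
    edges = np.flatnonzero(np.diff(on.astype(int)))
    starts = list(np.flatnonzero(on[1:] & ~on[:-1]) + 1)
    if on[0]:
        starts.insert(0, 0)
    ends = list(np.flatnonzero(on[:-1] & ~on[1:]) + 1)
    if on[-1]:
        ends.append(x.size)
    del edges

    ms_per_sample = 1000.0 / pulse.sampling_rate
    # merge runs closer than merge_gap; remember multi-contact events
    merged = []  # (start, end, n_contacts)
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * ms_per_sample < merge_gap:
            merged[-1] = (merged[-1][0], e, merged[-1][2] + 1)
        else:
            merged.append((s, e, 1))

    rows = []
    for s, e, n_contacts in merged:
        plateau = float(np.median(x[s:e]))
        dist = np.abs(amps - plateau)
        k = int(np.argmin(dist))
        if dist[k] <= tolerance:
            level = int(levels[k])
            reason = "multiple_contacts" if n_contacts > 1 else ""
        else:
            level = -1
            reason = "unknown_level"
        cond = condition or ("control" if level == 0 else "gratings")
        rows.append((participant, cond, level,
                     pulse.t0 + s * ms_per_sample, pulse.t0 + e * ms_per_sample,
                     np.nan, reason != "", reason))
    return pd.DataFrame(rows, columns=["participant", "condition", "level",
                                       "onset_ms", "offset_ms", "correct",
                                       "excluded", "reason"])


def _empty_trials() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant", "condition", "level",
                                 "onset_ms", "offset_ms", "correct",
                                 "excluded", "reason"])


def hold_durations(trials: pd.DataFrame) -> pd.Series:
    return trials["offset_ms"] - trials["onset_ms"]


def apply_exclusions(trials: pd.DataFrame, beats: BeatSeries | None = None,
                     response_times: pd.Series | None = None,
                     min_hold: float = MIN_HOLD_MS,
                     max_hold: float = MAX_HOLD_MS,
                     sd_multiplier: float = SD_MULTIPLIER,
                     pool_levels: bool = True) -> pd.DataFrame:
    """Flag excluded trials for one participant; returns a copy.

    Order: pre-existing flags (multiple contacts / unknown level), verbal
    response before touch release, hold-duration bounds, the +/- SD outlier
    rule (mean/SD over the participant's surviving trials, pooled across
    levels within condition by default), and overlap with QC-failed beats.
    """
    out = trials.copy()
    if "excluded" not in out.columns:
        out["excluded"] = False
        out["reason"] = ""
    out["reason"] = out["reason"].fillna("").astype(str)
    hold = hold_durations(out)

    free = ~out["excluded"]
    if response_times is not None:
        hit = free & response_times.notna() & (response_times < out["offset_ms"])
        out.loc[hit, ["excluded", "reason"]] = [True, "response_before_release"]
        free &= ~hit
    short = free & (hold < min_hold)
    out.loc[short, ["excluded", "reason"]] = [True, "too_short"]
    long_ = free & ~short & (hold > max_hold)
    out.loc[long_, ["excluded", "reason"]] = [True, "too_long"]
    free &= ~short & ~long_

    # SD rule on surviving trials, per condition (levels pooled by default)
    group_cols = ["condition"] if pool_levels else ["condition", "level"]
    for _, idx in out[free].groupby(group_cols, observed=True).groups.items():
        h = hold.loc[idx]
        if len(h) < 2:
            continue
        mean, sd = float(h.mean()), float(h.std(ddof=1))
        bad = idx[np.abs(h - mean) > sd_multiplier * sd]
        out.loc[bad, ["excluded", "reason"]] = [True, "outlier_sd"]
        free.loc[bad] = False

    if beats is not None and len(beats):
        failed = np.flatnonzero(~beats.qc_pass)
        if failed.size:
            r = beats.r_times
            for j in failed:
                cyc_lo = r[j]
                cyc_hi = r[j + 1] if j + 1 < len(beats) else np.inf
                hit = free & (out["onset_ms"] < cyc_hi) & (out["offset_ms"] >= cyc_lo)
                out.loc[hit, ["excluded", "reason"]] = [True, "bad_beat"]
                free &= ~hit
    return out


def include_participant(trials: pd.DataFrame, alpha: float = 0.05):
    """Above-chance inclusion test.

    Exact two-sided binomial test (null p = 0.5) per difficulty level on the
    participant's retained gratings trials; the participant is kept iff any
    level is significant with accuracy above 0.5.  Returns
    ``(keep, per_level)`` where ``per_level`` has columns
    level / n / k / accuracy / p.
    """
    g = trials[(trials["condition"] == "gratings") & ~trials["excluded"]]
    if g.empty or g["correct"].isna().all():
        raise DataError("include_participant: no gratings trials with responses")
    rows = []
    for level, sub in g.groupby("level"):
        scored = sub["correct"].dropna()
        n = int(len(scored))
        if n == 0:
            warnings.warn(f"level {level}: zero scored trials, skipped")
            continue
        k = int(scored.sum())
        p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        rows.append((int(level), n, k, k / n, float(p)))
    per_level = pd.DataFrame(rows, columns=["level", "n", "k", "accuracy", "p"])
    keep = bool(((per_level["p"] < alpha) & (per_level["accuracy"] > 0.5)).any())
    return keep, per_level


def behaviour_summary(trials: pd.DataFrame) -> dict:
    """Per-level behavioural descriptives for one participant.

    Returns a dict with a per-level DataFrame (n, accuracy, median/mean
    hold), the pooled hold SD over retained gratings trials (the
    between-subject variability covariate), and the retained-trial
    fraction.
    """
    hold = hold_durations(trials)
    kept = trials[~trials["excluded"]]
    kept_hold = hold.loc[kept.index]
    rows = []
    for (cond, level), sub in kept.groupby(["condition", "level"]):
        h = kept_hold.loc[sub.index]
        acc = sub["correct"].mean() if sub["correct"].notna().any() else np.nan
        rows.append((cond, int(level), len(sub), acc,
                     float(h.median()), float(h.mean())))
    per_level = pd.DataFrame(rows, columns=["condition", "level", "n",
                                            "accuracy", "median_hold",
                                            "mean_hold"])
    gratings = kept[kept["condition"] == "gratings"]
    gh = kept_hold.loc[gratings.index]
    hold_sd = float(gh.std(ddof=1)) if len(gh) > 1 else 0.0
    return {
        "per_level": per_level,
        "hold_sd": hold_sd,
        "n_total": int(len(trials)),
        "n_retained": int(len(kept)),
        "retained_fraction": float(len(kept) / len(trials)) if len(trials) else np.nan,
    }
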