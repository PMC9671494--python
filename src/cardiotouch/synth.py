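"""Synthetic heartbeat trains, ECG-like waveforms, and touch-event streams.

Every generative knob that the downstream pipeline is supposed to estimate
(onset-phase coupling, a systole-initiation effect on hold duration,
difficulty-dependent accuracy, a touch-locked IBI deceleration carried by
diastole) is injectable and stored as ground truth alongside the events, so
tests never have to re-derive truth from the code under test.

Randomness: one root seed; per-participant child streams are spawned from
``numpy.random.SeedSequence(seed)`` in participant order (gratings stream
first, control stream second for each participant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import BeatSeries, EcgSignal
from .errors import ConfigError, DataError

__all__ = [
    "SynthConfig",
    "SynthParticipant",
    "SynthDataset",
    "generate_beat_train",
    "generate_touch_stream",
    "render_ecg",
    "render_pulse",
    "generate_dataset",
]

#: Hold-duration bounds (ms) used for clipping and validation.
HOLD_MIN, HOLD_MAX = 100.0, 5000.0

#: Default pulse amplitude per level (level 0 = flat control stimulus).
DEFAULT_AMPLITUDE_MAP = {0: 0.5, 1: 1.0, 2: 1.5, 3: 2.0, 4: 2.5,
                         5: 3.0, 6: 3.5, 7: 4.0}

# ECG template geometry (ms / mV); the T-wave is a rise/descent triangle
# whose descent hits baseline exactly at the beat's T-end.
_T_RISE_MS = 120.0
_T_DESCENT_MS = 80.0
_T_AMP = 0.35
_R_SIGMA_MS = 7.0
_P_AMP, _P_SIGMA_MS, _P_LEAD_MS = 0.12, 20.0, 160.0
_QS_AMP, _QS_SIGMA_MS, _QS_LEAD_MS = -0.10, 4.0, 22.0


@dataclass(frozen=True)
class SynthConfig:
    """All generative parameters; defaults emulate the study's descriptives."""

    n_participants: int = 46
    trials_per_condition: int = 150
    mean_ibi: float = 793.0          # ms
    ibi_sd: float = 110.0            # ms
    systole_len: float = 342.0       # ms
    systole_jitter_sd: float = 0.0   # ms, jitter on T-end placement
    bazett_scaling: bool = False     # scale systole with sqrt(IBI)
    ar_coef: float = 0.0             # AR(1) coefficient on IBIs, off by default
    onset_phase_kappa: float = 0.0   # von Mises concentration (0 = uniform)
    onset_phase_mu: float = 0.0      # degrees
    hold_base: tuple = (900.0, 950.0, 1000.0, 1050.0, 1200.0, 1300.0, 1400.0,
                        700.0)       # ms per level 1..7 + control
    hold_sd: float = 300.0           # ms, noise truncated at +/- 2.5 SD
    hold_systole_delta: float = 0.0  # ms added to systole-initiated holds
    accuracy_by_level: tuple = (0.97, 0.95, 0.93, 0.91, 0.85, 0.72, 0.62)
    ibi_deceleration: float = 0.0    # ms added to the onset beat's diastole
    trial_gap: tuple = (2500.0, 3500.0)  # ms, uniform inter-trial gap
    include_control: bool = True
    seed: int = 0

    def validate(self) -> "SynthConfig":
        if self.n_participants < 1:
            raise ConfigError("n_participants: must be >= 1")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition: must be >= 1")
        if not self.mean_ibi > self.systole_len > 0:
            raise ConfigError("mean_ibi/systole_len: need mean_ibi > systole_len > 0")
        if self.ibi_sd < 0:
            raise ConfigError("ibi_sd: must be >= 0")
        if self.onset_phase_kappa < 0:
            raise ConfigError("onset_phase_kappa: must be >= 0")
        if len(self.hold_base) != 8:
            raise ConfigError("hold_base: need 7 difficulty levels + control")
        if any(not HOLD_MIN < h < HOLD_MAX for h in self.hold_base):
            raise ConfigError(
                f"hold_base: values must lie strictly inside ({HOLD_MIN}, {HOLD_MAX})")
        if len(self.accuracy_by_level) != 7:
            raise ConfigError("accuracy_by_level: need 7 probabilities")
        if any(not 0.0 <= a <= 1.0 for a in self.accuracy_by_level):
            raise ConfigError("accuracy_by_level: probabilities must lie in [0, 1]")
        if self.hold_sd < 0:
            raise ConfigError("hold_sd: must be >= 0")
        if not 0 < self.trial_gap[0] <= self.trial_gap[1]:
            raise ConfigError("trial_gap: need 0 < min <= max")
        if abs(self.ar_coef) >= 1:
            raise ConfigError("ar_coef: must lie in (-1, 1)")
        return self


@dataclass
class SynthParticipant:
    """One simulated participant: true beats plus trials with ground truth.

    The gratings and control conditions are separate recordings, each with
    its own beat train.
    """

    participant: int
    beats: BeatSeries
    trials: pd.DataFrame  # includes gt_window / gt_phase_deg ground truth
    control_beats: BeatSeries | None = None
    control_trials: pd.DataFrame | None = None

    def beats_for(self, condition: str) -> BeatSeries:
        return self.beats if condition == "gratings" else self.control_beats


@dataclass
class SynthDataset:
    config: SynthConfig
    participants: list = field(default_factory=list)

    def all_trials(self) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            frames.append(p.trials)
            if p.control_trials is not None:
                frames.append(p.control_trials)
        return pd.concat(frames, ignore_index=True)


def _systole_lengths(config: SynthConfig, ibis: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    s = np.full(ibis.size, config.systole_len)
    if config.bazett_scaling:
        s = s * np.sqrt(ibis / config.mean_ibi)
    if config.systole_jitter_sd > 0:
        s = s + rng.normal(0.0, config.systole_jitter_sd, s.size)
    return np.clip(s, 1.0, ibis - 1.0)


def generate_beat_train(config: SynthConfig, duration: float,
                        rng: np.random.Generator | None = None):
    """R-peak and T-end times (ms) for one recording of ``duration`` ms.

    Successive R-peak gaps are Normal(mean_ibi, ibi_sd) truncated at
    ``2 * systole_len``; the first R-peak is at 0.  T-end = R + systole
    length (fixed by default, optionally Bazett-scaled and/or jittered).
    """
    config.validate()
    if duration <= 2 * config.mean_ibi:
        raise ConfigError("duration: must exceed 2 * mean_ibi")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    # truncate symmetrically around the mean (still >= 2 x systole_len) so
    # the realised mean IBI stays unbiased
    lo = 2 * config.systole_len
    hi = 2 * config.mean_ibi - lo if config.mean_ibi > lo else np.inf
    r = [0.0]
    prev_gap = config.mean_ibi
    while True:
        if config.ibi_sd > 0:
            gap = lo - 1.0
            while not lo <= gap <= hi:
                gap = (config.mean_ibi
                       + config.ar_coef * (prev_gap - config.mean_ibi)
                       + rng.normal(0.0, config.ibi_sd))
        else:
            gap = config.mean_ibi
        if r[-1] + gap >= duration:
            break
        r.append(r[-1] + gap)
        prev_gap = gap
    r = np.asarray(r)
    ibis = np.append(np.diff(r), config.mean_ibi)
    t_ends = r + _systole_lengths(config, ibis, rng)
    return r, t_ends


def _beat_series(r: np.ndarray, t_ends: np.ndarray) -> BeatSeries:
    t_peaks = t_ends - _T_DESCENT_MS
    return BeatSeries(r, t_peaks, t_ends, np.ones(r.size, dtype=bool))


def generate_touch_stream(config: SynthConfig, r_times: np.ndarray,
                          t_ends: np.ndarray, rng: np.random.Generator,
                          participant: int = 0, condition: str = "gratings"):
    """Place touch trials on a beat train; returns (trials, r', t_ends').

    Onset phases are von Mises(mu, kappa) mapped into the cycle.  When
    ``ibi_deceleration`` is non-zero the onset beat's diastole is lengthened
    by shifting all later beats, so the returned (possibly adjusted) beat
    train must be used downstream.  Ground-truth columns:

    - ``gt_phase_deg``: realised onset phase in the final geometry;
    - ``gt_window``: systole | diastole | gap from the equal-length window
      construction on the final geometry.
    """
    config.validate()
    r = np.asarray(r_times, dtype=float).copy()
    te = np.asarray(t_ends, dtype=float).copy()
    if r.size == 0:
        raise DataError("generate_touch_stream: empty beat train")
    n_trials = config.trials_per_condition
    if condition == "gratings":
        levels = np.tile(np.arange(1, 8), n_trials // 7 + 1)[:n_trials]
        rng.shuffle(levels)
    elif condition == "control":
        levels = np.zeros(n_trials, dtype=int)
    else:
        raise ConfigError(f"condition: unknown condition {condition!r}")

    mu_rad = np.deg2rad(config.onset_phase_mu)
    rows = []
    pointer = r[2] if r.size > 2 else r[0]
    i = 2
    for level in levels:
        while i + 1 < r.size and r[i] < pointer:
            i += 1
        if i + 3 >= r.size:
            raise DataError(
                "generate_touch_stream: beat train too short for requested trials")
        if config.onset_phase_kappa > 0:
            phase = np.rad2deg(rng.vonmises(mu_rad, config.onset_phase_kappa)) % 360.0
        else:
            phase = rng.uniform(0.0, 360.0)
        ibi = r[i + 1] - r[i]
        onset = r[i] + phase / 360.0 * ibi
        in_systole = onset < te[i]
        if config.ibi_deceleration != 0.0:
            r[i + 1:] += config.ibi_deceleration
            te[i + 1:] += config.ibi_deceleration

        base = config.hold_base[7] if level == 0 else config.hold_base[level - 1]
        hold = base + (config.hold_systole_delta if in_systole else 0.0)
        if config.hold_sd > 0:
            noise = rng.normal(0.0, config.hold_sd)
            while abs(noise) > 2.5 * config.hold_sd:  # bounded: keeps clean data clean
                noise = rng.normal(0.0, config.hold_sd)
            hold += noise
        hold = float(np.clip(hold, HOLD_MIN, HOLD_MAX))

        if level == 0:
            correct = np.nan
        else:
            correct = float(rng.random() < config.accuracy_by_level[level - 1])

        ibi_final = r[i + 1] - r[i]
        gt_phase = 360.0 * (onset - r[i]) / ibi_final
        win_len = te[i] - r[i]
        if onset < te[i]:
            gt_window = "systole"
        elif onset >= r[i + 1] - win_len:
            gt_window = "diastole"
        else:
            gt_window = "gap"
        rows.append((participant, condition, int(level), onset, onset + hold,
                     correct, gt_phase, gt_window))
        pointer = onset + hold + rng.uniform(*config.trial_gap)

    trials = pd.DataFrame(rows, columns=[
        "participant", "condition", "level", "onset_ms", "offset_ms",
        "correct", "gt_phase_deg", "gt_window"])
    return trials, r, te


def _participant_duration(config: SynthConfig) -> float:
    worst_hold = max(config.hold_base) + abs(config.hold_systole_delta) \
        + 2.5 * config.hold_sd
    per_trial = min(worst_hold, HOLD_MAX) + config.trial_gap[1] + config.mean_ibi
    return 6 * config.mean_ibi + config.trials_per_condition * per_trial \
        + 6 * config.mean_ibi


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Simulate all participants (deterministic given ``config.seed``)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    duration = _participant_duration(config)
    out = SynthDataset(config=config)
    for pid, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        r, te = generate_beat_train(config, duration, rng)
        trials, r, te = generate_touch_stream(config, r, te, rng,
                                              participant=pid,
                                              condition="gratings")
        part = SynthParticipant(pid, _beat_series(r, te), trials)
        if config.include_control:
            r2, te2 = generate_beat_train(config, duration, rng)
            ctrials, r2, te2 = generate_touch_stream(config, r2, te2, rng,
                                                     participant=pid,
                                                     condition="control")
            part.control_beats = _beat_series(r2, te2)
            part.control_trials = ctrials
        out.participants.append(part)
    return out


def render_ecg(r_times, t_ends, sampling_rate: float = 1000.0,
               duration_ms: float | None = None, noise_sd: float = 0.0,
               rng: np.random.Generator | None = None) -> EcgSignal:
    """Template PQRST waveform whose true R-peaks/T-ends are the inputs.

    The T-wave is a triangle rising over 120 ms and descending linearly to
    baseline exactly at the beat's T-end, so the trapezium-area detector has
    an unambiguous ground truth.  Gaussian noise of ``noise_sd`` mV is added
    when requested.
    """
    if sampling_rate < 250:
        raise ConfigError("sampling_rate: must be >= 250 Hz")
    r = np.asarray(r_times, dtype=float)
    te = np.asarray(t_ends, dtype=float)
    if duration_ms is None:
        duration_ms = (r[-1] + 1200.0) if r.size else 1000.0
    n = int(round(duration_ms * sampling_rate / 1000.0))
    t = np.arange(n) * (1000.0 / sampling_rate)
    x = np.zeros(n)

    def add_gauss(center, amp, sigma):
        lo = np.searchsorted(t, center - 5 * sigma)
        hi = np.searchsorted(t, center + 5 * sigma)
        x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)

    for rk, tk in zip(r, te):
        add_gauss(rk - _P_LEAD_MS, _P_AMP, _P_SIGMA_MS)
        add_gauss(rk - _QS_LEAD_MS, _QS_AMP, _QS_SIGMA_MS)
        add_gauss(rk, 1.0, _R_SIGMA_MS)
        add_gauss(rk + _QS_LEAD_MS, _QS_AMP, _QS_SIGMA_MS)
        apex = tk - _T_DESCENT_MS
        rise = (t >= apex - _T_RISE_MS) & (t < apex)
        x[rise] += _T_AMP * (t[rise] - (apex - _T_RISE_MS)) / _T_RISE_MS
        fall = (t >= apex) & (t < tk)
        x[fall] += _T_AMP * (tk - t[fall]) / _T_DESCENT_MS
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        x = x + rng.normal(0.0, noise_sd, n)
    return EcgSignal(x, sampling_rate)


def render_pulse(trials: pd.DataFrame, sampling_rate: float = 1000.0,
                 duration_ms: float | None = None,
                 amplitude_map: dict | None = None) -> EcgSignal:
    """Touch pulse channel: amplitude encodes the stimulus level during
    each trial's [onset, offset) span, zero elsewhere."""
    amap = DEFAULT_AMPLITUDE_MAP if amplitude_map is None else amplitude_map
    if duration_ms is None:
        duration_ms = float(trials["offset_ms"].max()) + 1000.0
    n = int(round(duration_ms * sampling_rate / 1000.0))
    x = np.zeros(n)
    for row in trials.itertuples():
        lo = int(round(row.onset_ms * sampling_rate / 1000.0))
        hi = int(round(row.offset_ms * sampling_rate / 1000.0))
        x[lo:hi] = amap[int(row.level)]
    return EcgSignal(x, sampling_rate)
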