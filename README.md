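# cardiotouch

Analysis pipeline for cardiac-cycle coupling of freely timed active
touches: ECG event detection (R-peaks and trapezium-area T-wave ends),
per-beat systole/diastole window construction with equated event
probability, circular phase assignment of touch onset / stationary hold /
offset, the trial-exclusion cascade, and the phase-conditional behavioural
analyses (event proportions, hold duration by initiation phase, accuracy
by phase, the hold-variability covariate, and touch-locked interbeat
intervals decomposed into systole and diastole).

A first-class synthetic-data module generates heartbeat trains, template
PQRST waveforms and touch-event streams with injectable, ground-truth
coupling structure (von Mises onset-phase coupling, a systole-initiation
effect on hold duration, difficulty-dependent accuracy, and a touch-locked
IBI deceleration carried by diastole), so every downstream stage is
testable without any external data.

## Layout

| module                   | purpose                                                        |
|--------------------------|----------------------------------------------------------------|
| `cardiotouch.synth`      | synthetic beats, ECG rendering, touch streams (ground truth)   |
| `cardiotouch.ecg`        | band-pass filter, R-peak detection, trapezium-area T-end       |
| `cardiotouch.trials`     | pulse-channel parsing, exclusion rules, behaviour summaries    |
| `cardiotouch.phase`      | cycle angles, systole/diastole windows, IBI context            |
| `cardiotouch.circstats`  | circular mean, Rayleigh test, Holm-Bonferroni                  |
| `cardiotouch.analyses`   | per-participant aggregate tables and group contrasts           |
| `cardiotouch.pipeline`   | configuration, orchestration, provenance manifest              |
| `cardiotouch.io`         | two-column signal files (text/HDF5) and TSV event tables       |

## CLI

```sh
# full synthetic pipeline: simulate -> exclusions -> phases -> analyses
cardiotouch all --seed 7 --out out/

# individual stages
cardiotouch simulate --seed 7 --out sim/ [--signals]
cardiotouch detect  --signal sim/signals/p0_gratings_ecg.tsv --out beats.tsv
cardiotouch trials  --pulse pulse.tsv --beats beats.tsv --out trials.tsv
cardiotouch phases  --trials trials.tsv --beats beats.tsv --out phases.tsv
cardiotouch analyse --in sim/ --out out/
```

Defaults reproduce the study's stated settings (3-30 Hz band, 550 ms
minimum R-peak distance, 100/5000 ms hold bounds, +/-3 SD outlier rule,
1.5x R-T consistency factor, alpha = 0.05); every parameter can be
overridden through a YAML config (`--config`). Exit codes: 0 ok,
1 configuration error, 2 data error. Reruns with the same seed are
bit-identical; each results bundle carries a `manifest.json` with the
config hash, seed and per-reason exclusion counts.

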