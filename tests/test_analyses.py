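import numpy as np
import pandas as pd
import pytest

from cardiotouch import analyses
from cardiotouch.errors import DataError
from cardiotouch.pipeline import PipelineConfig, run_pipeline
from cardiotouch.synth import SynthConfig


def phases_frame(records):
    """records: (participant, onset_window, offset_window, hold, correct,
    onset_angle)."""
    rows = []
    for i, (pid, ow, fw, hold, correct, angle) in enumerate(records):
        rows.append({"trial": i, "participant": pid, "condition": "gratings",
                     "level": 3, "correct": correct, "hold_ms": hold,
                     "onset_angle": angle, "onset_window": ow,
                     "offset_angle": (angle + 90) % 360, "offset_window": fw,
                     "hold_angle": (angle + 45) % 360, "hold_resultant": 0.5})
    return pd.DataFrame(rows)


class TestPhaseProportions:
    def test_48_of_100(self):
        recs = [(0, "systole", "diastole", 1000.0, 1.0, 10.0)] * 48 + \
               [(0, "diastole", "diastole", 1000.0, 1.0, 200.0)] * 52
        out = analyses.phase_proportions(phases_frame(recs))
        assert out["prop_start_systole"].item() == pytest.approx(0.48)

    def test_all_systole(self):
        recs = [(0, "systole", "systole", 1000.0, 1.0, 10.0)] * 10
        out = analyses.phase_proportions(phases_frame(recs))
        assert out["prop_start_systole"].item() == 1.0
        assert out["prop_end_systole"].item() == 1.0

    def test_unassigned_renormalized(self):
        recs = [(0, "systole", "systole", 1000.0, 1.0, 10.0)] * 5 + \
               [(0, "diastole", "diastole", 1000.0, 1.0, 200.0)] * 5 + \
               [(0, "unassigned", "unassigned", 1000.0, 1.0, 120.0)] * 10
        out = analyses.phase_proportions(phases_frame(recs))
        assert out["prop_start_systole"].item() == pytest.approx(0.5)
        assert out["n_start"].item() == 10

    def test_small_cell_missing(self):
        recs = [(0, "systole", "systole", 1000.0, 1.0, 10.0)] * 3
        out = analyses.phase_proportions(phases_frame(recs), min_trials=5)
        assert np.isnan(out["prop_start_systole"].item())


class TestDurationByPhase:
    def test_single_participant_equal_holds(self):
        recs = [(0, "systole", "systole", 1000.0, 1.0, 10.0)] * 5 + \
               [(0, "diastole", "systole", 1000.0, 1.0, 200.0)] * 5
        table, contrasts = analyses.duration_by_initiation_phase(phases_frame(recs))
        assert table["diff_dia_minus_sys_median"].item() == 0.0
        assert contrasts == {}  # fewer than 3 participants

    def test_planted_difference_sign(self):
        recs = []
        for pid in range(6):
            recs += [(pid, "systole", "systole", 1100.0, 1.0, 10.0)] * 5
            recs += [(pid, "diastole", "systole", 1000.0, 1.0, 200.0)] * 5
        table, contrasts = analyses.duration_by_initiation_phase(phases_frame(recs))
        assert np.allclose(table["diff_dia_minus_sys_median"], -100.0)
        c = contrasts["gratings"]
        assert c.mean_diff == pytest.approx(-100.0)

    def test_missing_cell_dropped_from_contrast(self):
        recs = []
        for pid in range(4):
            recs += [(pid, "systole", "systole", 1000.0, 1.0, 10.0)] * 3
            if pid != 3:
                recs += [(pid, "diastole", "systole", 900.0, 1.0, 200.0)] * 3
        _, contrasts = analyses.duration_by_initiation_phase(phases_frame(recs))
        assert contrasts["gratings"].n == 3


class TestAccuracyByPhase:
    def test_all_correct(self):
        recs = [(0, "systole", "diastole", 1000.0, 1.0, 10.0)] * 6 + \
               [(0, "diastole", "systole", 1000.0, 1.0, 200.0)] * 6
        out = analyses.accuracy_by_phase(phases_frame(recs))
        assert (out["accuracy"] == 1.0).all()

    def test_planted_phase_gap_recovered(self):
        recs = [(0, "systole", "systole", 1000.0, 1.0, 10.0)] * 9 + \
               [(0, "systole", "systole", 1000.0, 0.0, 10.0)] * 1 + \
               [(0, "diastole", "diastole", 1000.0, 1.0, 200.0)] * 7 + \
               [(0, "diastole", "diastole", 1000.0, 0.0, 200.0)] * 3
        out = analyses.accuracy_by_phase(phases_frame(recs))
        onset = out[out["event_type"] == "onset"].set_index("window")
        gap = onset.loc["systole", "accuracy"] - onset.loc["diastole", "accuracy"]
        assert gap == pytest.approx(0.2)


class TestCovariate:
    def behaviour(self, acc, sd):
        return pd.DataFrame({"participant": range(len(acc)),
                             "accuracy": acc, "hold_sd": sd})

    def duration(self, n):
        return pd.DataFrame({"participant": range(n), "condition": "gratings"})

    def test_perfect_correlation(self):
        acc = [0.6, 0.7, 0.8, 0.9]
        sd = [100.0, 200.0, 300.0, 400.0]
        _, res = analyses.variability_covariate_analysis(
            self.duration(4), self.behaviour(acc, sd))
        assert res["r"] == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        _, res = analyses.variability_covariate_analysis(
            self.duration(4), self.behaviour([0.6, 0.7, 0.8, 0.9], [200.0] * 4))
        assert np.isnan(res["r"])

    def test_too_few_participants(self):
        with pytest.raises(DataError):
            analyses.variability_covariate_analysis(
                self.duration(2), self.behaviour([0.6, 0.7], [1.0, 2.0]))

    def test_matches_scipy_pearson(self, rng):
        from scipy import stats

        acc = rng.uniform(0.5, 1.0, 20)
        sd = 0.5 * acc + rng.normal(0, 0.1, 20)
        _, res = analyses.variability_covariate_analysis(
            self.duration(20), self.behaviour(acc, sd))
        ref = stats.pearsonr(acc, sd)
        assert res["r"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)


class TestIbiPositionAnalysis:
    def contexts(self, ibis_by_trial, systole=342.0):
        rows = []
        for trial, ibis in enumerate(ibis_by_trial):
            for pos, ibi in zip((-2, -1, 0, 1, 2), ibis):
                rows.append((0, "gratings", trial, pos, ibi, systole,
                             ibi - systole))
        return pd.DataFrame(rows, columns=["participant", "condition", "trial",
                                           "position", "ibi", "systole",
                                           "diastole"])

    def test_constant_ibi(self):
        per_part, group, _ = analyses.ibi_position_analysis(
            self.contexts([[800.0] * 5] * 4))
        assert np.allclose(per_part["ibi"], 800.0)
        assert np.allclose(group["ibi_mean"], 800.0)

    def test_elevation_in_diastole(self):
        ctx = self.contexts([[800.0, 800.0, 830.0, 800.0, 800.0]] * 4)
        per_part, group, _ = analyses.ibi_position_analysis(ctx)
        g = group.set_index("position")
        assert g.loc[0, "ibi_mean"] - g.loc[-1, "ibi_mean"] == pytest.approx(30.0)
        assert g.loc[0, "diastole_mean"] - g.loc[-1, "diastole_mean"] \
            == pytest.approx(30.0)
        assert g.loc[0, "systole_mean"] == g.loc[-1, "systole_mean"]


class TestGroupCircular:
    def test_concentrated_means(self):
        recs = [(pid, "systole", "systole", 1000.0, 1.0, 90.0)
                for pid in range(8)]
        out = analyses.group_circular_summary(phases_frame(recs))
        onset = out[out["event_type"] == "onset"].iloc[0]
        assert onset["mean_angle"] == pytest.approx(90.0)
        assert onset["resultant"] == pytest.approx(1.0)
        assert onset["p"] < 0.001

    def test_von_mises_recovery(self, rng):
        mu = 150.0
        rows = []
        for pid in range(40):
            angles = np.rad2deg(rng.vonmises(np.deg2rad(mu), 2.0, 30)) % 360
            for a in angles:
                rows.append((pid, "systole", "systole", 1000.0, 1.0, a))
        out = analyses.group_circular_summary(phases_frame(rows))
        onset = out[out["event_type"] == "onset"].iloc[0]
        assert abs((onset["mean_angle"] - mu + 180) % 360 - 180) < 10.0
        assert onset["p"] < 1e-6


@pytest.fixture(scope="module")
def result():
    cfg = PipelineConfig(synth=SynthConfig(
        n_participants=5, trials_per_condition=49, include_control=False),
        seed=99)
    return run_pipeline(cfg)


class TestOracleEquivalence:
    """Group statistics recomputed by naive single-pass loops over trials."""

    def test_prop_start_systole(self, result):
        for _, row in result.proportions.iterrows():
            sub = result.phases[(result.phases["participant"] == row["participant"])
                                & (result.phases["condition"] == row["condition"])]
            n_sys = n_dia = 0
            for _, t in sub.iterrows():
                if t["onset_window"] == "systole":
                    n_sys += 1
                elif t["onset_window"] == "diastole":
                    n_dia += 1
            assert row["prop_start_systole"] == pytest.approx(n_sys / (n_sys + n_dia))

    def test_median_hold_by_phase(self, result):
        for _, row in result.duration_table.iterrows():
            sub = result.phases[(result.phases["participant"] == row["participant"])
                                & (result.phases["onset_window"] == "systole")]
            holds = sorted(sub["hold_ms"])
            k = len(holds)
            naive = holds[k // 2] if k % 2 else (holds[k // 2 - 1] + holds[k // 2]) / 2
            assert row["median_systole"] == pytest.approx(naive)

    def test_group_circular_mean(self, result):
        from cardiotouch.circstats import circular_mean

        row = result.circular[(result.circular["event_type"] == "onset")].iloc[0]
        means = []
        for pid, sub in result.phases.groupby("participant"):
            angles = sub["onset_angle"].dropna().to_numpy()
            means.append(circular_mean(angles)[0])
        naive, _ = circular_mean(means)
        assert row["mean_angle"] == pytest.approx(naive)
        assert row["n"] == len(means)
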