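"""Group-level behavioural analyses.

Builds the per-participant aggregate tables (proportions of events per
cardiac window, hold durations by initiation phase, accuracy by phase,
the hold-variability covariate, IBIs by beat position, circular means per
event type) and runs the native group contrasts: Rayleigh tests on
participant means, the paired phase contrast with a normality check and
nonparametric fallback, and Pearson correlation for the covariate.
Heavier repeated-measures machinery (rmANOVA/rmANCOVA) is expected to be
run on the exported tables by standard statistical packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import CircularSummary, circular_mean, holm_bonferroni, rayleigh_test
from .errors import DataError

__all__ = [
    "phase_proportions",
    "duration_by_initiation_phase",
    "accuracy_by_phase",
    "variability_covariate_analysis",
    "ibi_position_analysis",
    "group_circular_summary",
    "PairedContrast",
]

log = logging.getLogger(__name__)

MIN_TRIALS_PER_CELL = 5


@dataclass(frozen=True)
class PairedContrast:
    """Result of a paired group contrast on per-participant summaries."""

    n: int
    mean_a: float
    mean_b: float
    mean_diff: float          # b - a
    ci_low: float
    ci_high: float
    shapiro_p: float
    test: str                 # 't' or 'wilcoxon'
    statistic: float
    p: float


def _paired_contrast(a: np.ndarray, b: np.ndarray,
                     alpha: float = 0.05) -> PairedContrast:
    """Paired contrast b vs a: Shapiro-Wilk on differences, then paired t
    or Wilcoxon signed-rank; t-based 95% CI on the mean difference."""
    diff = b - a
    n = diff.size
    if n < 3:
        raise DataError("paired contrast: need >= 3 complete pairs")
    if float(np.std(diff, ddof=1)) == 0.0:
        # constant differences: tests are degenerate
        m = float(diff.mean())
        return PairedContrast(n=int(n), mean_a=float(a.mean()),
                              mean_b=float(b.mean()), mean_diff=m,
                              ci_low=m, ci_high=m, shapiro_p=1.0,
                              test="degenerate",
                              statistic=0.0 if m == 0 else np.inf,
                              p=1.0 if m == 0 else 0.0)
    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p < alpha:
        res = stats.wilcoxon(b, a)
        test, statistic, p = "wilcoxon", float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_rel(b, a)
        test, statistic, p = "t", float(res.statistic), float(res.pvalue)
    sem = diff.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    m = float(diff.mean())
    return PairedContrast(n=int(n), mean_a=float(a.mean()), mean_b=float(b.mean()),
                          mean_diff=m, ci_low=m - tcrit * sem,
                          ci_high=m + tcrit * sem, shapiro_p=shapiro_p,
                          test=test, statistic=statistic, p=p)


def phase_proportions(phases: pd.DataFrame,
                      min_trials: int = MIN_TRIALS_PER_CELL) -> pd.DataFrame:
    """Proportion of touches starting / ending in systole, per participant
    and condition, over assigned events only (so systole + diastole = 1)."""
    rows = []
    for (pid, cond), sub in phases.groupby(["participant", "condition"]):
        row = {"participant": pid, "condition": cond}
        for event in ("onset", "offset"):
            win = sub[f"{event}_window"]
            n_sys = int((win == "systole").sum())
            n_dia = int((win == "diastole").sum())
            n = n_sys + n_dia
            key = "start" if event == "onset" else "end"
            if n < min_trials:
                log.info("participant %s %s %s: only %d assigned events",
                         pid, cond, event, n)
                row[f"prop_{key}_systole"] = np.nan
            else:
                row[f"prop_{key}_systole"] = n_sys / n
            row[f"n_{key}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def duration_by_initiation_phase(phases: pd.DataFrame, statistic: str = "median"):
    """Hold duration by the cardiac window containing touch onset.

    Returns ``(table, contrasts)``: a per-participant x condition table with
    systole/diastole hold medians and means plus the diastole - systole
    difference score, and a dict of paired group contrasts per condition
    (on the requested ``statistic``).
    """
    agg = (phases[phases["onset_window"].isin(["systole", "diastole"])]
           .groupby(["participant", "condition", "onset_window"])["hold_ms"]
           .agg(["median", "mean", "count"]).reset_index())
    wide = agg.pivot(index=["participant", "condition"],
                     columns="onset_window", values=["median", "mean", "count"])
    wide.columns = [f"{stat}_{win}" for stat, win in wide.columns]
    wide = wide.reset_index()
    for stat in ("median", "mean"):
        wide[f"diff_dia_minus_sys_{stat}"] = (
            wide.get(f"{stat}_diastole") - wide.get(f"{stat}_systole"))
    contrasts = {}
    for cond, sub in wide.groupby("condition"):
        sub = sub.dropna(subset=[f"{statistic}_systole", f"{statistic}_diastole"])
        dropped = wide[wide["condition"] == cond].shape[0] - sub.shape[0]
        if dropped:
            log.info("%s: %d participant(s) missing a phase cell, dropped",
                     cond, dropped)
        if len(sub) >= 3:
            contrasts[cond] = _paired_contrast(
                sub[f"{statistic}_systole"].to_numpy(float),
                sub[f"{statistic}_diastole"].to_numpy(float))
    return wide, contrasts


def accuracy_by_phase(phases: pd.DataFrame, per_level: bool = False) -> pd.DataFrame:
    """Proportion correct per cardiac window x event type (gratings only),
    one row per participant cell; input for delegated rmANOVA."""
    g = phases[(phases["condition"] == "gratings") & phases["correct"].notna()]
    group = ["participant", "level"] if per_level else ["participant"]
    rows = []
    for event in ("onset", "offset"):
        sub = g[g[f"{event}_window"].isin(["systole", "diastole"])]
        acc = (sub.groupby(group + [f"{event}_window"])["correct"]
               .agg(["mean", "count"]).reset_index()
               .rename(columns={f"{event}_window": "window",
                                "mean": "accuracy", "count": "n"}))
        acc.insert(0, "event_type", event)
        rows.append(acc)
    return pd.concat(rows, ignore_index=True)


def variability_covariate_analysis(duration_table: pd.DataFrame,
                                   behaviour: pd.DataFrame):
    """Join the hold-SD covariate to the duration table and correlate
    accuracy with hold variability across participants.

    ``behaviour`` needs one row per participant with columns
    ``participant``, ``accuracy``, ``hold_sd``.  Returns
    ``(joined_table, result_dict)``; the Pearson r is computed natively and
    its p-value from the exact t transform.
    """
    if len(behaviour) < 3:
        raise DataError("variability covariate: need >= 3 participants")
    joined = duration_table.merge(
        behaviour[["participant", "accuracy", "hold_sd"]], on="participant",
        how="left")
    x = behaviour["accuracy"].to_numpy(float)
    y = behaviour["hold_sd"].to_numpy(float)
    if np.std(y) == 0 or np.std(x) == 0:
        log.warning("zero-variance covariate or accuracy: correlation undefined")
        return joined, {"r": np.nan, "p": np.nan, "n": len(behaviour)}
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return joined, {"r": r, "p": p, "n": int(n)}


def ibi_position_analysis(contexts: pd.DataFrame, alpha: float = 0.05):
    """Mean IBI and systole/diastole sub-lengths per beat position.

    ``contexts`` is the long table from :func:`~cardiotouch.phase.ibi_context_table`.
    Returns ``(per_participant, group, posthoc)``: per-participant means per
    position, group means, and Holm-corrected paired t-tests of position 0
    against every other position, separately for the full IBI and the two
    sub-lengths.
    """
    per_part = (contexts.groupby(["participant", "condition", "position"])
                [["ibi", "systole", "diastole"]].mean().reset_index())
    group = (per_part.groupby(["condition", "position"])
             [["ibi", "systole", "diastole"]].agg(["mean", "std"]))
    group.columns = [f"{m}_{s}" for m, s in group.columns]
    group = group.reset_index()
    rows = []
    for cond, sub in per_part.groupby("condition"):
        wide = {m: sub.pivot(index="participant", columns="position", values=m)
                for m in ("ibi", "systole", "diastole")}
        for measure, tab in wide.items():
            tab = tab.dropna()
            pvals, entries = [], []
            for pos in [p for p in tab.columns if p != 0]:
                d = (tab[0] - tab[pos]).to_numpy(float)
                if d.size < 2 or float(np.std(d, ddof=1)) == 0.0:
                    # degenerate cell: no or constant differences
                    t, p = (0.0, 1.0) if d.size < 2 or d.mean() == 0 \
                        else (np.inf, 0.0)
                else:
                    res = stats.ttest_rel(tab[0], tab[pos])
                    t, p = float(res.statistic), float(res.pvalue)
                pvals.append(p)
                entries.append((cond, measure, pos,
                                float((tab[0] - tab[pos]).mean()), t, p))
            adj, rej = holm_bonferroni(pvals, alpha)
            for e, a, rj in zip(entries, adj, rej):
                rows.append(e + (float(a), bool(rj)))
    posthoc = pd.DataFrame(rows, columns=["condition", "measure", "position",
                                          "mean_diff_0_minus_pos", "t", "p",
                                          "p_holm", "reject"])
    return per_part, group, posthoc


def group_circular_summary(phases: pd.DataFrame, per_level: bool = False,
                           alpha: float = 0.05):
    """Second-level circular analysis: one circular mean per participant per
    cell, then a Rayleigh test across participant means.

    Returns a DataFrame with one row per condition x event type (x level),
    carrying the group circular mean, mean resultant length, Rayleigh z and
    p (Holm-corrected across the seven levels when ``per_level``).
    """
    angle_cols = {"onset": "onset_angle", "hold_mean": "hold_angle",
                  "offset": "offset_angle"}
    group_cols = ["condition"] + (["level"] if per_level else [])
    rows = []
    for key, sub in phases.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        for event, col in angle_cols.items():
            means = []
            for pid, psub in sub.groupby("participant"):
                angles = psub[col].dropna()
                if len(angles) == 0:
                    continue
                mean, _ = circular_mean(angles.to_numpy(float))
                if np.isfinite(mean):
                    means.append(mean)
            if len(means) < 2:
                log.info("cell %s/%s: <2 participant means, no test", key, event)
                continue
            summary = rayleigh_test(np.asarray(means))
            rows.append(dict(zip(group_cols, key), event_type=event,
                             n=summary.n, mean_angle=summary.mean_angle,
                             resultant=summary.resultant,
                             rayleigh_z=summary.rayleigh_z, p=summary.p))
    out = pd.DataFrame(rows)
    if per_level and not out.empty:
        out["p_holm"] = np.nan
        for (cond, event), idx in out.groupby(["condition", "event_type"]).groups.items():
            adj, _ = holm_bonferroni(out.loc[idx, "p"].to_numpy(), alpha)
            out.loc[idx, "p_holm"] = adj
    return out
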