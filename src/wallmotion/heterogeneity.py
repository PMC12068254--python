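"""Distributional heterogeneity diagnostics.

Patients on whom a plain classifier fails tend to show a small TW-vs-HR
contrast in their movement-feature distributions.  This module quantifies
that per patient: two-sample Kolmogorov–Smirnov statistics per kinematic
channel, dynamic-time-warping distance between the patient's mean TW and
mean HR speed series, and the 1-D Wasserstein distance between the pooled
TW and HR speed values — then compares failed against succeeded patients
(a second KS test on the per-patient KS statistics, and Levene's variance
equality test on the pooled speed values of the two groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError
from .io import HR, TW, UNLABELED
from .kinematics import CHANNEL_NAMES, build_feature_series


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample KS: sup |ECDF_a - ECDF_b| with the asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each sample needs at least 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def levene_test(groups) -> tuple[float, float]:
    """Classic (mean-centered) Levene W with its F-distribution p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise DataError("each group needs at least 2 values")
    res = sps.levene(*groups, center="mean")
    return float(res.statistic), float(res.pvalue)


def dtw_distance(s1, s2) -> float:
    """Classic dynamic-time-warping distance.

    Absolute-difference local cost, unit match/insert/delete steps, no
    window, no path normalization; returns the optimal cumulative cost.
    """
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    if s1.size == 0 or s2.size == 0:
        raise DataError("series must be non-empty")
    n, m = s1.size, s2.size
    cost = np.abs(s1[:, None] - s2[None, :])
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        for j in range(1, m + 1):
            row[j] = cost[i - 1, j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[n, m])


def wasserstein_1d(a, b) -> float:
    """First-order 1-D Wasserstein distance (area between the two ECDFs)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("samples must be non-empty")
    return float(sps.wasserstein_distance(a, b))


@dataclass
class HeterogeneityReport:
    per_patient: pd.DataFrame          # one row per patient with KS/DTW/W columns
    group_ks: dict                     # failed-vs-succeeded KS on the KS statistics
    group_levene: dict                 # failed-vs-succeeded Levene on speed values
    failed: list = field(default_factory=list)
    succeeded: list = field(default_factory=list)

    def to_boxplot_csv(self, path) -> None:
        """Long-format CSV (patient, group, channel, ks_statistic) for boxplots."""
        rows = []
        for _, row in self.per_patient.iterrows():
            group = "failed" if row["patient_id"] in self.failed else "succeeded"
            for ch in CHANNEL_NAMES:
                rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "group": group,
                        "channel": ch,
                        "ks_statistic": row[f"ks_{ch}"],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def patient_heterogeneity_report(
    trajectories,
    failed_patients=(),
    interpolation_factor: int = 1,
) -> HeterogeneityReport:
    """Per-patient TW-vs-HR distribution diagnostics.

    For each patient: the KS statistic per feature channel between the
    pooled per-timestep TW and HR values; the DTW distance between the mean
    TW speed series and the mean HR speed series; the Wasserstein distance
    between pooled TW and HR speed values.  Patients missing a labeled class
    are excluded with a warning.  If ``failed_patients`` is given, group
    comparisons (failed vs succeeded) are added: a KS test between the two
    groups' per-patient KS statistics (pooled over channels) and Levene's
    test on the groups' pooled speed values.
    """
    by_patient: dict = {}
    for tr in trajectories:
        if tr.label == UNLABELED:
            continue
        by_patient.setdefault(tr.patient_id, {TW: [], HR: []})[tr.label].append(
            build_feature_series(tr, interpolation_factor)
        )

    rows = []
    speed_values: dict = {}
    for pid, classes in sorted(by_patient.items()):
        if not classes[TW] or not classes[HR]:
            warnings.warn(f"patient {pid} lacks a labeled class; excluded", stacklevel=2)
            continue
        row = {"patient_id": pid}
        for ci, ch in enumerate(CHANNEL_NAMES):
            tw_vals = np.concatenate([s.values[ci] for s in classes[TW]])
            hr_vals = np.concatenate([s.values[ci] for s in classes[HR]])
            stat, p = ks_two_sample(tw_vals, hr_vals)
            row[f"ks_{ch}"] = stat
            row[f"ks_{ch}_p"] = p
            if ch == "speed":
                row["wasserstein_speed"] = wasserstein_1d(tw_vals, hr_vals)
                speed_values[pid] = np.concatenate([tw_vals, hr_vals])
        mean_tw_speed = np.mean([s.values[0] for s in classes[TW]], axis=0)
        mean_hr_speed = np.mean([s.values[0] for s in classes[HR]], axis=0)
        row["dtw_speed"] = dtw_distance(mean_tw_speed, mean_hr_speed)
        rows.append(row)
    per_patient = pd.DataFrame(rows)

    failed = [p for p in failed_patients if p in set(per_patient.get("patient_id", []))]
    succeeded = [p for p in per_patient.get("patient_id", []) if p not in failed]
    group_ks: dict = {}
    group_levene: dict = {}
    if failed and succeeded:
        ks_cols = [f"ks_{ch}" for ch in CHANNEL_NAMES]
        f_stats = per_patient[per_patient.patient_id.isin(failed)][ks_cols].to_numpy().ravel()
        s_stats = per_patient[per_patient.patient_id.isin(succeeded)][ks_cols].to_numpy().ravel()
        stat, p = ks_two_sample(f_stats, s_stats)
        group_ks = {"statistic": stat, "pvalue": p}
        stat, p = levene_test(
            [
                np.concatenate([speed_values[p_] for p_ in failed]),
                np.concatenate([speed_values[p_] for p_ in succeeded]),
            ]
        )
        group_levene = {"statistic": stat, "pvalue": p}
    return HeterogeneityReport(
        per_patient=per_patient,
        group_ks=group_ks,
        group_levene=group_levene,
        failed=list(failed),
        succeeded=list(succeeded),
    )
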