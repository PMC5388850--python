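"""Kaplan-Meier recurrence-free-survival curves and log-rank comparison.

Curves can be stratified by the recorded response group or by a
classifier's predictions, mirroring the comparison between outcome-based
and ultrasound-predicted survival separation.  Estimation uses all
follow-up; any truncation (e.g. five-year plots) is presentational.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

REQUIRED_COLUMNS = ("patient_id", "months", "event")


@dataclass
class KMCurve:
    """Product-limit estimate: S(0)=1, non-increasing steps at event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        past = self.event_times <= t
        return float(self.survival[past][-1]) if past.any() else 1.0


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"survival records missing column(s): {', '.join(missing)}")
    if len(records) == 0:
        raise ValueError("need at least one survival record")
    if (records["months"] < 0).any():
        raise ValueError("survival times must be non-negative")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event flags must be 0 or 1")
    return records


def km_curve(records: pd.DataFrame, label: str = "") -> KMCurve:
    """Kaplan-Meier estimator; censorings shrink the risk set without steps.

    Ties between events and censorings at the same time follow the
    standard convention (events first).
    """
    records = _validate(records)
    fitter = KaplanMeierFitter()
    fitter.fit(records["months"], event_observed=records["event"], label=label or None)
    table = fitter.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = np.array([float(fitter.survival_function_at_times(t).iloc[0]) for t in times])
    return KMCurve(
        event_times=times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        label=label,
    )


def log_rank(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Standard 1-df log-rank chi-square over the pooled event times."""
    a = _validate(group_a)
    b = _validate(group_b)
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        return float("nan"), float("nan")
    res = logrank_test(
        a["months"], b["months"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def stratify(
    records: pd.DataFrame, groups: pd.Series | str = "group"
) -> dict:
    """KM curves per group plus the pairwise log-rank test (two groups).

    ``groups`` is either the name of a column of ``records`` or a Series
    of group labels indexed by patient_id (e.g. classifier predictions).
    """
    records = _validate(records)
    if isinstance(groups, str):
        if groups not in records.columns:
            raise ValueError(f"records have no column {groups!r}")
        assignment = records[groups]
    else:
        assignment = groups.reindex(records["patient_id"])
        missing = assignment.isna()
        if missing.any():
            pid = records["patient_id"][missing.to_numpy()].iloc[0]
            raise ValueError(f"no group/prediction available for patient {pid!r}")
        assignment = pd.Series(assignment.to_numpy(), index=records.index)
    names = sorted(pd.unique(assignment))
    curves = {
        str(name): km_curve(records[assignment == name], label=str(name)) for name in names
    }
    out: dict = {"curves": curves}
    if len(names) == 2:
        stat, p = log_rank(records[assignment == names[0]], records[assignment == names[1]])
        out["log_rank_statistic"] = stat
        out["log_rank_p"] = p
    return out


def stratify_by_prediction(predictions: pd.Series, records: pd.DataFrame) -> dict:
    """Survival stratified by predicted (rather than observed) response."""
    return stratify(records, groups=predictions)
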