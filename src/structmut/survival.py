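"""Kaplan-Meier curves and the two-group log-rank test on overall survival."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank


@dataclass
class SurvivalCohort:
    """Per-patient time (months), event flag (1 death / 0 censored), group label."""

    table: pd.DataFrame  # columns: patient_id, time, event, group

    def __post_init__(self):
        required = {"patient_id", "time", "event", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if (self.table["time"] < 0).any():
            raise ValueError("negative survival time")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 or 1")

    def group(self, label: str) -> pd.DataFrame:
        sub = self.table[self.table["group"] == label]
        if sub.empty:
            raise ValueError(f"group {label!r} is empty")
        return sub

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SurvivalCohort":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class KaplanMeierCurve:
    time: np.ndarray  # event/censoring times (starts at 0)
    survival: np.ndarray  # product-limit estimate, non-increasing, starts at 1
    n_at_risk: np.ndarray


def kaplan_meier(cohort: SurvivalCohort, group: str) -> KaplanMeierCurve:
    """Product-limit survival estimate for one group."""
    sub = cohort.group(group)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    return KaplanMeierCurve(time=times, survival=surv, n_at_risk=at_risk)


def logrank_test(
    cohort: SurvivalCohort, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value."""
    a = cohort.group(group_a)
    b = cohort.group(group_b)
    if a["event"].sum() + b["event"].sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def label_altered(
    patient_ids: Iterable[str],
    altered_patients: Iterable[str],
    altered_label: str = "altered",
    wt_label: str = "WT",
) -> pd.Series:
    """Group labels from a caller-defined altered set.

    The altered set is typically patients carrying a nonsynonymous mutation
    or copy-number alteration in the gene of interest; deciding which calls
    qualify is the caller's responsibility.
    """
    altered = set(altered_patients)
    ids = list(patient_ids)
    return pd.Series(
        [altered_label if p in altered else wt_label for p in ids], index=ids
    )
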