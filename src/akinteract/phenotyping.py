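"""KDIGO-based cohort construction from serum-creatinine time series.

Eligibility screen: at least ``min_tests`` (default 3) consecutive
measurements spanning at most 14 days, with every inter-measurement gap at
most 7 days, and a < 50% change between the 1st and 2nd measurements of the
run.  The 2nd measurement of the earliest eligible run is the baseline.

Case definition (serum-creatinine KDIGO criteria, applied to every
post-baseline measurement): a rise of >= 0.3 mg/dL within 48 h of baseline
(``delta_048h``), or a value >= 1.5x baseline within 7 days (``ratio_7d``).
The earliest qualifying measurement date is the event (index) date; controls
take the 3rd measurement of the eligible run as their reference date.

Exclusions: age < 18, baseline creatinine strictly above 5.0 mg/dL, or any
configured pre-existing kidney-disease ICD-10 code dated strictly before
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import taxonomy

#: group labels
CASE, CONTROL = "case", "control"


@dataclass(frozen=True)
class EligibilityRule:
    min_tests: int = 3
    max_span_days: int = 14
    max_gap_days: int = 7
    max_baseline_change: float = 0.5

    def __post_init__(self):
        if min(self.min_tests, self.max_span_days, self.max_gap_days) <= 0:
            raise ValueError("eligibility thresholds must be positive")
        if not self.max_baseline_change > 0:
            raise ValueError("max_baseline_change must be positive")
        if self.min_tests < 3:
            raise ValueError("min_tests below 3 leaves no post-baseline reference")


@dataclass(frozen=True)
class ExclusionRule:
    min_age: int = 18
    max_baseline_scr: float = 5.0
    excluded_icd10_codes: tuple[str, ...] = taxonomy.DEFAULT_EXCLUDED_CODES

    def __post_init__(self):
        if self.min_age <= 0 or self.max_baseline_scr <= 0:
            raise ValueError("exclusion thresholds must be positive")


def find_eligible_window(
    dates, scr, rule: EligibilityRule = EligibilityRule()
) -> tuple[int, float] | None:
    """Earliest eligible ``min_tests``-measurement run in one series.

    Returns ``(baseline_date, baseline_scr)`` — the 2nd measurement of the
    run — or ``None`` if the series is ineligible.  ``dates`` must be
    sorted ascending.
    """
    d = np.asarray(dates)
    s = np.asarray(scr, dtype=float)
    k = rule.min_tests
    if len(d) < k:
        return None
    for i in range(len(d) - k + 1):
        win_d = d[i : i + k]
        if win_d[-1] - win_d[0] > rule.max_span_days:
            continue
        if np.any(np.diff(win_d) > rule.max_gap_days):
            continue
        if abs(s[i + 1] - s[i]) / s[i] >= rule.max_baseline_change:
            continue
        return int(win_d[1]), float(s[i + 1])
    return None


def classify_outcome(
    dates,
    scr,
    baseline_date: int,
    baseline_scr: float,
    *,
    delta_mg_dl: float = 0.3,
    delta_window_days: int = 2,
    ratio: float = 1.5,
    ratio_window_days: int = 7,
    reference_date: int | None = None,
) -> tuple[str, int, str] | None:
    """Apply the creatinine criteria to all post-baseline measurements.

    Returns ``(group, index_date, triggering_criterion)``; ``None`` when no
    post-baseline measurement exists (ineligible).  For controls the index
    date is ``reference_date`` when given (the 3rd measurement of the
    eligible run), else the first post-baseline measurement date.
    """
    d = np.asarray(dates)
    s = np.asarray(scr, dtype=float)
    post = d > baseline_date
    if not post.any():
        return None
    dd = d[post] - baseline_date
    vv = s[post]
    delta_hit = (dd <= delta_window_days) & (vv - baseline_scr >= delta_mg_dl)
    ratio_hit = (dd <= ratio_window_days) & (vv >= ratio * baseline_scr)
    hit = delta_hit | ratio_hit
    if hit.any():
        j = int(np.argmax(hit))
        crit = "delta_048h" if delta_hit[j] else "ratio_7d"
        return CASE, int(d[post][j]), crit
    if reference_date is None:
        reference_date = int(d[post][0])
    return CONTROL, int(reference_date), "none"


def apply_exclusions(
    cohort: pd.DataFrame,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    rule: ExclusionRule = ExclusionRule(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove under-age, high-baseline and pre-existing kidney-disease records.

    Sequential removal (age, then baseline creatinine, then diagnosis codes
    strictly before baseline); returns the filtered cohort and a per-rule
    removal ledger.
    """
    ledger: dict[str, int] = {}
    out = cohort.merge(patients[["patient_id", "age"]], on="patient_id", how="left")
    keep = out["age"] >= rule.min_age
    ledger["excluded_age"] = int((~keep).sum())
    out = out[keep]
    keep = out["baseline_scr"] <= rule.max_baseline_scr  # rule is strictly ">"
    ledger["excluded_baseline_scr"] = int((~keep).sum())
    out = out[keep]
    if len(diagnoses) and rule.excluded_icd10_codes:
        bad = diagnoses[diagnoses["icd10_code"].isin(rule.excluded_icd10_codes)]
        bad = bad.merge(out[["patient_id", "baseline_date"]], on="patient_id")
        bad_ids = set(bad.loc[bad["date"] < bad["baseline_date"], "patient_id"])
    else:
        bad_ids = set()
    keep = ~out["patient_id"].isin(bad_ids)
    ledger["excluded_kidney_history"] = int((~keep).sum())
    out = out[keep].drop(columns=["age"]).reset_index(drop=True)
    return out, ledger


class KdigoPhenotyper(BaseEstimator):
    """Vectorized cohort builder over the labs/patients/diagnoses tables.

    Parameters mirror :class:`EligibilityRule`, the two KDIGO criteria and
    :class:`ExclusionRule`; ``run`` returns the cohort table plus a flow
    ledger (sample-size accounting from input patients to final cohort).
    """

    def __init__(
        self,
        eligibility: EligibilityRule = EligibilityRule(),
        exclusion: ExclusionRule = ExclusionRule(),
        delta_mg_dl: float = 0.3,
        delta_window_days: int = 2,
        ratio: float = 1.5,
        ratio_window_days: int = 7,
    ):
        self.eligibility = eligibility
        self.exclusion = exclusion
        self.delta_mg_dl = delta_mg_dl
        self.delta_window_days = delta_window_days
        self.ratio = ratio
        self.ratio_window_days = ratio_window_days

    # -- internal vectorized stages -------------------------------------
    def _eligible_baselines(self, labs: pd.DataFrame) -> pd.DataFrame:
        rule = self.eligibility
        k = rule.min_tests
        labs = labs.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
        pid = labs["patient_id"]
        d = labs["date"]
        s = labs["scr"]
        ok = pid.shift(k - 1) == pid
        for j in range(1, k):
            ok &= (d.shift(k - 1 - j) - d.shift(k - j)) <= rule.max_gap_days
        ok &= (d - d.shift(k - 1)) <= rule.max_span_days
        ok &= (s.shift(k - 2) - s.shift(k - 1)).abs() / s.shift(k - 1) < rule.max_baseline_change
        runs = pd.DataFrame(
            {
                "patient_id": pid,
                "baseline_date": d.shift(k - 2),
                "baseline_scr": s.shift(k - 2),
                "reference_date": d.shift(k - 3) if k > 3 else d,
            }
        )[ok.fillna(False)]
        first = runs.groupby("patient_id", sort=True).head(1).copy()
        first["baseline_date"] = first["baseline_date"].astype(int)
        first["reference_date"] = first["reference_date"].astype(int)
        return first.reset_index(drop=True)

    def _classify(self, labs: pd.DataFrame, baselines: pd.DataFrame) -> pd.DataFrame:
        post = labs.merge(
            baselines[["patient_id", "baseline_date", "baseline_scr", "reference_date"]],
            on="patient_id",
        )
        post = post[post["date"] > post["baseline_date"]]
        dd = post["date"] - post["baseline_date"]
        delta_hit = (dd <= self.delta_window_days) & (
            post["scr"] - post["baseline_scr"] >= self.delta_mg_dl
        )
        ratio_hit = (dd <= self.ratio_window_days) & (
            post["scr"] >= self.ratio * post["baseline_scr"]
        )
        post = post.assign(delta_hit=delta_hit, hit=delta_hit | ratio_hit)
        hits = post[post["hit"]]
        first_hit = (
            hits.sort_values(["patient_id", "date"], kind="mergesort")
            .groupby("patient_id", sort=True)
            .head(1)
        )
        cohort = baselines.copy()
        cohort = cohort.merge(
            first_hit[["patient_id", "date", "delta_hit"]], on="patient_id", how="left"
        )
        is_case = cohort["date"].notna()
        cohort["group"] = np.where(is_case, CASE, CONTROL)
        cohort["index_date"] = np.where(is_case, cohort["date"], cohort["reference_date"]).astype(int)
        cohort["criterion"] = np.where(
            is_case, np.where(cohort["delta_hit"].eq(True), "delta_048h", "ratio_7d"), "none"
        )
        return cohort[
            ["patient_id", "group", "baseline_date", "baseline_scr", "index_date", "criterion"]
        ]

    def run(
        self,
        labs: pd.DataFrame,
        patients: pd.DataFrame,
        diagnoses: pd.DataFrame,
    ) -> tuple[pd.DataFrame, dict[str, int]]:
        """Build the cohort table; returns ``(cohort, flow_ledger)``."""
        n_input = patients["patient_id"].nunique()
        baselines = self._eligible_baselines(labs)
        cohort = self._classify(labs, baselines)
        ledger = {
            "input_patients": int(n_input),
            "eligible_series": int(len(cohort)),
            "ineligible": int(n_input - len(cohort)),
            "classified_cases": int((cohort["group"] == CASE).sum()),
            "classified_controls": int((cohort["group"] == CONTROL).sum()),
        }
        cohort, excl = apply_exclusions(cohort, patients, diagnoses, self.exclusion)
        ledger.update(excl)
        ledger["final_cases"] = int((cohort["group"] == CASE).sum())
        ledger["final_controls"] = int((cohort["group"] == CONTROL).sum())
        ledger["final_patients"] = int(len(cohort))
        cohort = cohort.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        return cohort, ledger


def brute_force_classify(
    dates,
    scr,
    baseline_date: int,
    baseline_scr: float,
    *,
    delta_mg_dl: float = 0.3,
    delta_window_days: int = 2,
    ratio: float = 1.5,
    ratio_window_days: int = 7,
) -> tuple[str, int | None]:
    """Independent O(n) scan over every post-baseline measurement.

    Reference oracle for :func:`classify_outcome`: returns the group label
    and, for cases, the earliest qualifying date; used in tests only.
    """
    best: int | None = None
    for day, value in zip(dates, scr):
        gap = day - baseline_date
        if gap <= 0:
            continue
        qualifies = (gap <= delta_window_days and value - baseline_scr >= delta_mg_dl) or (
            gap <= ratio_window_days and value >= ratio * baseline_scr
        )
        if qualifies and (best is None or day < best):
            best = day
    if best is None:
        return CONTROL, None
    return CASE, best
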