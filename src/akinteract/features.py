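"""Feature-matrix construction: exposure windows, product terms, covariates.

A drug class counts as "use" when it was newly started 1-7 days (the
default window) before the patient's index date; a start on the index date
itself is "non-use" to prevent reverse-causality bias, and a start 8 or
more days before the index date is "non-use" as well.  A product term for a
pair of classes is the elementwise AND of the two class indicators, i.e. 1
when both were newly started inside the same window before the same index
date.  Product columns that are zero for every case are dropped.

Covariates: age (years, untransformed), a male indicator, three hospital
one-hot columns, and seven pre-baseline medical-history indicators, so with
the full taxonomy the width is 32 + retained products + 5 + 7.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import taxonomy


@dataclass(frozen=True)
class ExposureWindow:
    lower_days: int = 1
    upper_days: int = 7

    def __post_init__(self):
        if not (1 <= self.lower_days <= self.upper_days):
            raise ValueError("window must satisfy 1 <= lower <= upper")

    @classmethod
    def parse(cls, text) -> "ExposureWindow":
        """Accept '1-7', (1, 7) or an ExposureWindow."""
        if isinstance(text, ExposureWindow):
            return text
        if isinstance(text, (tuple, list)):
            return cls(int(text[0]), int(text[1]))
        lo, hi = str(text).split("-")
        return cls(int(lo), int(hi))

    @property
    def label(self) -> str:
        return f"{self.lower_days}-{self.upper_days}"


PRODUCT_SEP = "*"


def encode_exposure(start_date, index_date, window: ExposureWindow = ExposureWindow()) -> int:
    """1 iff the start falls ``lower..upper`` days before the index date."""
    if start_date is None:
        return 0
    diff = index_date - start_date
    return int(window.lower_days <= diff <= window.upper_days)


def derive_drug_start(event_dates, index_date, washout_days: int = 180):
    """Earliest qualifying start among one patient's same-class events.

    Scans the date-sorted events on or before the index date and returns
    the first with no same-class event inside the preceding
    ``washout_days``; later events are treated as continuations of that
    course.  Under an unbounded lookback this is the patient's first
    recorded event of the class.  Returns ``None`` when no event precedes
    the index date.
    """
    prev = None
    for day in event_dates:
        if day > index_date:
            break
        if prev is None or day - prev > washout_days:
            return day
        prev = day
    return None


def enumerate_product_terms(drug_classes) -> list[tuple[str, str]]:
    """All unordered class pairs, lexicographic; C(n, 2) of them."""
    classes = list(drug_classes)
    if len(set(classes)) != len(classes):
        raise ValueError("drug class names must be distinct")
    return list(itertools.combinations(sorted(classes), 2))


def product_name(a: str, b: str) -> str:
    a, b = sorted((a, b))
    return f"{a}{PRODUCT_SEP}{b}"


@dataclass
class FeatureMatrix:
    """Patient x feature table with binary outcome and column provenance."""

    X: pd.DataFrame  # index = patient_id
    y: pd.Series
    provenance: dict[str, str] = field(default_factory=dict)  # column -> drug|product|demographic|history
    window: ExposureWindow = ExposureWindow()
    washout_days: int = 180

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def n_patients(self) -> int:
        return len(self.X)

    @property
    def columns(self):
        return list(self.X.columns)

    def column_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for col in self.X.columns:
            kind = self.provenance.get(col, "unknown")
            counts[kind] = counts.get(kind, 0) + 1
        return counts

    def subset(self, patient_index) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.iloc[patient_index], self.y.iloc[patient_index],
            self.provenance, self.window, self.washout_days,
        )

    def write(self, path_prefix: str) -> None:
        out = self.X.copy()
        out.insert(0, "outcome", self.y.to_numpy())
        out.to_csv(f"{path_prefix}.csv")
        meta = {
            "window": self.window.label,
            "washout_days": self.washout_days,
            "provenance": self.provenance,
        }
        with open(f"{path_prefix}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, path_prefix: str) -> "FeatureMatrix":
        df = pd.read_csv(f"{path_prefix}.csv", index_col=0)
        with open(f"{path_prefix}.meta.json") as fh:
            meta = json.load(fh)
        y = df.pop("outcome")
        return cls(df, y, meta["provenance"], ExposureWindow.parse(meta["window"]),
                   meta["washout_days"])


def drop_empty_case_products(fm: FeatureMatrix) -> tuple[FeatureMatrix, int]:
    """Drop product columns that are all-zero among cases."""
    cases = fm.y.to_numpy() == 1
    drop = [
        col
        for col in fm.X.columns
        if fm.provenance.get(col) == "product" and not fm.X.loc[cases, col].any()
    ]
    X = fm.X.drop(columns=drop)
    prov = {c: k for c, k in fm.provenance.items() if c not in drop}
    return FeatureMatrix(X, fm.y, prov, fm.window, fm.washout_days), len(drop)


def encode_history(diagnoses: pd.DataFrame, baseline_date: int,
                   code_map: dict[str, tuple[str, ...]] | None = None) -> dict[str, int]:
    """Seven medical-history indicators for one patient.

    A condition is present iff any mapped code is dated strictly before
    baseline.  ``diagnoses`` holds that patient's rows only.
    """
    code_map = code_map or taxonomy.DEFAULT_ICD10_MAP
    out = {}
    for cond in taxonomy.HISTORY_CONDITIONS:
        if cond not in code_map:
            raise KeyError(f"no ICD-10 codes configured for condition {cond!r}")
        codes = set(code_map[cond])
        mask = diagnoses["icd10_code"].isin(codes) & (diagnoses["date"] < baseline_date)
        out[f"mh_{cond}"] = int(mask.any())
    return out


class ExposureFeaturizer(BaseEstimator):
    """Build the full feature matrix from cohort + event tables.

    transform(cohort, drugs, patients, diagnoses) -> FeatureMatrix with
    drug, product, demographic and history columns; product columns empty
    among cases are dropped when ``drop_empty`` (the default).
    """

    def __init__(
        self,
        window: ExposureWindow | str | tuple = ExposureWindow(),
        washout_days: int = 180,
        drug_classes: tuple[str, ...] = taxonomy.DRUG_CLASSES,
        icd10_map: dict[str, tuple[str, ...]] | None = None,
        drop_empty: bool = True,
    ):
        self.window = window
        self.washout_days = washout_days
        self.drug_classes = drug_classes
        self.icd10_map = icd10_map
        self.drop_empty = drop_empty

    def _drug_indicators(self, cohort: pd.DataFrame, drugs: pd.DataFrame,
                         window: ExposureWindow) -> pd.DataFrame:
        idx = cohort[["patient_id", "index_date"]]
        if len(drugs):
            ev = drugs.merge(idx, on="patient_id")
            ev = ev[ev["start_date"] <= ev["index_date"]]
            # earliest on-or-before-index event per (patient, class) is the
            # qualifying start under an unbounded lookback (see derive_drug_start)
            starts = (
                ev.groupby(["patient_id", "drug_class"], sort=True)
                .agg(start_date=("start_date", "min"), index_date=("index_date", "first"))
                .reset_index()
            )
            diff = starts["index_date"] - starts["start_date"]
            starts["use"] = (
                (diff >= window.lower_days) & (diff <= window.upper_days)
            ).astype(np.int8)
            wide = starts.pivot(index="patient_id", columns="drug_class", values="use")
        else:
            wide = pd.DataFrame(index=idx["patient_id"])
        wide = wide.reindex(index=cohort["patient_id"], columns=list(self.drug_classes),
                            fill_value=0).fillna(0).astype(np.int8)
        return wide

    def _history(self, cohort: pd.DataFrame, diagnoses: pd.DataFrame) -> pd.DataFrame:
        code_map = self.icd10_map or taxonomy.DEFAULT_ICD10_MAP
        cols = {}
        base = cohort.set_index("patient_id")["baseline_date"]
        for cond in taxonomy.HISTORY_CONDITIONS:
            if cond not in code_map:
                raise KeyError(f"no ICD-10 codes configured for condition {cond!r}")
            codes = set(code_map[cond])
            if len(diagnoses):
                dx = diagnoses[diagnoses["icd10_code"].isin(codes)].merge(
                    base.reset_index(), on="patient_id"
                )
                have = set(dx.loc[dx["date"] < dx["baseline_date"], "patient_id"])
            else:
                have = set()
            cols[f"mh_{cond}"] = cohort["patient_id"].isin(have).astype(np.int8).to_numpy()
        return pd.DataFrame(cols, index=cohort["patient_id"])

    def transform(
        self,
        cohort: pd.DataFrame,
        drugs: pd.DataFrame,
        patients: pd.DataFrame,
        diagnoses: pd.DataFrame,
    ) -> FeatureMatrix:
        window = ExposureWindow.parse(self.window)
        cohort = cohort.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
        y = pd.Series(
            (cohort["group"] == "case").astype(np.int8).to_numpy(),
            index=cohort["patient_id"], name="outcome",
        )

        D = self._drug_indicators(cohort, drugs, window)
        prov = {c: "drug" for c in D.columns}

        pairs = enumerate_product_terms(self.drug_classes)
        dvals = D.to_numpy()
        col_ix = {c: i for i, c in enumerate(D.columns)}
        prods = {
            product_name(a, b): dvals[:, col_ix[a]] & dvals[:, col_ix[b]]
            for a, b in pairs
        }
        P = pd.DataFrame(prods, index=D.index, dtype=np.int8)
        prov.update({c: "product" for c in P.columns})

        demo = patients.set_index("patient_id").loc[cohort["patient_id"]]
        demos = pd.DataFrame(index=D.index)
        demos["age"] = demo["age"].to_numpy().astype(np.int16)
        demos["sex_male"] = (demo["sex"].to_numpy() == "male").astype(np.int8)
        for hosp in taxonomy.HOSPITALS:
            demos[f"hospital_{hosp}"] = (demo["hospital"].to_numpy() == hosp).astype(np.int8)
        prov.update({c: "demographic" for c in demos.columns})

        H = self._history(cohort, diagnoses)
        prov.update({c: "history" for c in H.columns})

        X = pd.concat([D, P, demos, H], axis=1)
        fm = FeatureMatrix(X, y, prov, window, self.washout_days)
        if self.drop_empty:
            fm, _ = drop_empty_case_products(fm)
        return fm
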