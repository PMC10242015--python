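"""Synthetic longitudinal EHR generator with planted ground truth.

The generator emits the four delimited tables the downstream stages consume
(patients, serum-creatinine labs, drug-class start events, diagnoses) plus a
ground-truth table, for a case-control AKI study:

* ~8% of patients are AKI cases, drawn from a logistic outcome model in
  which one configurable drug pair carries a planted multiplicative product
  term — and therefore a known additive-scale interaction,
  ``RERI = or_a * or_b * or_product - or_a - or_b + 1``.
* Every true case's creatinine series is constructed to satisfy a KDIGO
  criterion (>= 0.3 mg/dL rise within 48 h, or >= 1.5x baseline within
  7 days) after an eligible 3-measurement run; every true control's series
  is constructed to fail both.  A configurable fraction of "decoy" patients
  violates the eligibility screen so the phenotyping filter is exercised.
* Dates are integer study-day offsets; identical seed + config produce
  byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import taxonomy


class SimulationConfigError(ValueError):
    """Raised when a SimulationConfig fails validation."""


class CalibrationError(RuntimeError):
    """Raised when the intercept cannot be calibrated to the target case fraction."""


def _default_start_probs() -> dict[str, tuple[float, float]]:
    return dict(taxonomy.DRUG_START_PROBS)


def _default_dx_prev() -> dict[str, float]:
    return dict(taxonomy.HISTORY_PREVALENCE)


def _default_dx_logodds() -> dict[str, float]:
    return dict(taxonomy.HISTORY_LOG_ODDS)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Odds ratios ``or_a``, ``or_b``, ``or_product`` act on the planted pair in
    the logistic outcome model; the intercept is calibrated by root finding
    so the realized case fraction matches ``case_fraction``.
    """

    n_patients: int
    seed: int = 0
    case_fraction: float = 0.081
    drug_classes: tuple[str, ...] = taxonomy.DRUG_CLASSES
    drug_start_probs: dict[str, tuple[float, float]] = field(default_factory=_default_start_probs)
    planted_pair: tuple[str, str] = ("loop_diuretics", "h2_blockers")
    or_a: float = 2.018
    or_b: float = 1.000
    or_product: float = 1.639
    #: marginal probability of a new start of each planted class
    planted_marginals: tuple[float, float] = (0.025, 0.122)
    #: sd of the mean-one lognormal co-prescription frailty shared by the
    #: planted pair (0 disables the co-start correlation)
    costart_sigma: float = 0.9
    age_mean: float = 62.0
    age_sd: float = 16.0
    sex_fraction: float = 0.545  # male
    hospital_probs: tuple[float, ...] = taxonomy.HOSPITAL_PROBS
    dx_prevalences: dict[str, float] = field(default_factory=_default_dx_prev)
    dx_log_odds: dict[str, float] = field(default_factory=_default_dx_logodds)
    age_log_or: float = 0.02  # per year, centered at age_mean
    male_log_or: float = 0.504
    window_days: tuple[int, int] = (1, 7)
    decoy_fraction: float = 0.10
    excluded_dx_prob: float = 0.01
    high_baseline_prob: float = 0.002
    icd10_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(taxonomy.DEFAULT_ICD10_MAP)
    )
    excluded_codes: tuple[str, ...] = taxonomy.DEFAULT_EXCLUDED_CODES

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SimulationConfigError("n_patients must be non-negative")
        probs = [
            self.case_fraction,
            self.sex_fraction,
            self.decoy_fraction,
            self.excluded_dx_prob,
            self.high_baseline_prob,
            *self.planted_marginals,
            *self.dx_prevalences.values(),
        ]
        for name, (pc, p0) in self.drug_start_probs.items():
            probs.extend([pc, p0])
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SimulationConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.hospital_probs) - 1.0) > 1e-9:
            raise SimulationConfigError("hospital_probs must sum to 1")
        if len(self.drug_classes) != 32:
            raise SimulationConfigError("exactly 32 drug classes are required")
        if len(set(self.drug_classes)) != len(self.drug_classes):
            raise SimulationConfigError("drug classes must be distinct")
        for ratio in (self.or_a, self.or_b, self.or_product):
            if not ratio > 0:
                raise SimulationConfigError("planted odds ratios must be > 0")
        for cls in self.planted_pair:
            if cls not in self.drug_classes:
                raise SimulationConfigError(f"planted class {cls!r} not in taxonomy")
        lo, hi = self.window_days
        if not (1 <= lo <= hi):
            raise SimulationConfigError("window_days must satisfy 1 <= lower <= upper")

    def implied_true_reri(self) -> float:
        """Additive-scale interaction implied by the generating odds ratios."""
        return self.or_a * self.or_b * self.or_product - self.or_a - self.or_b + 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([int(config.seed), stage])


def _patient_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:07d}" for i in range(n)], dtype=object)


def generate_population(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw demographics and pre-baseline diagnosis events.

    Returns ``(patients, diagnoses)``.  Diagnosis events are dated on days
    0-30, strictly before any patient's eventual baseline (day >= 43).
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_patients
    ids = _patient_ids(n)
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 0, 100).astype(int)
    male = rng.random(n) < config.sex_fraction
    hospital = rng.choice(np.array(taxonomy.HOSPITALS, dtype=object), size=n,
                          p=np.asarray(config.hospital_probs))
    patients = pd.DataFrame(
        {
            "patient_id": ids,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "hospital": hospital,
        }
    )

    rows: list[pd.DataFrame] = []
    for cond in taxonomy.HISTORY_CONDITIONS:
        prev = config.dx_prevalences.get(cond, 0.0)
        mask = rng.random(n) < prev
        if mask.any():
            code = config.icd10_map[cond][0]
            rows.append(
                pd.DataFrame(
                    {
                        "patient_id": ids[mask],
                        "icd10_code": code,
                        "date": rng.integers(0, 31, int(mask.sum())),
                    }
                )
            )
    # a small fraction carries a pre-existing kidney-disease exclusion code
    mask = rng.random(n) < config.excluded_dx_prob
    if mask.any():
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": ids[mask],
                    "icd10_code": config.excluded_codes[0],
                    "date": rng.integers(0, 31, int(mask.sum())),
                }
            )
        )
    if rows:
        diagnoses = pd.concat(rows, ignore_index=True)
    else:
        diagnoses = pd.DataFrame(columns=["patient_id", "icd10_code", "date"])
    diagnoses = diagnoses.sort_values(
        ["patient_id", "date", "icd10_code"], kind="mergesort"
    ).reset_index(drop=True)
    diagnoses["date"] = diagnoses["date"].astype(int) if len(diagnoses) else diagnoses["date"]
    return patients, diagnoses


def _covariate_eta(config: SimulationConfig, patients: pd.DataFrame,
                   diagnoses: pd.DataFrame) -> np.ndarray:
    eta = config.age_log_or * (patients["age"].to_numpy() - config.age_mean)
    eta = eta + config.male_log_or * (patients["sex"].to_numpy() == "male")
    if len(diagnoses):
        code_to_cond = {
            code: cond for cond, codes in config.icd10_map.items() for code in codes
        }
        dx = diagnoses.assign(condition=diagnoses["icd10_code"].map(code_to_cond))
        dx = dx.dropna(subset=["condition"])
        have = dx.groupby(["patient_id", "condition"]).size().unstack(fill_value=0) > 0
        have = have.reindex(index=patients["patient_id"],
                            columns=list(taxonomy.HISTORY_CONDITIONS), fill_value=False)
        for cond in taxonomy.HISTORY_CONDITIONS:
            eta = eta + config.dx_log_odds.get(cond, 0.0) * have[cond].to_numpy()
    return np.asarray(eta, dtype=float)


def calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(alpha + eta)) = target for alpha by bisection."""

    def gap(alpha: float) -> float:
        return float(expit(alpha + eta).mean() - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"case fraction {target} unattainable for the given linear predictor"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10))


def generate_outcomes_and_drugs(
    config: SimulationConfig,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw drug-start events and case/control ground truth.

    The outcome obeys ``logit p = alpha + log(or_a) x_a + log(or_b) x_b +
    log(or_product) x_a x_b + covariates`` for the planted pair; the
    remaining 30 classes are drawn conditional on the realized label with
    the configured case/control prevalences, which keeps the conditional
    outcome model exactly logistic-additive in every feature.
    """
    config.validate()
    rng = _rng(config, 2)
    n = len(patients)
    if n == 0:
        drugs = pd.DataFrame(columns=["patient_id", "drug_class", "start_date"])
        gt = pd.DataFrame(
            columns=["patient_id", "true_label", "true_event_date", "eligible",
                     "first_day", "baseline_day", "index_day", "criterion"]
        )
        return drugs, gt
    if diagnoses is None:
        diagnoses = pd.DataFrame(columns=["patient_id", "icd10_code", "date"])
    ids = patients["patient_id"].to_numpy()

    eta = _covariate_eta(config, patients, diagnoses)

    # planted exposures with shared co-prescription frailty
    cls_a, cls_b = config.planted_pair
    pa0, pb0 = config.planted_marginals
    if config.costart_sigma > 0:
        s = config.costart_sigma
        frailty = rng.lognormal(-0.5 * s * s, s, n)
    else:
        frailty = np.ones(n)
    x_a = rng.random(n) < np.clip(pa0 * frailty, 0.0, 0.95)
    x_b = rng.random(n) < np.clip(pb0 * frailty, 0.0, 0.95)

    eta_full = (
        eta
        + np.log(config.or_a) * x_a
        + np.log(config.or_b) * x_b
        + np.log(config.or_product) * (x_a & x_b)
    )
    alpha = calibrate_intercept(eta_full, config.case_fraction)
    y = rng.random(n) < expit(alpha + eta_full)

    # visit schedule (integer study days)
    first_day = rng.integers(42, 56, n)
    g1 = rng.integers(1, 4, n)
    baseline_day = first_day + g1
    crit_delta = rng.random(n) < 0.5
    case_gap = np.where(crit_delta, rng.integers(1, 3, n), rng.integers(3, 8, n))
    g2 = rng.integers(1, 4, n)
    index_day = np.where(y, baseline_day + case_gap, baseline_day + g2)
    decoy = rng.random(n) < config.decoy_fraction

    lo, hi = config.window_days
    pieces: list[pd.DataFrame] = []
    for cls in config.drug_classes:
        if cls == cls_a:
            z = x_a
        elif cls == cls_b:
            z = x_b
        else:
            pc, p0 = config.drug_start_probs.get(cls, (0.0, 0.0))
            z = rng.random(n) < np.where(y, pc, p0)
        start_use = index_day - rng.integers(lo, hi + 1, n)
        u = rng.random(n)
        far_start = index_day - rng.integers(hi + 1, hi + 35, n)
        future_start = index_day + rng.integers(0, 6, n)
        cont_early = index_day - rng.integers(hi + 8, hi + 21, n)
        cont_late = index_day - rng.integers(lo, hi + 1, n)

        use = z
        far = (~z) & (u < 0.12)
        fut = (~z) & (u >= 0.12) & (u < 0.17)
        cont = (~z) & (u >= 0.17) & (u < 0.25)
        for mask, dates in (
            (use, start_use),
            (far, far_start),
            (fut, future_start),
            (cont, cont_early),
            (cont, cont_late),
        ):
            if mask.any():
                pieces.append(
                    pd.DataFrame(
                        {
                            "patient_id": ids[mask],
                            "drug_class": cls,
                            "start_date": dates[mask],
                        }
                    )
                )
    if pieces:
        drugs = pd.concat(pieces, ignore_index=True)
        drugs["start_date"] = drugs["start_date"].astype(int)
    else:
        drugs = pd.DataFrame(columns=["patient_id", "drug_class", "start_date"])
    drugs = drugs.sort_values(
        ["patient_id", "drug_class", "start_date"], kind="mergesort"
    ).reset_index(drop=True)

    gt = pd.DataFrame(
        {
            "patient_id": ids,
            "true_label": np.where(y, "case", "control"),
            "true_event_date": pd.array(
                np.where(y, index_day, -1), dtype="Int64"
            ),
            "eligible": ~decoy,
            "first_day": first_day,
            "baseline_day": baseline_day,
            "index_day": index_day,
            "criterion": np.where(
                y, np.where(crit_delta, "delta_048h", "ratio_7d"), "none"
            ),
        }
    )
    gt.loc[~y, "true_event_date"] = pd.NA
    return drugs, gt


def generate_lab_series(config: SimulationConfig, ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Construct serum-creatinine series consistent with the ground truth.

    Values are built directly to satisfy (cases) or fail (controls) the
    KDIGO criteria relative to the baseline measurement — no rejection
    sampling — and rounded to 2 decimals, the resolution of a creatinine
    assay.  Decoy patients get series that violate the eligibility screen
    in one of three ways (too few tests, an 8-day gap, >= 50% baseline
    instability).
    """
    config.validate()
    rng = _rng(config, 3)
    n = len(ground_truth)
    if n == 0:
        return pd.DataFrame(columns=["patient_id", "date", "scr"])
    gt = ground_truth
    ids = gt["patient_id"].to_numpy()
    is_case = (gt["true_label"].to_numpy() == "case")
    eligible = gt["eligible"].to_numpy(dtype=bool)
    first = gt["first_day"].to_numpy(dtype=int)
    base_day = gt["baseline_day"].to_numpy(dtype=int)
    idx_day = gt["index_day"].to_numpy(dtype=int)
    delta_case = gt["criterion"].to_numpy() == "delta_048h"

    b = np.clip(rng.lognormal(np.log(0.8), 0.25, n), 0.3, 3.0)
    high = rng.random(n) < config.high_baseline_prob
    b = np.where(high, np.clip(b, 0.75, 3.0) * 7.0, b)

    v1 = b * (1.0 + rng.uniform(-0.2, 0.2, n))
    cap = np.minimum(0.29, 0.45 * b)
    v3_control = b + (-0.2 * b) + (cap + 0.2 * b) * rng.random(n)
    v3_delta = b + rng.uniform(0.32, 0.9, n)
    v3_ratio = b * rng.uniform(1.55, 2.2, n)
    v3 = np.where(is_case, np.where(delta_case, v3_delta, v3_ratio), v3_control)

    extra_u = rng.random(n)
    extra_day = np.where(is_case,
                         idx_day + rng.integers(1, 6, n),
                         idx_day + rng.integers(8, 16, n))
    extra_val = np.where(
        is_case,
        v3 * (1.0 + rng.uniform(-0.1, 0.1, n)),
        b + (-0.2 * b) + (cap + 0.2 * b) * rng.random(n),
    )
    has_extra = np.where(is_case, extra_u < 0.30, extra_u < 0.40)

    decoy_variant = rng.integers(0, 3, n)

    pid_col: list[np.ndarray] = []
    day_col: list[np.ndarray] = []
    val_col: list[np.ndarray] = []

    el = eligible
    # eligible patients: first, baseline, third(index) [+ optional extra]
    for days, vals, mask in (
        (first, v1, el),
        (base_day, b, el),
        (idx_day, v3, el),
        (extra_day, extra_val, el & has_extra),
    ):
        pid_col.append(ids[mask])
        day_col.append(days[mask])
        val_col.append(vals[mask])

    # decoys
    for variant, offsets, mults in (
        (0, (0, 2), (1.0, 1.05)),
        (1, (0, 8, 10), (1.0, 1.05, 1.02)),
        (2, (0, 2, 4), (1.0, 1.62, 1.60)),
    ):
        mask = (~el) & (decoy_variant == variant)
        if not mask.any():
            continue
        for off, mult in zip(offsets, mults):
            pid_col.append(ids[mask])
            day_col.append(first[mask] + off)
            val_col.append(b[mask] * mult)

    labs = pd.DataFrame(
        {
            "patient_id": np.concatenate(pid_col),
            "date": np.concatenate(day_col).astype(int),
            "scr": np.round(np.concatenate(val_col), 2),
        }
    )
    labs["scr"] = np.maximum(labs["scr"], 0.01)
    labs = labs.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    return labs


def simulate(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator; returns the five tables keyed by name."""
    patients, diagnoses = generate_population(config)
    drugs, ground_truth = generate_outcomes_and_drugs(config, patients, diagnoses)
    labs = generate_lab_series(config, ground_truth)
    return {
        "patients": patients,
        "labs": labs,
        "drugs": drugs,
        "diagnoses": diagnoses,
        "ground_truth": ground_truth,
    }


def write_tables(tables: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Write each table as ``<name>.csv`` under ``outdir``; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = os.path.join(str(outdir), f"{name}.csv")
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(indir) -> dict[str, pd.DataFrame]:
    import os

    out = {}
    for name in ("patients", "labs", "drugs", "diagnoses", "ground_truth"):
        path = os.path.join(str(indir), f"{name}.csv")
        if os.path.exists(path):
            out[name] = pd.read_csv(path)
    return out
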