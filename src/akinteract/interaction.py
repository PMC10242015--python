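"""Additive-scale drug-drug interaction inference and SHAP importance.

For a drug pair with lasso log-odds coefficients ``b1`` (class A), ``b2``
(class B) and ``b3`` (their product term), the relative excess risk due to
interaction is

    RERI = exp(b1 + b2 + b3) - exp(b1) - exp(b2) + 1,

zero meaning no interaction on the additive scale.  RERI is invalid when
either individual adjusted odds ratio is below 1 (an exactly-zero lasso
coefficient gives OR = 1.000, which passes).  Confidence intervals come
from a percentile bootstrap: resamples of the training set, each of the
original size, are refit at the tuned penalty; for B = 2,000 estimates the
95% CI is the interval between the 50th and 1,950th order statistics.  A
pair is flagged as a positive interaction only under the dual rule: the
product-term OR CI lower limit exceeds 1 AND the RERI CI lower limit
exceeds 0.

Feature importance for the tree model uses per-patient SHAP attributions
(tree-path-dependent TreeSHAP on the margin scale) aggregated as the mean
absolute value per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .features import ExposureWindow, ExposureFeaturizer, FeatureMatrix, product_name
from .models import FittedModel, PenalizedLogisticRegression, fit_llr

logger = logging.getLogger(__name__)


@dataclass
class RERIResult:
    """Point estimates (and optionally bootstrap CIs) for one drug pair."""

    pair: tuple[str, str]
    or_a: float
    or_b: float
    or_product: float
    combined: float
    reri: float | None
    valid: bool
    reason: str = ""
    ci_or_product: tuple[float, float] | None = None
    ci_reri: tuple[float, float] | None = None
    flagged: bool = False


def reri(or_a: float, or_b: float, or_product: float,
         pair: tuple[str, str] = ("drug_a", "drug_b")) -> RERIResult:
    """Additive-scale interaction from three exponentiated coefficients.

    Invalid (no RERI emitted) when either individual OR is below 1.
    """
    for name, v in (("or_a", or_a), ("or_b", or_b), ("or_product", or_product)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    combined = or_a * or_b * or_product
    if or_a < 1.0 or or_b < 1.0:
        return RERIResult(pair, or_a, or_b, or_product, combined, None, False,
                          reason="individual adjusted OR below 1")
    value = combined - or_a - or_b + 1.0
    return RERIResult(pair, or_a, or_b, or_product, combined, value, True)


def reri_value(or_a: float, or_b: float, or_product: float) -> float:
    """Bare RERI arithmetic (no validity gating)."""
    return or_a * or_b * or_product - or_a - or_b + 1.0


@dataclass
class BootstrapDistribution:
    """Percentile-bootstrap estimates for one scalar parameter."""

    parameter: str
    estimates: np.ndarray  # sorted ascending
    seed: int
    ci: tuple[float, float]
    n_redrawn: int = 0


def _percentile_ci(sorted_estimates: np.ndarray) -> tuple[float, float]:
    """Order-statistic CI: indices ceil(0.025 B) and floor(0.975 B) (1-based).

    For B = 2,000 these are the 50th and 1,950th order statistics.
    """
    b = len(sorted_estimates)
    if b < 2:
        raise ValueError("need at least 2 bootstrap estimates")
    lo = int(np.ceil(0.025 * b)) - 1
    hi = int(np.floor(0.975 * b)) - 1
    return float(sorted_estimates[lo]), float(sorted_estimates[hi])


def percentile_bootstrap(data, estimator, B: int = 2000, seed: int = 0,
                         max_redraws: int = 100) -> BootstrapDistribution:
    """Resample ``data`` rows with replacement; CI from empirical order statistics.

    ``estimator`` maps one resample (same length as ``data``) to a scalar;
    a failing resample (exception or NaN) is redrawn and counted.
    """
    data = np.asarray(data) if not isinstance(data, (pd.DataFrame, pd.Series)) else data
    n = len(data)
    rng = np.random.default_rng(seed)
    estimates = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, n)
            sample = data.iloc[idx] if hasattr(data, "iloc") else data[idx]
            try:
                val = float(estimator(sample))
            except Exception:
                val = float("nan")
            if np.isfinite(val):
                estimates[b] = val
                break
            redrawn += 1
        else:
            raise RuntimeError("estimator failed on every redraw of a resample")
    estimates.sort()
    return BootstrapDistribution(
        parameter=getattr(estimator, "__name__", "estimate"),
        estimates=estimates,
        seed=seed,
        ci=_percentile_ci(estimates),
        n_redrawn=redrawn,
    )


def detect_interactions(
    model: PenalizedLogisticRegression,
    fm_train: FeatureMatrix,
    pairs: list[tuple[str, str]] | None = None,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap the lasso refit (penalty fixed) and apply the dual rule.

    Candidate ``pairs`` default to every retained product term with a
    nonzero product coefficient.  Each bootstrap resample of the training
    set is refit at the tuned penalty; per pair, the product-term OR and
    RERI distributions give percentile CIs.  ``flagged`` is True iff the
    OR CI lower limit > 1 and the RERI CI lower limit > 0; RERI CIs are
    only computed when the point-estimate validity rule passes.
    """
    coefs = model.coefficients_
    name_ix = {n: i for i, n in enumerate(model.feature_names_)}
    if pairs is None:
        pairs = []
        for col, kind in fm_train.provenance.items():
            if kind == "product" and coefs.get(col, 0.0) != 0.0:
                a, b = col.split("*")
                pairs.append((a, b))
    usable: list[tuple[str, str, str]] = []
    for a, b in pairs:
        pname = product_name(a, b)
        if pname not in name_ix or a not in name_ix or b not in name_ix:
            logger.warning("pair (%s, %s): product term absent from model; skipped", a, b)
            continue
        usable.append((a, b, pname))
    if not usable:
        return pd.DataFrame(
            columns=["class_a", "class_b", "or_a", "or_b", "or_product", "combined",
                     "reri", "or_product_lo", "or_product_hi", "reri_lo", "reri_hi",
                     "valid", "flagged"]
        )

    needed = sorted({ix for a, b, p in usable for ix in
                     (name_ix[a], name_ix[b], name_ix[p])})
    Xm = sp.csr_matrix(fm_train.X.to_numpy(dtype=np.float64))
    y = fm_train.y.to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    n = Xm.shape[0]
    boot = np.empty((B, len(needed)))
    solver = None
    for r in range(B):
        idx = rng.integers(0, n, n)
        coef, _icpt, solver = model.refit_fixed(Xm[idx], y[idx], solver)
        boot[r] = coef[needed]
    col_of = {ix: j for j, ix in enumerate(needed)}

    rows = []
    for a, b, pname in usable:
        res = reri(
            float(np.exp(coefs[a])),
            float(np.exp(coefs[b])),
            float(np.exp(coefs[pname])),
            pair=(a, b),
        )
        b1 = boot[:, col_of[name_ix[a]]]
        b2 = boot[:, col_of[name_ix[b]]]
        b3 = boot[:, col_of[name_ix[pname]]]
        orp = np.sort(np.exp(b3))
        res.ci_or_product = _percentile_ci(orp)
        if res.valid:
            rr = np.sort(np.exp(b1 + b2 + b3) - np.exp(b1) - np.exp(b2) + 1.0)
            res.ci_reri = _percentile_ci(rr)
            res.flagged = res.ci_or_product[0] > 1.0 and res.ci_reri[0] > 0.0
        rows.append(
            {
                "class_a": a, "class_b": b,
                "or_a": res.or_a, "or_b": res.or_b, "or_product": res.or_product,
                "combined": res.combined, "reri": res.reri,
                "or_product_lo": res.ci_or_product[0], "or_product_hi": res.ci_or_product[1],
                "reri_lo": res.ci_reri[0] if res.ci_reri else np.nan,
                "reri_hi": res.ci_reri[1] if res.ci_reri else np.nan,
                "valid": res.valid, "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- SHAP

def shap_rank(model, X: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Mean-|SHAP| feature ranking for a gradient-boosted tree model.

    SHAP attributions are computed on the margin (log-odds) scale with the
    tree-path-dependent TreeSHAP algorithm; the summary is the mean
    absolute value per feature, ranked descending, with a direction column
    (mean SHAP among rows where a binary feature is 1, else the sign of
    the SHAP-value correlation for continuous features).
    """
    import xgboost as xgb

    if isinstance(model, FittedModel):
        model = model.estimator
    if isinstance(model, xgb.XGBClassifier):
        booster = model.get_booster()
    elif isinstance(model, xgb.Booster):
        booster = model
    else:
        raise TypeError("SHAP ranking requires a gradient-boosted tree model")
    dm = xgb.DMatrix(X.to_numpy(dtype=np.float64), feature_names=[str(c) for c in X.columns])
    contrib = booster.predict(dm, pred_contribs=True)  # (n, p + 1); last = bias
    shap_vals = contrib[:, :-1]
    mean_abs = np.abs(shap_vals).mean(axis=0)
    direction = np.zeros(X.shape[1])
    xv = X.to_numpy(dtype=np.float64)
    for j in range(X.shape[1]):
        col = xv[:, j]
        if set(np.unique(col)) <= {0.0, 1.0}:
            on = col == 1.0
            direction[j] = shap_vals[on, j].mean() if on.any() else 0.0
        else:
            sd = col.std()
            direction[j] = float(np.corrcoef(col, shap_vals[:, j])[0, 1]) if sd > 0 else 0.0
    out = pd.DataFrame(
        {
            "feature": [str(c) for c in X.columns],
            "mean_abs_shap": mean_abs,
            "direction": direction,
        }
    ).sort_values(["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    out = out.reset_index(drop=True)
    return out.head(top_k) if top_k else out


def shap_values(model, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-patient SHAP matrix and base values (margin scale)."""
    import xgboost as xgb

    if isinstance(model, FittedModel):
        model = model.estimator
    booster = model.get_booster() if isinstance(model, xgb.XGBClassifier) else model
    if not isinstance(booster, xgb.Booster):
        raise TypeError("SHAP values require a gradient-boosted tree model")
    dm = xgb.DMatrix(X.to_numpy(dtype=np.float64), feature_names=[str(c) for c in X.columns])
    contrib = booster.predict(dm, pred_contribs=True)
    return contrib[:, :-1], contrib[:, -1]


# ------------------------------------------------------- sensitivity runs

def sensitivity_reruns(
    cohort: pd.DataFrame,
    drugs: pd.DataFrame,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    windows=((1, 7), (1, 14), (1, 30)),
    pairs: list[tuple[str, str]] | None = None,
    B: int = 500,
    seed: int = 0,
    llr_kwargs: dict | None = None,
) -> dict:
    """Rebuild features and re-run LLR + RERI detection per exposure window.

    Returns a dict keyed by window label with the feature matrix summary,
    the interaction table and per-window exposure prevalences, plus an
    ``aligned`` table of flags across windows.
    """
    llr_kwargs = dict(llr_kwargs or {})
    results: dict = {}
    frames = []
    for win in windows:
        window = ExposureWindow.parse(win)
        fz = ExposureFeaturizer(window=window)
        fm = fz.transform(cohort, drugs, patients, diagnoses)
        model = fit_llr(fm, **llr_kwargs)
        table = detect_interactions(model, fm, pairs=pairs, B=B, seed=seed)
        drug_cols = [c for c, k in fm.provenance.items() if k == "drug"]
        prevalence = fm.X[drug_cols].mean().to_dict()
        results[window.label] = {
            "interactions": table,
            "n_features": fm.X.shape[1],
            "exposure_prevalence": prevalence,
            "lambda": model.lambda_,
        }
        t = table[["class_a", "class_b", "or_product", "reri", "flagged"]].copy()
        t["reri"] = t["reri"].astype(float)
        t["window"] = window.label
        frames.append(t)
    frames = [f for f in frames if len(f)]
    results["aligned"] = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    return results
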