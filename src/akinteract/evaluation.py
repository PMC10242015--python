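"""Evaluation-metric battery for the binary AKI prediction models.

Brier score (mean squared error between outcome and predicted probability)
with a nonparametric bootstrap CI; AUROC with a DeLong variance CI and AUPR
with a bootstrap CI; logistic-recalibration calibration slope and intercept
(targets 1 and 0 — a slope below 1 means the predicted risks are too
extreme); confusion-matrix classification metrics at a fixed or
Youden-optimal threshold; learning/robustness curves over training-set
fractions; and paired model comparisons (DeLong test for AUROC, bootstrap
test for AUPR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_curve


def _check_preds(y, p):
    y = np.asarray(y).astype(int).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty prediction set")
    if len(y) != len(p):
        raise ValueError("y and p must have equal length")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return y, p


def brier_score(y, p, n_boot: int = 1000, seed: int = 0,
                alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Mean squared error between outcome and predicted probability, with CI."""
    y, p = _check_preds(y, p)
    sq = (p - y) ** 2
    value = float(sq.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(y), size=(n_boot, len(y)))
    boots = sq[idx].mean(axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return value, (float(lo), float(hi))


# ---------------------------------------------------------------- DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_components(y: np.ndarray, scores: np.ndarray):
    """Per-observation placement values for one or more score vectors.

    ``scores`` has shape (k, n); returns (aucs, covariance matrix) per the
    fast DeLong algorithm with midranks.
    """
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both outcome classes are required")
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        all_r = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(all_r)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def auroc_with_ci(y, p, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Rank-based (tie-aware) AUROC with a DeLong-variance CI."""
    y, p = _check_preds(y, p)
    aucs, cov = _delong_components(y, p[None, :])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = norm.ppf(1 - alpha / 2)
    auc = float(aucs[0])
    return auc, (max(0.0, auc - z * se), min(1.0, auc + z * se))


def delong_variance(y, p) -> float:
    y, p = _check_preds(y, p)
    _, cov = _delong_components(y, p[None, :])
    return float(cov[0, 0])


def aupr_with_ci(y, p, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Area under the precision-recall curve with a bootstrap CI."""
    y, p = _check_preds(y, p)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes are required")
    value = float(average_precision_score(y, p))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(y)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            boots[b] = np.nan
            continue
        boots[b] = average_precision_score(yb, p[idx])
    boots = boots[~np.isnan(boots)]
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return value, (float(lo), float(hi))


# ------------------------------------------------------------ calibration

def calibration_slope_intercept(y, p, clip: float = 1e-6) -> dict:
    """Logistic recalibration: regress the outcome on logit(prediction).

    Slope target 1 (below 1 = predictions too extreme), intercept target 0
    (below 0 = risk overestimated).  Returns point estimates, Wald CIs and
    an interpretation string.
    """
    y, p = _check_preds(y, p)
    p = np.clip(p, clip, 1 - clip)
    lp = logit(p)
    if np.allclose(lp, lp[0]):
        raise ValueError("constant predictions: calibration slope undefined")
    res = sm.Logit(y, sm.add_constant(lp)).fit(disp=0)
    ci = res.conf_int()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    notes = []
    if slope < 1:
        notes.append("slope < 1: predicted risks are too extreme")
    if intercept < 0:
        notes.append("intercept < 0: predicted risk overestimated")
    return {
        "slope": slope,
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "intercept": intercept,
        "intercept_ci": (float(ci[0][0]), float(ci[0][1])),
        "interpretation": "; ".join(notes) or "calibrated",
    }


# --------------------------------------------------- classification metrics

def youden_threshold(y, p) -> float:
    """Probability cutoff maximising sensitivity + specificity - 1."""
    y, p = _check_preds(y, p)
    fpr, tpr, thr = roc_curve(y, p)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def classification_metrics(y, p, threshold: float | str = "youden",
                           train_preds: tuple | None = None) -> dict:
    """Confusion-matrix rates at a resolved threshold.

    ``threshold`` is a fixed cutoff, or ``"youden"`` — resolved on
    ``train_preds=(y_train, p_train)`` when supplied (the recommended
    usage), else on the evaluation set itself.
    """
    y, p = _check_preds(y, p)
    if threshold == "youden":
        if train_preds is not None:
            t = youden_threshold(*train_preds)
        else:
            t = youden_threshold(y, p)
    else:
        t = float(threshold)
    pred = p >= t
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def _rate(num, den):
        return num / den if den else float("nan")

    sens = _rate(tp, tp + fn)
    ppv = _rate(tp, tp + fp)
    spec = _rate(tn, tn + fp)
    npv = _rate(tn, tn + fn)
    f1 = _rate(2 * ppv * sens, ppv + sens) if not (np.isnan(ppv) or np.isnan(sens)) else float("nan")
    return {
        "threshold": t,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "ppv": ppv, "specificity": spec, "npv": npv, "f1": f1,
    }


# ------------------------------------------------------------- robustness

def robustness_curve(fit_fn, fm_train, fm_test,
                     fractions=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
                     seed: int = 0) -> pd.DataFrame:
    """Refit on stratified training subsamples; evaluate on the fixed test set.

    ``fit_fn(X, y) -> estimator with predict_proba``.  Fractions yielding a
    single-class subsample are recorded as missing points.
    """
    fractions = sorted(float(f) for f in fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    y = fm_train.y.to_numpy()
    rows = []
    for frac in fractions:
        if frac == 1.0:
            idx = np.arange(len(y))
        else:
            idx = []
            for cls in np.unique(y):
                members = np.flatnonzero(y == cls)
                take = max(1, int(round(frac * len(members))))
                idx.append(rng.choice(members, size=take, replace=False))
            idx = np.sort(np.concatenate(idx))
        yb = y[idx]
        if yb.min() == yb.max():
            rows.append({"fraction": frac, "auroc": np.nan, "aupr": np.nan})
            continue
        est = fit_fn(fm_train.X.iloc[idx], yb)
        proba = est.predict_proba(fm_test.X)
        p = np.asarray(proba)[:, 1] if np.ndim(proba) == 2 else np.asarray(proba)
        auroc, _ = auroc_with_ci(fm_test.y.to_numpy(), p)
        aupr = float(average_precision_score(fm_test.y.to_numpy(), p))
        rows.append({"fraction": frac, "auroc": auroc, "aupr": aupr})
    return pd.DataFrame(rows)


# --------------------------------------------------------- model comparison

def compare_models(preds_a: pd.DataFrame, preds_b: pd.DataFrame,
                   n_boot: int = 1000, seed: int = 0) -> dict:
    """Paired comparison of two prediction sets on the same patients.

    DeLong test for the AUROC difference; paired percentile-bootstrap test
    for the AUPR difference.
    """
    a = preds_a.sort_values("patient_id").reset_index(drop=True)
    b = preds_b.sort_values("patient_id").reset_index(drop=True)
    if len(a) != len(b) or not (a["patient_id"].to_numpy() == b["patient_id"].to_numpy()).all():
        raise ValueError("prediction sets cover different patients")
    if not (a["y_true"].to_numpy() == b["y_true"].to_numpy()).all():
        raise ValueError("prediction sets disagree on outcomes")
    y = a["y_true"].to_numpy().astype(int)
    pa = a["y_prob"].to_numpy(dtype=float)
    pb = b["y_prob"].to_numpy(dtype=float)

    aucs, cov = _delong_components(y, np.vstack([pa, pb]))
    d_auc = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0 or np.isclose(d_auc, 0.0) and var < 1e-16:
        p_auroc = 1.0
        z = 0.0
    else:
        z = d_auc / np.sqrt(var)
        p_auroc = float(2 * norm.sf(abs(z)))

    ap_a = float(average_precision_score(y, pa))
    ap_b = float(average_precision_score(y, pb))
    rng = np.random.default_rng(seed)
    diffs = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        diffs.append(
            average_precision_score(yb, pa[idx]) - average_precision_score(yb, pb[idx])
        )
    diffs = np.asarray(diffs)
    p_lo = float(np.mean(diffs <= 0))
    p_hi = float(np.mean(diffs >= 0))
    p_aupr = min(1.0, 2 * min(p_lo, p_hi))
    return {
        "auroc_a": float(aucs[0]), "auroc_b": float(aucs[1]),
        "delta_auroc": d_auc, "z_auroc": float(z), "p_auroc": p_auroc,
        "aupr_a": ap_a, "aupr_b": ap_b, "delta_aupr": ap_a - ap_b,
        "p_aupr": p_aupr,
    }
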