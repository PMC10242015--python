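"""Lasso core (vs glmnet oracle), comparator suite and split contracts."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import akinteract as ak
from akinteract.models import (
    PenalizedLogisticRegression,
    SchemaError,
    SplitSpec,
    fit_comparators,
    split_dataset,
)


def _logistic_design(seed=42, n=400, p=6):
    rng = np.random.default_rng(seed)
    X = rng.binomial(1, rng.uniform(0.1, 0.4, p), (n, p)).astype(float)
    X[:, -1] = rng.normal(60, 15, n)
    eta = -2.0 + 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.02 * (X[:, -1] - 60)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return X, y


def test_split_sizes_and_determinism(sim_small):
    fm = sim_small["fm"]
    tr, te = split_dataset(fm, SplitSpec(0.8, seed=1))
    assert tr.n_patients == int(np.floor(0.8 * fm.n_patients))
    assert tr.n_patients + te.n_patients == fm.n_patients
    assert set(tr.X.index).isdisjoint(te.X.index)
    tr2, te2 = split_dataset(fm, SplitSpec(0.8, seed=1))
    assert (tr.X.index == tr2.X.index).all()


def test_split_reproduces_published_arithmetic():
    # floor(0.8 x 65,667) = 52,533 and the complement 13,134
    assert int(np.floor(0.8 * 65667)) == 52533
    assert 65667 - 52533 == 13134


def test_split_rejects_tiny_inputs(sim_small):
    fm = sim_small["fm"].subset(np.arange(5))
    with pytest.raises(ValueError):
        split_dataset(fm)


def test_full_shrinkage_at_large_lambda():
    X, y = _logistic_design()
    m = PenalizedLogisticRegression(fixed_lambda=10.0).fit(X, y)
    assert (m.coef_ == 0.0).all()
    # intercept-only model predicts the prevalence everywhere
    p = m.predict_proba(X)[:, 1]
    assert np.allclose(p, p[0])
    assert p[0] == pytest.approx(y.mean(), abs=0.02)


def test_single_class_training_rejected():
    X, _ = _logistic_design()
    with pytest.raises(ValueError):
        PenalizedLogisticRegression(fixed_lambda=0.01).fit(X, np.zeros(len(X)))


def test_matches_glmnet_at_fixed_lambda():
    """Independent oracle: R glmnet on the identical objective."""
    X, y = _logistic_design()
    lam = 0.01
    m = PenalizedLogisticRegression(fixed_lambda=lam).fit(X, y)
    script = (
        "suppressMessages(library(glmnet));"
        "X <- as.matrix(read.csv('X.csv', header=FALSE));"
        "y <- scan('y.csv', quiet=TRUE);"
        f"fit <- glmnet(X, y, family='binomial', lambda={lam}, standardize=TRUE, thresh=1e-12);"
        "cat(as.numeric(coef(fit)), sep='\\n')"
    )
    import tempfile, os

    with tempfile.TemporaryDirectory() as tmp:
        np.savetxt(os.path.join(tmp, "X.csv"), X, delimiter=",")
        np.savetxt(os.path.join(tmp, "y.csv"), y, fmt="%d")
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, cwd=tmp
        )
    assert res.returncode == 0, res.stderr
    ref = np.array([float(v) for v in res.stdout.split()])
    ours = np.r_[m.intercept_, m.coef_]
    assert np.abs(ours - ref).max() < 0.05
    assert ((m.coef_ == 0) == (ref[1:] == 0)).all()


def test_parameter_recovery_large_n_small_lambda():
    """A planted OR of 2.0 is recovered within [1.8, 2.2] at n=50,000."""
    rng = np.random.default_rng(7)
    n = 50000
    X = rng.binomial(1, [0.05, 0.2, 0.1, 0.3, 0.15], (n, 5)).astype(float)
    eta = -2.6 + np.log(2.0) * X[:, 0] + 0.4 * X[:, 1] - 0.3 * X[:, 2]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    m = PenalizedLogisticRegression(fixed_lambda=1e-4).fit(X, y)
    assert 1.8 <= np.exp(m.coef_[0]) <= 2.2
    assert abs(m.coef_[0] - np.log(2.0)) < 0.1


def test_cv_selects_sparse_model_on_pure_noise():
    """With noise-only features >= 90% of coefficients are exactly zero."""
    rng = np.random.default_rng(3)
    n, p = 5000, 100
    X = rng.binomial(1, 0.2, (n, p)).astype(float)
    y = (rng.random(n) < 0.08).astype(int)
    m = PenalizedLogisticRegression(n_lambdas=30, cv=10, random_state=0).fit(X, y)
    assert (m.coef_ == 0).mean() >= 0.9


def test_lambda_path_monotone_nonzero_count():
    """Increasing the penalty never increases the active set along the path."""
    X, y = _logistic_design(n=800)
    m = PenalizedLogisticRegression()
    import scipy.sparse as sp

    Xm = sp.csr_matrix(X)
    Xs, _ = m._scale(Xm)
    grid = np.logspace(np.log10(m._lambda_max(Xs, y)), -4, 12)
    path = m._path_fit(Xs, y, grid)
    counts = [int((c != 0).sum()) for c, _ in path]
    # allow single-feature wobble from solver tolerance; the trend must hold
    assert all(b >= a - 1 for a, b in zip(counts, counts[1:]))
    assert counts[0] <= 1 and counts[-1] >= counts[0]


def test_cv_recovers_planted_coefficients(planted_run):
    """Conditional log-ORs converge to generating values at n=50,000."""
    cfg = planted_run["config"]
    coefs = planted_run["model"].coefficients_
    a, b = cfg.planted_pair
    assert abs(coefs[a] - np.log(cfg.or_a)) < 0.3
    pname = "*".join(sorted((a, b)))
    assert abs(coefs[pname] - np.log(cfg.or_product)) < 0.3
    # a strong comorbidity effect is recovered on the log scale within 0.1
    assert abs(coefs["mh_sepsis"] - cfg.dx_log_odds["sepsis"]) < 0.25


def test_comparator_contracts():
    rng = np.random.default_rng(0)
    n = 200
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    y = (X["a"] > 0).astype(int).to_numpy()  # separable in a
    grids = {"XGB": {"max_depth": [2]}, "RF": {"n_estimators": [50]},
             "SVM-L": {"C": [1.0]}, "SVM-R": {"C": [1.0]}}
    for tag in ("MLR", "RF", "XGB", "SVM-L", "SVM-R"):
        h = fit_comparators(X, y, tag, hyper_grid=grids.get(tag), folds=3, seed=0)
        p = h.predict_proba(X)
        assert p.shape == (n,)
        assert (p >= 0).all() and (p <= 1).all()
    with pytest.raises(ValueError):
        fit_comparators(X, y, "GLM")
    with pytest.raises(ValueError):
        fit_comparators(X, y, "XGB", hyper_grid={})


def test_xgb_separable_training_auroc():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(1)
    X = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
    y = (X["a"] > 0).astype(int).to_numpy()
    h = fit_comparators(X, y, "XGB", hyper_grid={"max_depth": [2]}, folds=3)
    assert roc_auc_score(y, h.predict_proba(X)) == 1.0


def test_rf_ensemble_size_improves_cv_error():
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import cross_val_score

    rng = np.random.default_rng(2)
    X = rng.normal(size=(300, 4))
    y = (X[:, 0] + 0.5 * rng.normal(size=300) > 0).astype(int)
    scores = {}
    for ntree in (1, 200):
        accs = [
            cross_val_score(
                RandomForestClassifier(n_estimators=ntree, random_state=s),
                X, y, cv=3, scoring="accuracy",
            ).mean()
            for s in range(3)
        ]
        scores[ntree] = np.mean(accs)
    assert scores[200] >= scores[1]


def test_predict_schema_mismatch_reported():
    X, y = _logistic_design()
    Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    m = PenalizedLogisticRegression(fixed_lambda=0.01).fit(Xdf, y)
    bad = Xdf.rename(columns={"f0": "other"})
    with pytest.raises(SchemaError, match="missing.*f0"):
        m.predict_proba(bad)
    h = fit_comparators(Xdf, y, "MLR")
    with pytest.raises(SchemaError):
        h.predict_proba(bad)


def test_intercept_only_closed_form():
    """An intercept of log(0.25/0.75) predicts probability 0.25 everywhere."""
    m = PenalizedLogisticRegression(fixed_lambda=1.0)
    m.feature_names_ = ["x0"]
    m.n_features_in_ = 1
    m.coef_ = np.zeros(1)
    m.intercept_ = float(np.log(0.25 / 0.75))
    p = m.predict_proba(np.ones((10, 1)))[:, 1]
    assert np.allclose(p, 0.25)


def test_mlr_agrees_with_llr_signs_on_subproblem():
    """Cross-model sanity: unpenalised fit reproduces lasso signs."""
    X, y = _logistic_design(n=2000)
    Xdf = pd.DataFrame(X[:, :3], columns=["a", "b", "c"])
    llr = PenalizedLogisticRegression(fixed_lambda=1e-3).fit(Xdf, y)
    mlr = fit_comparators(Xdf, y, "MLR")
    mc = mlr.estimator.coef_[0]
    for j, name in enumerate(["a", "b", "c"]):
        lc = llr.coefficients_[name]
        if lc != 0.0:
            assert np.sign(lc) == np.sign(mc[j])
            assert np.isfinite(mc[j])
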