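"""RERI arithmetic, validity rule, percentile bootstrap, SHAP ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import akinteract as ak
from akinteract.interaction import (
    _percentile_ci,
    percentile_bootstrap,
    reri,
    reri_value,
    shap_rank,
    shap_values,
)


def test_reri_published_worked_example():
    """Loop diuretic (2.018) x H2 blocker (1.000), product term 1.639."""
    res = reri(2.018, 1.000, 1.639)
    assert res.valid
    assert res.combined == pytest.approx(3.307, abs=1e-3)
    assert res.reri == pytest.approx(1.289, abs=1e-3)


def test_reri_identity_and_algebraic_null():
    assert reri(1.0, 1.0, 1.0).reri == 0.0
    res = reri(2.0, 3.0, (2.0 + 3.0 - 1.0) / (2.0 * 3.0))
    assert res.reri == pytest.approx(0.0, abs=1e-12)


def test_reri_validity_rule():
    res = reri(0.9, 1.5, 2.0)
    assert not res.valid and res.reri is None
    # an exactly-zero lasso coefficient gives OR 1.000, which passes
    assert reri(1.0, 2.0, 1.5).valid


def test_reri_rejects_nonpositive_inputs():
    with pytest.raises(ValueError):
        reri(0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        reri(2.0, -1.0, 1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=1.0, max_value=5.0),
    b=st.floats(min_value=1.0, max_value=5.0),
)
def test_additive_null_identity_property(a, b):
    """RERI(a, b, (a+b-1)/(ab)) = 0 for all a, b >= 1."""
    assert reri_value(a, b, (a + b - 1.0) / (a * b)) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=1.0, max_value=5.0),
    b=st.floats(min_value=1.0, max_value=5.0),
    p1=st.floats(min_value=0.1, max_value=4.0),
    dp=st.floats(min_value=1e-6, max_value=2.0),
)
def test_reri_strictly_increasing_in_product_or(a, b, p1, dp):
    assert reri_value(a, b, p1 + dp) > reri_value(a, b, p1)


def test_percentile_ci_order_statistics():
    # a permutation of 1..2000 has CI exactly (50, 1950)
    rng = np.random.default_rng(0)
    est = rng.permutation(np.arange(1, 2001)).astype(float)
    assert _percentile_ci(np.sort(est)) == (50.0, 1950.0)


def test_percentile_bootstrap_constant_estimator():
    bd = percentile_bootstrap(np.ones(50) * 3.5, np.mean, B=100, seed=1)
    assert bd.ci == (3.5, 3.5)


def test_percentile_bootstrap_endpoints_are_order_statistics():
    rng = np.random.default_rng(2)
    data = rng.normal(size=120)
    bd = percentile_bootstrap(data, np.mean, B=200, seed=3)
    assert bd.ci[0] in bd.estimates and bd.ci[1] in bd.estimates
    assert bd.ci[0] <= bd.ci[1]
    assert (np.diff(bd.estimates) >= 0).all()


def test_percentile_bootstrap_redraws_failing_resamples():
    calls = {"n": 0}

    def flaky(sample):
        calls["n"] += 1
        if calls["n"] % 5 == 0:
            return float("nan")
        return float(np.mean(sample))

    bd = percentile_bootstrap(np.arange(30, dtype=float), flaky, B=50, seed=4)
    assert bd.n_redrawn > 0
    assert len(bd.estimates) == 50


def test_percentile_bootstrap_reproducible_under_seed():
    data = np.random.default_rng(5).normal(size=80)
    a = percentile_bootstrap(data, np.mean, B=100, seed=9)
    b = percentile_bootstrap(data, np.mean, B=100, seed=9)
    assert (a.estimates == b.estimates).all()


def test_detect_interactions_small_planted_pair():
    """A strong planted product effect is flagged at modest n and B."""
    rng = np.random.default_rng(6)
    n = 6000
    xa = rng.random(n) < 0.15
    xb = rng.random(n) < 0.20
    xc = rng.random(n) < 0.25
    eta = -2.6 + np.log(2.0) * xa + np.log(1.5) * xb + np.log(2.5) * (xa & xb)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(np.int8)
    X = pd.DataFrame(
        {
            "a": xa.astype(np.int8), "b": xb.astype(np.int8), "c": xc.astype(np.int8),
            "a*b": (xa & xb).astype(np.int8), "a*c": (xa & xc).astype(np.int8),
        },
        index=[f"p{i}" for i in range(n)],
    )
    prov = {"a": "drug", "b": "drug", "c": "drug", "a*b": "product", "a*c": "product"}
    fm = ak.FeatureMatrix(X, pd.Series(y, index=X.index), prov)
    model = ak.fit_llr(fm, fixed_lambda=5e-4)
    table = ak.detect_interactions(
        model, fm, pairs=[("a", "b"), ("a", "c")], B=150, seed=0
    )
    planted = table[(table.class_a == "a") & (table.class_b == "b")].iloc[0]
    null = table[(table.class_a == "a") & (table.class_b == "c")].iloc[0]
    assert planted["flagged"]
    assert planted["or_product_lo"] > 1.0
    assert not null["flagged"]
    # combined OR identity holds up to floating tolerance
    assert planted["combined"] == pytest.approx(
        planted["or_a"] * planted["or_b"] * planted["or_product"], rel=1e-12
    )


def test_detect_interactions_skips_absent_pairs(sim_small):
    fm = sim_small["fm"]
    model = ak.fit_llr(fm, fixed_lambda=0.01)
    table = ak.detect_interactions(
        model, fm, pairs=[("no_such_class", "h2_blockers")], B=10, seed=0
    )
    assert len(table) == 0


def test_shap_planted_dominant_feature_ranks_first():
    rng = np.random.default_rng(7)
    n = 1500
    X = pd.DataFrame(
        {
            "dominant": rng.integers(0, 2, n),
            "weak": rng.integers(0, 2, n),
            "noise": rng.integers(0, 2, n),
        }
    ).astype(float)
    eta = -2.0 + np.log(5.0) * X["dominant"] + 0.3 * X["weak"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    h = ak.fit_comparators(X, y, "XGB", hyper_grid={"max_depth": [3]}, folds=3)
    ranking = shap_rank(h, X)
    assert ranking.iloc[0]["feature"] == "dominant"
    assert ranking.iloc[0]["direction"] > 0
    assert (ranking["mean_abs_shap"] >= 0).all()
    assert sorted(ranking["rank"]) == [1, 2, 3]


def test_shap_additivity_and_unused_feature():
    import xgboost as xgb

    rng = np.random.default_rng(8)
    n = 800
    X = pd.DataFrame({"a": rng.integers(0, 2, n), "unused": np.zeros(n)}).astype(float)
    y = ((X["a"] == 1) & (rng.random(n) < 0.8)).astype(int)
    h = ak.fit_comparators(X, y, "XGB", hyper_grid={"max_depth": [2]}, folds=3)
    sv, base = shap_values(h, X)
    dm = xgb.DMatrix(X.to_numpy(), feature_names=list(X.columns))
    margin = h.estimator.get_booster().predict(dm, output_margin=True)
    assert np.abs(sv.sum(axis=1) + base - margin).max() < 1e-5
    ranking = shap_rank(h, X)
    assert ranking.set_index("feature").loc["unused", "mean_abs_shap"] == 0.0


def test_shap_rejects_non_tree_models():
    X = pd.DataFrame({"a": [0.0, 1.0, 0.0, 1.0]})
    y = np.array([0, 1, 0, 1])
    h = ak.fit_comparators(X, y, "MLR")
    with pytest.raises(TypeError):
        shap_rank(h, X)


def test_dual_rule_type_i_control_under_additive_null():
    """With the product OR at the additive-null value the planted pair is
    essentially never flagged (dual-rule false-positive control)."""
    flags = 0
    reps = 10
    for r in range(reps):
        cfg = ak.SimulationConfig(
            n_patients=6000, seed=100 + r,
            or_a=2.018, or_b=1.0,
            or_product=(2.018 + 1.0 - 1.0) / 2.018,  # implied RERI = 0
        )
        tables = ak.simulate(cfg)
        cohort, _ = ak.KdigoPhenotyper().run(
            tables["labs"], tables["patients"], tables["diagnoses"]
        )
        fm = ak.ExposureFeaturizer(drop_empty=False).transform(
            cohort, tables["drugs"], tables["patients"], tables["diagnoses"]
        )
        model = ak.fit_llr(fm, fixed_lambda=1e-3)
        table = ak.detect_interactions(
            model, fm, pairs=[cfg.planted_pair], B=100, seed=r
        )
        if len(table):
            flags += int(table["flagged"].iloc[0])
    assert flags / reps <= 0.10


def test_sensitivity_reruns_windows(sim_small):
    t = sim_small["tables"]
    res = ak.sensitivity_reruns(
        sim_small["cohort"], t["drugs"], t["patients"], t["diagnoses"],
        windows=("1-7", "1-14", "1-30"),
        pairs=[("loop_diuretics", "h2_blockers")],
        B=30, seed=0,
        llr_kwargs={"fixed_lambda": 1e-3},
    )
    assert {"1-7", "1-14", "1-30"} <= set(res)
    aligned = res["aligned"]
    assert set(aligned["window"]) == {"1-7", "1-14", "1-30"}
    # exposure prevalence is non-decreasing as the window widens
    for cls in ("loop_diuretics", "h2_blockers", "nsaids"):
        prevs = [res[w]["exposure_prevalence"][cls] for w in ("1-7", "1-14", "1-30")]
        assert prevs[0] <= prevs[1] <= prevs[2]
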