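"""End-to-end orchestration: simulate -> phenotype -> features -> fit ->
evaluate -> interactions, with per-stage seeds, timings and a run manifest.

One global seed fans out to per-stage seeds through a fixed counter scheme
(``SeedSequence([seed, stage_index])``), so any stage can be re-run in
isolation and reproduce its output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, interaction, synthetic
from .features import ExposureFeaturizer, ExposureWindow
from .models import SplitSpec, fit_comparators, fit_llr, split_dataset
from .phenotyping import KdigoPhenotyper

STAGES = ("simulate", "phenotype", "features", "fit", "evaluate", "interactions")

DEFAULT_CONFIG: dict = {
    "n_patients": 5000,
    "seed": 0,
    "simulate": {},  # overrides for SimulationConfig fields
    "features": {"window": "1-7", "washout_days": 180},
    "split": {"train_fraction": 0.8},
    "models": {"tags": ["LLR", "XGB"], "n_lambdas": 30, "folds": 10},
    "interactions": {"bootstrap_B": 200, "max_pairs": 25},
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    """Merge a YAML file or dict over the documented defaults."""
    import yaml

    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if key in cfg and isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            cfg[key].update(val)
        else:
            cfg[key] = val
    missing = [k for k in ("n_patients", "seed") if cfg.get(k) is None]
    if missing:
        raise ConfigError(f"missing config keys: {missing}")
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage child seed (< 2^31) from the global seed."""
    k = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    timings: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    version: str = "0.1.0"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config, outdir: str, seed: int | None = None) -> RunManifest:
    """Execute every stage, writing tables, metrics and the manifest to ``outdir``."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    os.makedirs(outdir, exist_ok=True)
    cfg_text = json.dumps(cfg, sort_keys=True)
    seeds = {s: stage_seed(cfg["seed"], s) for s in STAGES}
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(), seeds=seeds
    )
    outputs: dict[str, str] = {}

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - stage-tagged abort
                raise StageError(name, exc) from exc
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            return result

        return deco

    def _write(df: pd.DataFrame, name: str):
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False)
        outputs[name] = path

    # simulate ----------------------------------------------------------
    def do_simulate():
        sim_cfg = synthetic.SimulationConfig(
            n_patients=int(cfg["n_patients"]), seed=seeds["simulate"], **cfg["simulate"]
        )
        tables = synthetic.simulate(sim_cfg)
        for name, df in tables.items():
            _write(df, f"{name}.csv")
        return tables

    tables = _stage("simulate")(do_simulate)

    # phenotype ---------------------------------------------------------
    def do_phenotype():
        cohort, ledger = KdigoPhenotyper().run(
            tables["labs"], tables["patients"], tables["diagnoses"]
        )
        _write(cohort, "cohort.csv")
        path = os.path.join(outdir, "flow_ledger.json")
        with open(path, "w") as fh:
            json.dump(ledger, fh, indent=1)
        outputs["flow_ledger.json"] = path
        return cohort

    cohort = _stage("phenotype")(do_phenotype)

    # features ----------------------------------------------------------
    def do_features():
        window = ExposureWindow.parse(cfg["features"]["window"])
        fz = ExposureFeaturizer(
            window=window, washout_days=int(cfg["features"]["washout_days"])
        )
        fm = fz.transform(cohort, tables["drugs"], tables["patients"], tables["diagnoses"])
        prefix = os.path.join(outdir, f"features_w{window.label}")
        fm.write(prefix)
        outputs[f"features_w{window.label}.csv"] = f"{prefix}.csv"
        return fm

    fm = _stage("features")(do_features)

    # fit ---------------------------------------------------------------
    def do_fit():
        train, test = split_dataset(
            fm, SplitSpec(float(cfg["split"]["train_fraction"]), seeds["fit"])
        )
        fitted = {}
        mcfg = cfg["models"]
        for tag in mcfg["tags"]:
            if tag == "LLR":
                model = fit_llr(
                    train,
                    n_lambdas=int(mcfg.get("n_lambdas", 30)),
                    cv=int(mcfg.get("folds", 10)),
                    random_state=seeds["fit"],
                )
                cs = model.coefficient_set()
                path = os.path.join(outdir, "model_llr.json")
                with open(path, "w") as fh:
                    json.dump(
                        {"intercept": cs.intercept, "lambda": cs.lam,
                         "coefficients": cs.nonzero()},
                        fh, indent=1, sort_keys=True,
                    )
                outputs["model_llr.json"] = path
                fitted["LLR"] = model
            else:
                handle = fit_comparators(
                    train.X, train.y.to_numpy(), tag,
                    folds=int(mcfg.get("folds", 10)), seed=seeds["fit"],
                )
                if tag == "XGB":
                    path = os.path.join(outdir, "model_xgb.json")
                    handle.estimator.get_booster().save_model(path)
                    outputs["model_xgb.json"] = path
                fitted[tag] = handle
        return train, test, fitted

    train, test, fitted = _stage("fit")(do_fit)

    # evaluate ----------------------------------------------------------
    def do_evaluate():
        window = ExposureWindow.parse(cfg["features"]["window"])
        report = {}
        for tag, model in fitted.items():
            est = model if tag == "LLR" else model
            p_test = (
                est.predict_proba(test.X)[:, 1]
                if tag == "LLR"
                else model.predict_proba(test.X)
            )
            p_train = (
                est.predict_proba(train.X)[:, 1]
                if tag == "LLR"
                else model.predict_proba(train.X)
            )
            y_te = test.y.to_numpy()
            auroc, auroc_ci = evaluation.auroc_with_ci(y_te, p_test)
            aupr, aupr_ci = evaluation.aupr_with_ci(
                y_te, p_test, n_boot=200, seed=seeds["evaluate"]
            )
            brier, brier_ci = evaluation.brier_score(
                y_te, p_test, n_boot=200, seed=seeds["evaluate"]
            )
            try:
                cal = evaluation.calibration_slope_intercept(y_te, p_test)
            except ValueError as exc:  # e.g. an intercept-only model
                cal = {"error": str(exc)}
            cls = evaluation.classification_metrics(
                y_te, p_test, "youden", train_preds=(train.y.to_numpy(), p_train)
            )
            report[tag] = {
                "window": window.label,
                "auroc": auroc, "auroc_ci": auroc_ci,
                "aupr": aupr, "aupr_ci": aupr_ci,
                "brier": brier, "brier_ci": brier_ci,
                "calibration": cal, "classification": cls,
            }
        path = os.path.join(outdir, f"metrics_w{window.label}.json")
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        outputs[os.path.basename(path)] = path
        return report

    _stage("evaluate")(do_evaluate)

    # interactions ------------------------------------------------------
    def do_interactions():
        window = ExposureWindow.parse(cfg["features"]["window"])
        icfg = cfg["interactions"]
        llr = fitted.get("LLR")
        if llr is None:
            return None
        pairs = None
        max_pairs = icfg.get("max_pairs")
        if max_pairs is not None:
            cand = [
                tuple(c.split("*"))
                for c, k in train.provenance.items()
                if k == "product" and llr.coefficients_.get(c, 0.0) != 0.0
            ]
            pairs = cand[: int(max_pairs)] or None
        table = interaction.detect_interactions(
            llr, train, pairs=pairs, B=int(icfg["bootstrap_B"]), seed=seeds["interactions"]
        )
        _write(table, f"interactions_w{window.label}.csv")
        if "XGB" in fitted:
            ranking = interaction.shap_rank(fitted["XGB"], train.X)
            _write(ranking, f"shap_w{window.label}.csv")
        return table

    _stage("interactions")(do_interactions)

    for name, path in sorted(outputs.items()):
        manifest.checksums[name] = _sha256(path)
    manifest.write(os.path.join(outdir, "manifest.json"))
    return manifest
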