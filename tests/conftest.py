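"""Shared fixtures: synthetic cohorts at two scales.

``sim_small`` is a quick cohort for unit-level checks; ``planted_run`` is
the full-scale planted-interaction study (50,000 patients, CV-tuned lasso,
B=500 bootstrap) shared by the parameter-recovery and interaction tests so
the expensive pipeline is executed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

import akinteract as ak


@pytest.fixture(scope="session")
def sim_small():
    """n=8,000 synthetic study: tables, cohort, flow ledger, feature matrix."""
    cfg = ak.SimulationConfig(n_patients=8000, seed=2)
    tables = ak.simulate(cfg)
    cohort, ledger = ak.KdigoPhenotyper().run(
        tables["labs"], tables["patients"], tables["diagnoses"]
    )
    fm = ak.ExposureFeaturizer().transform(
        cohort, tables["drugs"], tables["patients"], tables["diagnoses"]
    )
    return {"config": cfg, "tables": tables, "cohort": cohort, "ledger": ledger, "fm": fm}


@pytest.fixture(scope="session")
def planted_run():
    """Full-scale planted-interaction study used by the recovery checks.

    Generates 50,000 patients with the planted loop-diuretic x H2-blocker
    interaction (or_a=2.018, or_b=1.000, or_product=1.639), phenotypes and
    featurizes them, fits the CV-tuned lasso, and runs the bootstrap
    interaction detector on the planted pair plus 20 null pairs at B=500.
    """
    cfg = ak.SimulationConfig(n_patients=50000, seed=11)
    tables = ak.simulate(cfg)
    cohort, ledger = ak.KdigoPhenotyper().run(
        tables["labs"], tables["patients"], tables["diagnoses"]
    )
    fm = ak.ExposureFeaturizer().transform(
        cohort, tables["drugs"], tables["patients"], tables["diagnoses"]
    )
    model = ak.fit_llr(fm, n_lambdas=40, cv=10, random_state=1)
    planted = cfg.planted_pair
    planted_col = "*".join(sorted(planted))
    null_products = [
        c for c, k in fm.provenance.items() if k == "product" and c != planted_col
    ]
    rng = np.random.default_rng(5)
    null_pairs = [
        tuple(c.split("*")) for c in rng.choice(null_products, 20, replace=False)
    ]
    table = ak.detect_interactions(
        model, fm, pairs=[planted] + null_pairs, B=500, seed=3
    )
    return {
        "config": cfg,
        "tables": tables,
        "cohort": cohort,
        "ledger": ledger,
        "fm": fm,
        "model": model,
        "interactions": table,
        "null_pairs": null_pairs,
    }
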