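"""Default drug-class taxonomy, comorbidity list and ICD-10 code maps.

The 32 therapeutic drug classes are the nephrotoxicity-relevant ATC-level
buckets commonly screened in AKI pharmacovigilance work (antibiotics,
antihypertensives including diuretics, antineoplastics, immunosuppressants,
acid-suppressing drugs, lipid-lowering drugs, NSAIDs and a few others).
The per-class "use" prevalences (fraction of patients with a new start
inside the exposure window, separately for AKI cases and controls) are the
study conditions the synthetic generator emulates.

All code lists are configurable; the constants here are documented defaults.
"""

from __future__ import annotations

#: 32 therapeutic drug classes, in display order.
DRUG_CLASSES: tuple[str, ...] = (
    "penicillins",
    "cephalosporins",
    "carbapenems",
    "aminoglycosides",
    "glycopeptides",
    "tetracyclines",
    "fluoroquinolones",
    "macrolides",
    "smx_tmp",
    "azoles",
    "amphotericin_b",
    "antiherpes_nucleosides",
    "interferons",
    "calcium_channel_blockers",
    "ace_inhibitors",
    "arbs",
    "alpha_blockers",
    "beta_blockers",
    "loop_diuretics",
    "aldosterone_antagonists",
    "other_diuretics",
    "folate_antimetabolites",
    "platinum_agents",
    "calcineurin_inhibitors",
    "sulfhydryl_dmards",
    "h2_blockers",
    "proton_pump_inhibitors",
    "statins",
    "fibrates",
    "nsaids",
    "sglt2_inhibitors",
    "vitamin_d3",
)

#: Exposure prevalence (fraction with a new start in the window) by class,
#: as (case, control).  These marginals drive the conditional draws for
#: non-planted classes in the synthetic generator.
DRUG_START_PROBS: dict[str, tuple[float, float]] = {
    "penicillins": (0.087, 0.045),
    "cephalosporins": (0.094, 0.135),
    "carbapenems": (0.030, 0.006),
    "aminoglycosides": (0.007, 0.001),
    "glycopeptides": (0.043, 0.001),
    "tetracyclines": (0.002, 0.001),
    "fluoroquinolones": (0.020, 0.014),
    "macrolides": (0.018, 0.010),
    "smx_tmp": (0.011, 0.002),
    "azoles": (0.004, 0.0005),
    "amphotericin_b": (0.003, 0.0002),
    "antiherpes_nucleosides": (0.004, 0.003),
    "interferons": (0.001, 0.0005),
    "calcium_channel_blockers": (0.093, 0.077),
    "ace_inhibitors": (0.042, 0.036),
    "arbs": (0.020, 0.009),
    "alpha_blockers": (0.007, 0.003),
    "beta_blockers": (0.020, 0.010),
    "loop_diuretics": (0.097, 0.019),
    "aldosterone_antagonists": (0.046, 0.011),
    "other_diuretics": (0.005, 0.005),
    "folate_antimetabolites": (0.003, 0.0002),
    "platinum_agents": (0.025, 0.002),
    "calcineurin_inhibitors": (0.002, 0.0004),
    "sulfhydryl_dmards": (0.0002, 0.0004),
    "h2_blockers": (0.120, 0.122),
    "proton_pump_inhibitors": (0.128, 0.073),
    "statins": (0.027, 0.033),
    "fibrates": (0.002, 0.003),
    "nsaids": (0.133, 0.157),
    "sglt2_inhibitors": (0.001, 0.001),
    "vitamin_d3": (0.0004, 0.002),
}

#: Hospital site labels and their patient shares.
HOSPITALS: tuple[str, ...] = ("itabashi", "hikarigaoka", "surugadai")
HOSPITAL_PROBS: tuple[float, ...] = (0.729, 0.117, 0.154)

#: Seven comorbidities used as medical-history covariates.
HISTORY_CONDITIONS: tuple[str, ...] = (
    "hypertension",
    "diabetes",
    "heart_failure",
    "anemia",
    "sepsis",
    "chronic_kidney_disease",
    "chronic_liver_disease",
)

#: Overall prevalence of a pre-baseline diagnosis per condition
#: (case/control-weighted population marginal).
HISTORY_PREVALENCE: dict[str, float] = {
    "hypertension": 0.152,
    "diabetes": 0.238,
    "heart_failure": 0.090,
    "anemia": 0.100,
    "sepsis": 0.026,
    "chronic_kidney_disease": 0.005,
    "chronic_liver_disease": 0.011,
}

#: Default conditional log-odds of AKI per comorbidity (generator outcome
#: model); magnitudes are the case/control odds ratios implied by the
#: emulated prevalences.
HISTORY_LOG_ODDS: dict[str, float] = {
    "hypertension": 0.747,
    "diabetes": 0.355,
    "heart_failure": 1.075,
    "anemia": 0.415,
    "sepsis": 1.978,
    "chronic_kidney_disease": 1.264,
    "chronic_liver_disease": 0.703,
}

#: Default condition -> ICD-10 code set map for history encoding.
DEFAULT_ICD10_MAP: dict[str, tuple[str, ...]] = {
    "hypertension": ("I10",),
    "diabetes": ("E11", "E14"),
    "heart_failure": ("I50",),
    "anemia": ("D64",),
    "sepsis": ("A41",),
    "chronic_kidney_disease": ("N18.1", "N18.2"),
    "chronic_liver_disease": ("K76",),
}

#: Default pre-existing kidney-disease exclusion list: CKD stage >= 3,
#: diabetic nephropathy, unspecified kidney failure.
DEFAULT_EXCLUDED_CODES: tuple[str, ...] = (
    "N18.3",
    "N18.4",
    "N18.5",
    "E11.2",
    "N19",
)
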