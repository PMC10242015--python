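# akinteract

Detection of drug–drug interactions that raise the risk of acute kidney
injury (AKI), for pharmacoepidemiologists working with longitudinal
electronic-health-record tables. The package implements a complete
case-control pipeline — KDIGO-based phenotyping of serum-creatinine series,
exposure-window feature engineering with pairwise product terms, a
cross-validated lasso logistic core plus a comparator model suite, a full
evaluation-metric battery, and additive-scale interaction inference — and
ships a synthetic-EHR generator with planted ground truth so every stage is
testable without access to protected health data.

## The statistic at the core

For a drug pair with fitted log-odds coefficients β̂₁ (class A), β̂₂
(class B) and β̂₃ (their product term), the **relative excess risk due to
interaction** is

```
RERI = e^(β̂₁+β̂₂+β̂₃) − e^(β̂₁) − e^(β̂₂) + 1
```

RERI = 0 means no interaction on the additive scale; RERI is invalid when
either individual adjusted odds ratio is below 1. Because the lasso
(glmnet-style objective `(1/n)·NLL + λ‖β‖₁`, λ tuned by stratified 10-fold
cross-validation) gives no standard errors, 95% CIs come from a percentile
bootstrap: 2,000 resamples of the training set refit at the tuned λ, CI =
the 50th and 1,950th order statistics. A pair is reported as a positive
interaction only under the dual rule: lower limit of the product-term OR CI
> 1 **and** lower limit of the RERI CI > 0. The gradient-boosted tree
comparator is interpreted via mean-|SHAP| feature ranking (tree-path-
dependent TreeSHAP).

## Worked example

```python
import akinteract as ak

cfg = ak.SimulationConfig(n_patients=50000, seed=11)   # planted pair:
tables = ak.simulate(cfg)                              # loop diuretics (OR 2.018)
cohort, ledger = ak.KdigoPhenotyper().run(             # x H2 blockers (OR 1.000),
    tables["labs"], tables["patients"], tables["diagnoses"]
)                                                      # product-term OR 1.639
fm = ak.ExposureFeaturizer().transform(
    cohort, tables["drugs"], tables["patients"], tables["diagnoses"]
)
model = ak.fit_llr(fm, n_lambdas=40, cv=10, random_state=1)
table = ak.detect_interactions(model, fm, pairs=[cfg.planted_pair], B=500, seed=3)
print(table[["or_a", "or_b", "or_product", "reri", "or_product_lo",
             "reri_lo", "flagged"]].round(3).to_string(index=False))
```

prints (about two minutes on one CPU):

```
 or_a  or_b  or_product  reri  or_product_lo  reri_lo  flagged
 1.76 1.022       1.627 1.145          1.045    0.126     True
```

Reading: the adjusted OR for loop diuretics alone is 1.76, for H2 blockers
alone 1.02, and the product term 1.63 with a bootstrap CI excluding 1; the
estimated RERI of 1.15 (CI lower limit 0.13 > 0) recovers the interaction
planted by the generator (implied true RERI
`2.018·1.000·1.639 − 2.018 − 1.000 + 1 = 1.2895`), so the pair is flagged.

The same flow is available from a shell:

```bash
akinteract simulate --n 20000 --seed 7 --outdir run/
akinteract phenotype --indir run/ --outdir run/
akinteract features  --indir run/ --outdir run/ --window 1-7
akinteract run-all   --outdir run/ --seed 7          # everything + manifest
```

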