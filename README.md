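# nephrisk

Kidney-failure risk prediction for chronic kidney disease (CKD) cohorts,
built around a naive Bayes classifier that stays computable under
arbitrary missing data.

## The problem

Stage 3–5 CKD patients face a material risk of progressing to kidney
failure and needing kidney replacement therapy (KRT: dialysis or
transplant). Timely referral — vascular-access creation, transition
management, intensified prevention programs — depends on accurate
short- (6-month) and long-horizon (24-month) risk estimates. The
established equation-based benchmarks (the Kidney Failure Risk
Equations, KFRE) are complete-case scores: in real-world registries
where key labs such as the urine albumin-to-creatinine ratio (ACR) are
missing for most patients, they simply cannot be computed. `nephrisk`
implements the alternative: a naive Bayes risk engine whose posterior

```
P(Y=1 | e) = P(Y=1) ∏ᵢ P(eᵢ | Y=1) / Σ_y P(Y=y) ∏ᵢ P(eᵢ | Y=y)
```

takes the product over *observed* evidence only — missing predictors
marginalize out exactly — so every patient gets a risk, from a fully
documented record down to an empty one (which falls back to the prior).
Each prediction carries two explanation metrics:

* **VOI** (value of information) for each missing variable: the expected
  reduction in outcome entropy, `H(Y|e) − Σₓ P(x|e) H(Y|e,x)` in bits —
  the conditional mutual information `I(Y; X | e)` — ranking which
  unmeasured labs would sharpen the prognosis most;
* **NL** (normalized likelihood) for each observed variable:
  `P(eᵢ|Y=1)/P(eᵢ)`, the single-variable posterior lift; NL > 1 marks
  risk-increasing evidence.

Around the engine sit the pieces a validation study needs: CKD-EPI
(2009) eGFR estimation and KDIGO G-staging, ascertainment-window
feature engineering (12-month lab averaging, OLS eGFR slope), endpoint
assembly, a configurable KFRE implementation with computability
accounting, ROC AUC with DeLong variance, paired DeLong comparison
under a fixed-sequence non-inferiority (margin 0.05) → superiority
procedure, quintile calibration, Youden-index cutoffs, exact Poisson
incidence intervals, and a referral-impact simulator reporting events
prevented and the number needed to treat,
`NNT = 1 / (PPV · (1 − 1/effect_size))`.

Because real nephrology registry data cannot be shared, the package
includes a synthetic cohort generator reproducing the statistical
shape of such cohorts (stage mixture, lab marginals, per-variable
missingness, horizon-specific event rates), so the whole pipeline is
testable end to end.

## Worked example

```sh
python examples/01_predict_with_missing_data.py
```

trains a 24-month model on a synthetic registry-like cohort and scores
four patients:

```
trained on 1679 records; prior 24-month KRT risk 0.189

rich record, advanced CKD      risk = 0.791
rich record, stable stage 3    risk = 0.005
sparse record (eGFR only)      risk = 0.598
empty record                   risk = 0.189
```

An eGFR of 14 alone puts the posterior at 0.60; adding a fast eGFR
decline, anemia and diabetes raises it to 0.79; a stable stage-3
patient sits near zero; and the empty record returns the cohort prior —
no record is ever "not computable". The other examples cover the
explanation metrics (`02`), the KFRE computability gap and paired
DeLong comparison (`03`), validation statistics (`04`), the
referral-impact simulation (`05`) and simulated expert-panel agreement
(`06`). A thin CLI wraps the same workflows
(`nephrisk synth|train|predict|explain|validate|compare|simulate-impact`).

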