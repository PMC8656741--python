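"""Train a 24-month KRT risk model on a synthetic cohort and score
patients with very different amounts of recorded information.

The naive-Bayes engine marginalizes missing predictors exactly, so a
risk is produced for every patient -- a fully empty record simply falls
back to the cohort prior.
"""

import pandas as pd

from nephrisk import fit_nbc, registry_like_config, generate_cohort, predict, specs_for_horizon

train = generate_cohort(registry_like_config(n=4000, seed=11), horizons=(24,))
train = train[train["event_24m"].notna()]
model = fit_nbc(train, "event_24m", specs_for_horizon(24), horizon_months=24)
print(f"trained on {len(train)} records; prior 24-month KRT risk {model.prior:.3f}\n")

patients = {
    "rich record, advanced CKD": {
        "age": 68, "sex": "male", "egfr": 14.0, "egfr_slope": -6.0,
        "hemoglobin": 9.8, "phosphate": 5.1, "albumin": 3.4,
        "etiology_diabetes": 1,
    },
    "rich record, stable stage 3": {
        "age": 75, "sex": "female", "egfr": 52.0, "egfr_slope": -0.5,
        "hemoglobin": 13.5, "phosphate": 3.2, "albumin": 4.3,
        "etiology_diabetes": 0,
    },
    "sparse record (eGFR only)": {"egfr": 14.0},
    "empty record": {},
}

for label, record in patients.items():
    pred = predict(model, record)
    print(f"{label:30s} risk = {pred.risk:.3f}")
print(
    "\nRisk is P(KRT within 24 months | observed evidence); with no evidence"
    f" it equals the training prior {model.prior:.3f}."
)
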