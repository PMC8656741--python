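"""Benchmark the naive-Bayes model against a KFRE-style equation on a
registry-like synthetic cohort: computability under real-world
missingness, and a paired DeLong comparison on the complete cases.

The bundled KFRE coefficients are a SYNTHETIC placeholder (the
functional form is real, the numbers are not published values).
"""

import numpy as np

from nephrisk import (
    computability,
    delong_compare,
    fit_nbc,
    registry_like_config,
    generate_cohort,
    kfre_risk_frame,
    score_frame,
    specs_for_horizon,
    synthetic_placeholder_coefficients,
)

train = generate_cohort(registry_like_config(n=4000, seed=11), horizons=(24,))
train = train[train["event_24m"].notna()]
model = fit_nbc(train, "event_24m", specs_for_horizon(24), horizon_months=24)

test = generate_cohort(registry_like_config(n=4000, seed=12), horizons=(24,))
test = test[test["event_24m"].notna()].rename(columns={"etiology_diabetes": "diabetes"})

coeffs = synthetic_placeholder_coefficients()["4VAR"]
report = computability(test, {"nbc": [], "kfre_4var": list(coeffs.required)})
print("registry-like cohort (heavy lab missingness):")
for score, share in report.share_computable.items():
    print(f"  {score:10s} computable for {share:6.1%} of {report.n_total} records")

# a paired accuracy comparison needs complete cases, which only an
# ACR-rich study-style cohort provides in numbers
from nephrisk import study_like_config

test = generate_cohort(study_like_config(n=4000, seed=12), horizons=(24,))
test = test[test["event_24m"].notna()].rename(columns={"etiology_diabetes": "diabetes"})
kfre_scores = kfre_risk_frame(coeffs, test)
complete = kfre_scores.notna().to_numpy()
labels = test["event_24m"].astype(int).to_numpy()[complete]
if 0 < labels.sum() < len(labels):
    nbc_scores = score_frame(model, test[complete])
    r = delong_compare(nbc_scores, kfre_scores.to_numpy()[complete], labels)
    print(
        f"\ncomplete cases only (n={complete.sum()}): "
        f"AUC nbc {r.auc_candidate:.3f} vs kfre {r.auc_comparator:.3f}, "
        f"delta {r.delta:+.3f}, p {r.p_value:.3f} -> {r.verdict}"
    )
else:
    print("\ntoo few complete-case events for a paired comparison")
print(
    "\nThe equation-based score exists only for complete cases; the"
    " naive-Bayes risk exists for every record."
)
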