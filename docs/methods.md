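# Methods

## The risk model

`nephrisk` models KRT initiation within a fixed horizon (6 or 24
months) as a binary outcome Y and predicts it with a naive Bayes
classifier: a star-topology Bayesian network in which every predictor
X_i is conditionally independent of the others given Y. Training
estimates the outcome prior P(Y=1) as the event fraction and one
conditional probability table (CPT) per predictor,

    P(X_i = level | Y = y) = (count(level, y) + α) / (count(y) + α·L),

with Laplace smoothing α = 1 pseudo-count per cell (L = number of
levels), so every probability is strictly positive and log-space
scoring never underflows. Rows with a missing X_i contribute to
neither numerator nor denominator for that variable (available-case
counting, no imputation); at scoring time missing evidence drops out
of the likelihood product, which is the exact marginalization under
the conditional-independence assumption. Both choices together make
the model trainable and computable under arbitrary missingness, which
is its reason to exist next to complete-case risk equations.

Continuous predictors are discretized into equal-frequency bins
(default 5) with edges at training quantiles and unbounded outer bins.
Equal-frequency binning was chosen over equal-width because lab
distributions (ferritin, PTH, ACR) are heavily skewed; the bin count
trades resolution against CPT estimation noise and 5 is a conventional
middle ground. The two horizons use the registry-style predictor sets
of 28 (6-month) and 34 (24-month) variables listed in
`nephrisk.variables`.

Explanation metrics:

* **Value of information** for a missing variable X:
  VOI = H(Y|e) − Σ_x P(x|e) H(Y|e, X=x) with
  P(x|e) = Σ_y P(x|y) P(y|e), i.e. the conditional mutual information
  I(Y; X | e) under the model; base-2 logarithm (bits). The base is
  configurable on the model (`log_base`).
* **Normalized likelihood** for an observed variable:
  NL = P(e_i|Y=1)/P(e_i) with P(e_i) evaluated against the prior, so
  NL equals the single-variable posterior lift P(Y=1|e_i)/P(Y=1).
  Other impact definitions exist; this one is isolated behind
  `normalized_likelihood` so an alternative can be swapped without
  touching the prediction bundle. Ranking ties are broken
  lexicographically by variable name for determinism.

## Cohort model and features

eGFR comes from the 2009 CKD-EPI creatinine equation; its coefficients
are data (`GfrEquationParams`), defaulted to the published values with
the ancestry multiplier fixed at 1, so recalibrated equations can be
injected. KDIGO stages use half-open bands [0,15), [15,30), [30,45),
[45,60), [60,90), [90,∞) — the printed integer ranges ("45–59") are
read as real intervals so every non-negative eGFR is classifiable.

Blood biomarkers are averaged over the 12 months before the index
visit; the window is (index − 12 mo, index], inclusive of index-day
labs. The eGFR slope is the OLS slope of eGFR on time in years over
the same window, requiring ≥ 2 points (with exactly 2 it is the
secant). A protein-creatinine ratio converts to ACR by a
multiplicative factor, default 0.6; a richer 24-h-proteinuria
conversion table can be injected but is disabled by default. Endpoint
assembly classifies each history as event / event-free /
excluded-death / lost-to-follow-up; acute, transient dialysis episodes
are not events, deaths before both KRT and horizon end exclude the
patient, and a patient with no creatinine assessment after the horizon
end and no dialysis-dependence note is lost to follow-up.

## Benchmark equation and computability

The KFRE benchmark implements risk = 1 − S0^exp(Σ β_j (x_j − x̄_j))
with 4- and 6-variable predictor sets and transforms/unit conversions
declared in a coefficient document. The package deliberately ships only
a *synthetic placeholder* coefficient set (plausible signs and rough
magnitudes; the file and loader say so) because the published
coefficients are not included here; users benchmarking against the real
equations supply them in the same format. The 8-variable variant is
omitted (it needs serum bicarbonate, which the predictor registry does
not carry). `computability` counts complete cases per score; the naive
Bayes score is computable for every record by construction.

## Validation statistics

AUC uses the Mann–Whitney estimator (ties count ½) with DeLong
placement-value variance for confidence intervals. Paired comparisons
use the DeLong covariance of the two placements; the contrast is
delta = AUC(candidate) − AUC(comparator). The fixed-sequence procedure
first tests non-inferiority — the one-sided 95% lower bound of delta
must stay above −0.05 (the margin is published practice; the
confidence level is our choice of the conventional 95%) — and only
then superiority (delta ≥ 0.05 with two-sided p < 0.05), which keeps
the type-I error without multiplicity adjustment. When only a
published (delta, p) summary is available, `verdict_from_summary`
applies the same logic on the point estimate. Degenerate identical
scores yield delta 0, p 1, verdict non-inferior.

Calibration charts partition the scored cohort into score quintiles
with boundaries at order statistics (sizes differ by ≤ 1; tied scores
stay in one bin, so heavy ties can distort fifths — documented
behaviour). Youden cutoffs scan observed score values with the rule
`score > cutoff`, ties toward the lower cutoff. Incidence densities
use the exact Poisson CI via the chi-square quantile relation. An AUC
above 0.70 is surfaced as an `acceptable` flag, the conventional bar.

## Referral-impact simulation

All impact arithmetic is on expectations: referred patients carry an
event probability equal to the operating point's PPV, non-referred the
FOR, and the intervention divides referred risk by the effect size.
Reported integers (events prevented, NNT) use nearest-integer
rounding; raw values are retained. The referral count is an input, not
derived from PPV/FOR/baseline — published operating points are rounded
and rarely solve the accounting identity exactly, so the simulator
warns (never errors) when the implied baseline deviates by more than
2%. The overall program effect size is baseline events divided by
total expected events under the policy. The all-in comparator refers
everyone, equivalent to a referral at PPV = baseline/n.

## Synthetic cohort generator

The generator emulates the *statistical shape* of two cohort
archetypes: a late-stage real-world registry (stage mixture
53.1/35.6/11.3% across stages 3/4/5, mean eGFR 31.93, 24-month event
rate 19.32%, 6-month 4.33%, heavy lab missingness — e.g. ACR missing
in 99.6% of records, PTH 58%) and an earlier-stage prospective study
cohort (88.5% stage 3, mean eGFR 41.92, event rates 0.28%/2.17%, ACR
nearly complete). Stage mixture, marginal means/SDs, missingness rates
and event rates are transcribed from published descriptive tables of
such cohorts; the printed 24-h proteinuria SD (150 g/24 h against a
mean of 3.6) is physically impossible and was replaced by 5 g/24 h.

Design choices worth knowing:

* **Stage-first eGFR sampling.** A single truncated normal cannot
  match both the published stage mixture and the published overall
  eGFR mean. The generator samples the stage from the mixture, then
  eGFR from a parent normal truncated to the stage band, with the
  parent location re-solved by root-finding so the mixture mean equals
  the target. Both the mixture (±0.01) and the mean (±0.5) then hold.
* **Dependence structure.** Cross-variable dependence is induced only
  through eGFR: selected labs (hemoglobin, phosphate, calcium, PTH)
  shift their means linearly with standardized eGFR. The true
  covariance of real cohorts is unpublished; this is a modeling
  choice, recorded in the frame's metadata.
* **Outcome model.** Events are Bernoulli draws from a logistic model
  on standardized eGFR (−2.4), eGFR slope (−0.9), log-ACR (+0.55),
  diabetes etiology (+0.35) and age (+0.3), with the intercept
  calibrated per horizon by bisection against the mean predicted rate
  on a fixed-seed 50,000-draw sample (tolerance well below 0.002; with
  zero weights the intercept is exactly logit(target)). The weights
  were set so a fitted model's holdout discrimination lands where such
  models perform on real validation data (AUC ≈ 0.85 at 24 months,
  ≈ 0.90 at 6 months). A shared uniform draw nests events across
  horizons.
* **Missingness** is applied after outcome generation (outcomes are
  never missing), MCAR by default; a MAR-on-stage mechanism shifts
  per-variable missingness odds by stage. Loss to follow-up is
  independent thinning (defaults 17.9% at 6 months, 58.3% at 24
  months for the registry preset), setting the outcome to missing.
* **Expert ratings** use a Gaussian copula on risk ranks mapped to ten
  equal-probability levels, with the mixing weight adjusted by a short
  fixed-point iteration so the achieved Pearson correlation matches
  the target (±0.05 at n ≥ 500); |target| = 1 bypasses the noise
  entirely and is exactly monotone.

What passing tests on synthetic data do and do not show: they verify
the engine's probability arithmetic, the missingness robustness, the
estimator implementations and the end-to-end plumbing under realistic
marginals and missingness; they do not validate clinical performance
on real patients, where dependence structures, coding practices and
ascertainment differ. One concrete artifact: the synthetic outcome is
exactly logistic in (eGFR, slope, log-ACR, diabetes, age), so an
equation-based score over those variables is near-optimal on synthetic
complete cases and can out-discriminate the naive Bayes model there —
a property of the generator, not a clinical finding.

## Numerical notes and degenerate inputs

Posterior computation runs in log space; VOI clamps tiny negative
floating-point residues to 0. Equal-frequency edges are deduplicated;
variables without at least two distinct observed values are flagged
unusable and dropped. `confusion_metrics` returns NaN (not an
exception) for zero-denominator rates; the KFRE raises a dedicated
not-computable signal distinct from invalid input; single-class
cohorts raise a training error (CLI exit code 3, versus 2 for
input/parse errors). Model documents round-trip through YAML with
exact float reproduction. Test problem sizes (cohorts of 2,000–10,000,
10,000-draw recovery checks, 1,000–2,000 simulation replicates) were
chosen to make Monte-Carlo tolerances meaningful while keeping the
suite fast.

## Known limitations

* Longitudinal realism is limited to 2–4 lab timepoints per patient —
  enough for averaging/slope features, not for trajectory modelling.
* The naive-Bayes conditional-independence assumption is wrong for
  correlated labs; the model is used for its robustness and
  explainability, not as a density estimator.
* Discretization loses within-bin information; NL/VOI are reported at
  bin resolution.
* The bundled KFRE coefficients are placeholders; computability
  accounting is exact, but benchmark *accuracy* numbers are only
  meaningful with user-supplied published coefficients.
* ICD-10 abstraction is out of scope: comorbidities enter as
  precomputed booleans. Pediatric and cystatin-based eGFR equations
  are not implemented.
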