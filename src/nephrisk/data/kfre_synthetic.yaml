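# SYNTHETIC placeholder KFRE coefficient document.
#
# These are NOT published coefficients. Signs and rough magnitudes are
# clinically plausible (risk falls with age and eGFR, rises with male
# sex, log-ACR, diabetes and hypertension) so that pipelines, tests and
# examples exercise realistic behaviour, but users benchmarking against
# the real equations must supply the published/recalibrated values in
# this same format.
#
# Units: age in years; eGFR in mL/min/1.73 m^2; ACR arrives in mg/mmol
# and unit_factor 8.84 converts it to mg/g before the log transform;
# sex enters as a male indicator (0/1); diabetes/hypertension as 0/1.
variants:
  - variant: 4VAR
    horizon_months: 24
    region: synthetic-placeholder
    citation: "synthetic placeholder set bundled with nephrisk; replace with published values"
    baseline_survival: 0.924
    predictors:
      - {name: age, coefficient: -0.020, center: 70.0}
      - {name: sex, coefficient: 0.16, center: 0.56}
      - {name: egfr, coefficient: -0.10, center: 35.0}
      - {name: acr, coefficient: 0.45, center: 5.14, transform: log, unit_factor: 8.84}
  - variant: 6VAR
    horizon_months: 24
    region: synthetic-placeholder
    citation: "synthetic placeholder set bundled with nephrisk; replace with published values"
    baseline_survival: 0.924
    predictors:
      - {name: age, coefficient: -0.021, center: 70.0}
      - {name: sex, coefficient: 0.15, center: 0.56}
      - {name: egfr, coefficient: -0.098, center: 35.0}
      - {name: acr, coefficient: 0.43, center: 5.14, transform: log, unit_factor: 8.84}
      - {name: diabetes, coefficient: -0.05, center: 0.40}
      - {name: hypertension, coefficient: -0.02, center: 0.79}
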