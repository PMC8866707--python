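# SYNTHETIC placeholder pooled-cohort-equation coefficient set -- NOT CLINICAL.
#
# Signs and rough magnitudes are plausible (risk rises with age, systolic
# blood pressure, treated hypertension, diabetes, smoking and total
# cholesterol; falls with HDL-C) but the values are invented for structural
# and monotonicity validation of the risk-stratification machinery only.
# Replace with a validated revised-PCE coefficient file for any real use.
model_form: revised-logistic
sexes:
  female:
    intercept: -10.20
    terms:
      - {variables: [age], transform: identity, coefficient: 0.080}
      - {variables: [age], transform: square, coefficient: -0.00012}
      - {variables: [sbp], transform: identity, coefficient: 0.018}
      - {variables: [bp_treated], transform: identity, coefficient: 0.40}
      - {variables: [diabetes], transform: identity, coefficient: 0.70}
      - {variables: [smoker], transform: identity, coefficient: 0.55}
      - {variables: [tc], transform: log, coefficient: 0.80}
      - {variables: [hdl], transform: log, coefficient: -0.90}
      - {variables: [age, smoker], transform: product, coefficient: -0.004}
  male:
    intercept: -9.80
    terms:
      - {variables: [age], transform: identity, coefficient: 0.080}
      - {variables: [age], transform: square, coefficient: -0.00012}
      - {variables: [sbp], transform: identity, coefficient: 0.018}
      - {variables: [bp_treated], transform: identity, coefficient: 0.40}
      - {variables: [diabetes], transform: identity, coefficient: 0.70}
      - {variables: [smoker], transform: identity, coefficient: 0.55}
      - {variables: [tc], transform: log, coefficient: 0.80}
      - {variables: [hdl], transform: log, coefficient: -0.90}
      - {variables: [age, smoker], transform: product, coefficient: -0.004}
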