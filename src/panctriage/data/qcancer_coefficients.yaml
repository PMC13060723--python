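# Synthetic sex-specific logistic coefficients for the regression-score
# engine.  These are NOT the published QCancer coefficients (which are
# available from the tool's publishers); they exist so the engine is fully
# exercised and testable.  The engine is model-agnostic: point this file at
# a transcription of the published model to evaluate it.
model_name: qcancer_synthetic
threshold: 0.02
age_min: 25
age_max: 89
default_bmi: 25.0
default_deprivation: 50
sexes:
  male:
    intercept: -7.2
    age_per_decade: 0.55      # per decade above age_ref
    age_ref: 60
    bmi_per_unit: -0.015      # per kg/m2 above default_bmi
    deprivation_per_decile: 0.02
    symptoms:
      abdominal_pain: 1.1
      uwl: 1.4
      new_onset_diabetes: 0.9
      dysphagia: 0.7
      indigestion: 0.5
      cibh: 0.6
      appetite_loss: 0.8
      vte: 0.9
      constipation: 0.3
      gi_bleed: 0.6
  female:
    intercept: -7.4
    age_per_decade: 0.55
    age_ref: 60
    bmi_per_unit: -0.015
    deprivation_per_decile: 0.02
    symptoms:
      abdominal_pain: 1.0
      uwl: 1.5
      new_onset_diabetes: 0.9
      dysphagia: 0.7
      indigestion: 0.5
      cibh: 0.6
      appetite_loss: 0.9
      vte: 1.0
      constipation: 0.3
      gi_bleed: 0.6
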