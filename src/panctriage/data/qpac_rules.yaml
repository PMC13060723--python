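# Illustrative default urgent-referral combination set for QPaC.  The
# "persistent symptom" criterion is deliberately not represented (it cannot
# be derived from reason-for-encounter data).  Replace with the published
# combinations for a faithful evaluation.
tool_name: QPaC
provenance_note: illustrative default - persistent criterion not applied
clauses:
  - {required_symptoms: [jaundice]}
  - {required_symptoms: [pancreatitis]}
  - {required_symptoms: [uwl, abdominal_pain]}
  - {required_symptoms: [uwl, cibh]}
  - {required_symptoms: [new_onset_diabetes, uwl]}
  - {required_symptoms: [new_onset_diabetes, abdominal_pain]}
  - {required_symptoms: [abdominal_pain, back_pain], min_age: 60}
  - {required_symptoms: [steatorrhoea]}
  - {required_symptoms: [dark_urine_pale_stools]}
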