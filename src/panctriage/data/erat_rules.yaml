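# Illustrative default combination-rule set for the electronic risk
# assessment tool (eRAT).  The published high-risk combination table is
# supplementary material of the original study and is NOT transcribed here;
# replace this file with the published table for a faithful evaluation.
# Engine semantics: a patient is flagged when ALL required_symptoms of any
# one clause co-occur within the accumulation window and the age/sex
# conditions hold.
tool_name: eRAT
provenance_note: illustrative default - replace with published combination table
clauses:
  - {required_symptoms: [jaundice]}
  - {required_symptoms: [uwl, abdominal_pain], min_age: 60}
  - {required_symptoms: [uwl, new_onset_diabetes]}
  - {required_symptoms: [abdominal_pain, new_onset_diabetes], min_age: 60}
  - {required_symptoms: [uwl, back_pain], min_age: 60}
  - {required_symptoms: [abdominal_pain, cibh], min_age: 60}
  - {required_symptoms: [ep_radiating]}
  - {required_symptoms: [steatorrhoea]}
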