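# Default free-text symptom lexicon (version 1).
#
# Illustrative, replaceable configuration: include patterns assert a symptom
# within a reason segment, exclude patterns veto it within the same segment.
# Matching is case-insensitive. Replace with a locally validated lexicon for
# any real deployment.
- code: jaundice
  include: ["jaundice", "jaundiced", "icterus", "icteric", "yellow (skin|sclera|eyes)"]
  exclude: ["family history", "fam hx", "fhx", "no jaundice", "neonatal", "obstetric cholestasis"]
- code: abdominal_pain
  include: ["abdo(minal)? pain", "abdo pain", "stomach (pain|ache)", "tummy (pain|ache)", "pain in abdomen", "epigastric pain(?! radiating)"]
  exclude: ["family history", "fhx", "no abdo"]
- code: ep_radiating
  include: ["epigastric pain radiating", "epigastric pain .{0,20}(to|into) (the )?back", "ep radiating"]
  exclude: ["family history"]
- code: back_pain
  include: ["back pain", "backache", "pain in (the )?(lower |upper )?back", "lumbar pain"]
  exclude: ["family history", "no back pain"]
- code: abdominal_distension
  include: ["abdo(minal)? distension", "distended abdomen", "bloat(ing|ed)", "abdo swelling"]
  exclude: ["family history"]
- code: cibh
  include: ["change[ds]? in bowel habit", "altered bowel habit", "bowel habit change", "cibh"]
  exclude: ["family history"]
- code: constipation
  include: ["constipat(ion|ed)", "hard stools", "unable to open bowels"]
  exclude: ["family history"]
- code: diarrhoea
  include: ["diarrh?oea", "loose stools?", "watery stools?"]
  exclude: ["family history", "traveller"]
- code: steatorrhoea
  include: ["steatorrh?oea", "fatty stools?", "oily stools?", "pale greasy stool"]
  exclude: ["family history"]
- code: nausea
  include: ["nausea", "nauseous", "nauseated", "feeling sick"]
  exclude: ["family history"]
- code: vomiting
  include: ["vomit(ing|ed|s)?", "emesis", "throwing up"]
  exclude: ["family history", "haematemesis"]
- code: indigestion
  include: ["indigestion", "dyspepsia", "heartburn", "reflux"]
  exclude: ["family history"]
- code: dysphagia
  include: ["dysphagia", "difficulty swallowing", "trouble swallowing", "food sticking"]
  exclude: ["family history"]
- code: appetite_loss
  include: ["(loss of|decreased|poor|reduced) appetite", "appetite loss", "anorexia", "not eating"]
  exclude: ["family history", "anorexia nervosa"]
- code: uwl
  include: ["weight loss", "losing weight", "lost weight", "unintentional wt loss", "uwl"]
  exclude: ["family history", "weight loss (program|clinic|advice)", "intentional weight loss", "trying to lose"]
- code: fatigue
  include: ["fatigue[d]?", "tired(ness)? all the time", "lethargy", "lethargic", "exhaust(ed|ion)", "TATT"]
  exclude: ["family history"]
- code: pruritus
  include: ["pruritus", "itch(y|ing)?", "generalised itch"]
  exclude: ["family history", "insect bite", "scabies", "head lice"]
- code: new_onset_diabetes
  include: ["new[ -]onset diabetes", "newly diagnosed diabetes", "new diabet(es|ic)"]
  exclude: ["family history", "fhx", "gestational", "diabetes (review|check|clinic|annual)"]
- code: pancreatitis
  include: ["pancreatitis", "inflamed pancreas", "pancreatic inflammation"]
  exclude: ["family history", "fhx", "pancreatic cancer", "history of pancreatitis"]
- code: gi_bleed
  include: ["gi bleed", "gastrointestinal bleed(ing)?", "melaena", "melena", "rectal bleed(ing)?", "blood in stool", "haematemesis"]
  exclude: ["family history"]
- code: vte
  include: ["vte", "venous thromboembolism", "deep vein thrombosis", "\\bdvt\\b", "pulmonary embolism", "\\bpe\\b"]
  exclude: ["family history", "pe tube", "physical education"]
- code: depression_anxiety
  include: ["depress(ion|ed)", "anxiety", "anxious", "low mood"]
  exclude: ["family history", "depression (review|clinic)", "medication review"]
- code: dark_urine_pale_stools
  include: ["dark urine", "pale stools?", "clay.coloured stools?", "tea.coloured urine"]
  exclude: ["family history"]
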