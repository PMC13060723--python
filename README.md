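# panctriage

External-validation pipeline for symptom-based pancreatic-cancer triage
tools (eRAT, QPaC, QCancer-style risk scores) on linked primary-care and
cancer-registry event tables.

The pipeline:

1. **`panctriage.synthetic`** — generates referentially consistent linked
   tables (patients, encounters with free-text reason-for-encounter,
   pathology, prescriptions, ICD-10 registry) with configurable per-symptom
   prevalence by future cancer status, so the whole analysis is testable
   without any real data.
2. **`panctriage.symptoms`** — maps free text to 23 canonical signs/symptoms
   via a replaceable YAML regex lexicon with segment-scoped include/exclude
   filters.
3. **`panctriage.features`** — derives new-onset diabetes (single elevated
   HbA1c, paired raised results >3 months apart, or first diabetes
   prescription; earliest route wins) and biochemical jaundice (bilirubin
   above a configurable upper limit), with HbA1c unit normalisation
   (NGSP/IFCC master equation).
4. **`panctriage.cohort`** — study entry at the first tool-relevant symptom,
   a 12-month accumulation window re-evaluated at each event date, stopping
   at flag / diagnosis / window end, index date and 12-month follow-up
   outcome; includes the pre-COVID sensitivity-analysis filter.
5. **`panctriage.tools`** — a shared combination-rule engine (rulesets as
   YAML clauses over symptom sets with age/sex conditions) and a
   sex-specific logistic risk score with threshold flagging and default
   substitution for missing BMI/deprivation. Shipped rulesets and
   coefficients are illustrative placeholders — point the engines at
   published tables for a faithful evaluation.
6. **`panctriage.stats`** — confusion matrices, PPV/NPV/sensitivity/
   specificity/accuracy with exact Clopper–Pearson 95% CIs (Wilson/Wald
   selectable), likelihood ratios with log-method CIs, per-symptom PPVs,
   Pearson χ² and Mann–Whitney U group comparisons.
7. **`panctriage.report` / `panctriage.cli`** — end-to-end orchestration
   emitting a seven-file machine-readable bundle (cohort flow, cohort
   characteristics, prevalence, per-symptom PPVs, per-tool confusion
   matrices and accuracy statistics, provenance).

## CLI

```bash
# synthetic linked tables
panctriage simulate --n 20000 --seed 1 --out data/

# text symptom extraction
panctriage extract --tables data/ --out events.csv

# evaluate one tool, then accuracy statistics
panctriage evaluate --tables data/ --tool erat --out evals.csv
panctriage stats --evaluations evals.csv --out stats.csv

# end to end: simulate -> extract -> evaluate all tools -> report bundle
panctriage run --simulate --n 20000 --seed 1 --out bundle/
```

`panctriage run --config run.yaml` accepts a YAML `RunConfig` pointing at
existing CSV tables (`input_dir`) instead of simulation, plus custom
lexicon, ruleset and coefficient files.

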