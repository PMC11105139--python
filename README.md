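# charlson-nlp

Hybrid rule-based/ML detection of medical conditions in French clinical
notes: the 16 comorbidities of the **Charlson comorbidity index (CCI)** plus
tobacco and alcohol consumption status, extracted at the hospital-stay level,
with an ICD-10 claim-code comparator and a full evaluation stack.

It is aimed at clinical-data-warehouse teams and epidemiologists who need
per-stay comorbidity variables from free text — e.g. to compute the CCI, to
estimate condition prevalences, or to audit the systematic undercoding of
billing (claim) data.

## What the pipeline does

For each clinical note:

1. **Preprocessing** — lowercase, strip diacritics, standardize quotes via an
   explicit per-character table that keeps an exact normalized→raw offset
   map; tokenize; detect sections (including `antecedents familiaux`, whose
   mentions are family-related, and irrelevant boilerplate such as signature
   blocks).
2. **NER** — 18 per-condition modules, each a curated dictionary of regular
   expressions with exclusion patterns for identified false-positive
   mechanisms (care-site names, lab-test denominations) and context rules
   that assign a severity status to the 5 two-status conditions
   (diabetes *uncomplicated / with end-organ damage*, liver disease
   *mild / moderate-to-severe*, solid tumor *localized / metastatic*,
   tobacco and alcohol *stopped / present*).
3. **Qualification** — discard mentions that are negated (*pas de diabète*),
   hypothetical (*suspicion de…*) or not about the patient (*chez le père*),
   using either NegEx-style cue/scope rules or a trainable classifier that
   embeds the snippet's tokens, mean-pools the entity tokens and applies a
   single fully-connected layer (`SnippetQualifier`, an sklearn-style
   estimator with hashed lexical features as the pluggable embedding
   backend).
4. **Aggregation** — a condition is present for the stay iff ≥ 1 mention
   survives qualification; the most severe detected status wins:

   present(c) ⇔ |kept mentions of c| ≥ 1,  status(c) = max over kept mentions

   The CCI is then `Σ w(c, status)` over present index conditions with the
   canonical 1/2/3/6 weights (tobacco/alcohol never contribute).

The **CLAIM** comparator derives the same per-stay variables from ICD-10
codes by configurable prefix lists. **Evaluation** scores both pipelines
against entity- and stay-level gold standards: overlap-based entity
matching, PPV / sensitivity / specificity / F1 per condition and per status,
micro/macro/weighted averages, percentile-bootstrap 95% CIs resampling
stays, and a PPV-only protocol for the very rare conditions (hemiplegia,
AIDS) which are excluded from the averages.

A deterministic **synthetic-corpus generator** produces French-style notes
with gold annotations, stay labels and claim records (configurable
prevalences, cue rates, out-of-vocabulary rates, claim under/overcoding), so
the whole stack is testable without any clinical data.

## Worked example

```bash
charlson-nlp simulate --out-dir corpus --seed 11 --n-stays 40 \
    --negation-rate 0 --hypothesis-rate 0 --family-rate 0 \
    --generic-fp-rate 0 --oov-cue-rate 0 --claim-undercoding-rate 0 \
    --inpatient-fraction 1.0
charlson-nlp annotate --notes corpus/notes.jsonl --out-dir out
charlson-nlp evaluate --pred out/stay_predictions.jsonl \
    --truth corpus/truth.json --out out/report.json --level stay
```

On this zero-noise corpus the stay-level report's micro-average row reads

```
f1=100.0  ppv=100.0  sensitivity=100.0  specificity=100.0
```

i.e. the rule-based pipeline recovers the gold standard exactly when every
mention phrasing is in the dictionaries — misses and false positives are
introduced only by the explicit noise knobs. The same flow with
`--claim-undercoding-rate 0.5` followed by `claim-map` shows the claim
pipeline's signature behaviour: sensitivity ≈ 50 with specificity ≈ 100,
while the NLP pipeline keeps sensitivity near 100.

The library mirrors the CLI:

```python
from charlson_nlp import (load_pipeline_config, generate_corpus,
                          run_nlp_pipeline, evaluate_pipeline, GeneratorConfig)

config = load_pipeline_config()                 # bundled dictionaries
gen = GeneratorConfig(n_stays=200, seed=7)
notes, truth, claims = generate_corpus(gen, config.definitions)
mentions, stays = run_nlp_pipeline(notes, config)
report = evaluate_pipeline(stays, truth.stay_labels, config.definitions,
                           level="stay", bootstrap_reps=1000, seed=7)
print(report.to_frame().head())
```

## Configuration

Everything lives in one YAML file
(`src/charlson_nlp/resources/default_config.yml`): per-condition regex
dictionaries, exclusions, severity rules, ICD-10 prefix lists, CCI weights,
the section lexicon and the qualification cue lexicon. Pass `--config` (or
`load_pipeline_config(path)`) to override; no code changes are needed to
edit a dictionary. See `docs/methods.md` for the underlying modelling
choices and limitations.
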