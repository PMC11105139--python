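# Methods

This note documents the models and procedures implemented in
`charlson-nlp`, the parameters that matter, the synthetic data the tests
run on, and the design choices made where the design was genuinely open.

## Problem setting

Comorbidities are routinely needed at the hospital-stay level — to compute
the Charlson comorbidity index (CCI), to adjust epidemiological analyses,
or to audit billing data — but they live mostly in free-text notes. The
package detects 18 conditions in French clinical notes (the 16 CCI
conditions plus tobacco and alcohol consumption status, which are clinically
relevant but never enter the CCI), aggregates detections per stay, and
compares the result with what ICD-10 claim codes would give.

## Pipeline

### Preprocessing

Normalization (lowercase, diacritic stripping, quote standardization) uses
an explicit per-character table rather than a generic Unicode decomposition,
so that every normalized character maps deterministically to the raw
character that produced it (`norm_to_raw`). Ligatures (œ → oe, æ → ae)
expand the string; all produced characters map back to the source
character. This auditability matters because gold-standard character spans
must survive normalize → match → report round trips exactly; a property
test drives 500 random notes through the round trip.

Tokenization splits on whitespace, then splits punctuation and French
elisions (`l'asthme` → `l'` + `asthme`). Sections are opened by title
patterns from a configurable lexicon (~15 French titles by default) and run
to the next title; `antecedents familiaux` is the family-history class,
signature/destinataire blocks are irrelevant. Untitled leading text is one
implicit relevant section. Overlapping title matches resolve
longest-match-at-position.

### NER

One matcher per condition: inclusion regexes (optionally carrying a status
hint, e.g. `tabagisme actif` → *present*), exclusion regexes for identified
false-positive mechanisms (care-site names such as *institut du cancer*,
lab denominations such as *sérologie VIH*), and severity rules — context
regexes that assign a status when they fire near the entity.

Numerical/tie-break choices:

- Overlapping matches of the same condition keep the longest span
  (leftmost on ties). Matches of different conditions may overlap freely.
- The context window is 8 tokens per side by default (6 for
  tobacco/alcohol), configurable per condition and per severity rule. The
  upstream work states only that window size "varies between modules".
- A severity cue must lie within its token window **and** in the same
  sentence (no `.;!?` between cue and entity). The same-sentence constraint
  is this package's choice; it prevents a neighbouring sentence's cue
  (e.g. *ascite* in the next finding) from upgrading an unrelated mention.
- Candidates from status hints and severity rules are pooled; the most
  severe wins; with no candidate the least severe status is the default
  (statuses are declared least → most severe; for tobacco/alcohol that
  order is *stopped* < *present*).

### Qualification

Rule-based: NegEx-style scopes. A cue qualifies the entity iff it lies
within a class window (negation 5 tokens, hypothesis 6, family 8 — package
defaults, configurable) on the proper side (negation distinguishes
preceding from following cues; hypothesis and family act on both sides)
with no scope terminator (`. ; : ! ?` or *mais*) strictly between. Mentions
inside a family-history section are family-related regardless of cues; a
mention overlapping an exclusion match or inside an irrelevant section is a
generic false positive. The discard decision is the OR of the four flags,
each recorded separately. These detectors are verified against a
brute-force oracle that enumerates every (cue occurrence, entity) pair over
randomized snippets.

Learned: the qualification classifier keeps the three-step shape
(1) embed each snippet token, (2) mean-pool the embeddings of the entity's
tokens, (3) classify with one fully-connected layer. The embedding backend
here is hashed lexical features (token identity, position-relative-to-entity
bucket clipped to ±3, and ±2-token neighbour features; blake2b hashing into
d = 2^16 dimensions), which trains in seconds on CPU and is a pluggable
interface — a contextual language-model encoder can be substituted without
touching pooling or the head. The head is logistic, trained by full-batch
gradient descent with backtracking line search, so the training loss is
nonincreasing by construction and runs are bit-reproducible. Note the ±2
neighbour window means context farther than two tokens from the entity is
invisible to the pooled vector; cues adjacent to the entity (the common
case in practice and in the generator) are what it learns. The decision
threshold defaults to 0.5 on the keep-probability.

### Aggregation, CCI, prevalence

A condition is present for a stay iff at least one mention survives
qualification; for two-status conditions the most severe status among kept
mentions wins, and a mention with no status counts as least severe. With
several notes per stay the kept mentions are pooled (union) before
aggregation. Aggregation is idempotent, order-independent and monotone
(adding a kept mention never removes a condition nor lowers its status) —
all property-tested.

CCI = Σ weight(condition, status) over present index conditions. The weight
table ships as config with the canonical 1/2/3/6 assignment (e.g. diabetes
1/2 by status, liver disease 1/3, solid tumor 2/6, AIDS 6); tests assert
against the configured table, not literature values, because the table is
config-first. A statused condition reported as bare "present" falls back to
the least-severe weight (configurable behaviour; the reference work does
not state it). No age adjustment.

Prevalence per source = positive stays / stays; the mean absolute
per-condition prevalence gap compares two sources.

### Claim comparator

A condition is claim-present iff any billed code starts with a configured
prefix (dot-free, uppercase); per-status prefix lists give the most severe
matching status. Diagnosis position (principal vs associated) is ignored.
The prefix lists are starter content in the spirit of the standard
claim-based comorbidity mappings.

## Evaluation

- Entity level: a prediction is correct iff it overlaps a gold mention of
  the same condition by ≥ 1 raw character (the overlap amount is not
  quantified upstream; ≥ 1 character is this package's reading).
  Predictions are judged independently: k predictions over one gold mention
  yield k TPs and no FN. Entity-level specificity is undefined — there is
  no entity-level TN universe — and is rendered as undefined, never 0.
- Stay level: per-stay TP/FP/FN/TN per condition; two-status conditions are
  additionally scored per status plus an "Any" (presence) row.
- Metrics are percentages; zero-denominator metrics propagate as undefined.
  Averages: micro = metrics of summed counts, macro = unweighted mean over
  defined per-condition values, weighted = support-weighted mean (support =
  gold positives). Averages are computed over the per-condition "Any" rows
  (16 rows) so statused conditions are not double-counted; the PPV-only
  conditions (hemiplegia, AIDS — too rare for unbiased sensitivity, so only
  PPV is reported, on upsampled positives in the original design) are
  excluded.
- 95% CIs: percentile bootstrap resampling **stays** (the independent
  sampling unit of the validation design; whether the original bootstrap
  resampled stays or notes is unstated). Deterministic given a seed;
  degenerate resamples are skipped and counted. Calibration is checked by
  simulation: ~95% of intervals cover a known true sensitivity.
- Display values round half-up to one decimal; raw values are kept in JSON.
- No multiple-testing correction is applied.

## Synthetic corpus

The generator emulates the data shapes the pipeline assumes: per-condition
prevalences (defaults follow the annotated inpatient cohort composition of
the reference setting, e.g. ~0.6 for peripheral vascular disease, ~0.03 for
hemiplegia, ~0.01 for AIDS), 1 + Poisson mentions per positive stay (mean
2.5, max 6 by default; the reference cohorts average ~2–3 validated
entities per positive note), cue rates (defaults: negation 0.15, hypothesis
0.05, family 0.05, generic FP 0.05 — roughly the ~25% discarded-entity
share seen in the reference cohorts), a 0.5 status mix for two-status
conditions, claim undercoding 0.3 and overcoding 0.01 (undercoding is the
documented failure mode of billing data; overcoding is rare).

Mention sentences are assembled as [optional cue] + dictionary phrase
[+ severity phrase], with the cue class recorded as the gold qualifier;
family mentions may instead land in a generated `antecedents familiaux`
section. Because phrasings are drawn verbatim from the dictionaries,
zero-noise corpora are exactly recoverable and every miss is attributable
to an explicit knob. The out-of-vocabulary rate covers both condition
phrasings (producing NER misses, hence the entity→stay aggregation gain)
and cue phrasings (producing qualification misses, hence NLP false
positives); `oov_forms` are validated to match no dictionary pattern.
Claims keep each true condition's representative code with probability
1 − undercoding and add a spurious absent-condition code with the
overcoding probability.

What the generator does **not** emulate: real discharge-summary discourse,
spelling errors, acronym ambiguity across conditions, implicit severity
(e.g. renal stage inferred from labs), pseudonymization artifacts, and
inter-annotator disagreement. Passing tests therefore demonstrate the
correctness of the machinery and the direction of the documented effects
(aggregation gain, claim trade-off), not clinical-grade accuracy on real
notes — the bundled dictionaries are deliberately compact starter content.

## Sizes used by the bundled experiments

Exact recovery runs on 200 stays; the claim trade-off on 1,000 inpatient
stays; the aggregation-gain corpus on 400 stays with mention mean 3 and 30%
OOV phrasings; the learned qualifier trains/tests on a 1,000/1,000 snippet
split at d = 2^16; bootstrap calibration uses 100 trials × 1,000 replicates
over 500 stays. These sizes give stable estimates while keeping the whole
suite fast on a single CPU.

## Known limitations

- The starter dictionaries (≥ 5 inclusion patterns, ≥ 1 exclusion, ≥ 2
  severity rules per statused condition) are original compact stand-ins,
  not the curated production dictionaries of a real deployment.
- "Composition rules" for dictionary regexes are realized as pattern-level
  alternation plus windowed severity rules — one possible reading.
- The hashed-feature qualifier sees only a ±2-token lexical neighbourhood;
  long-range or syntactic cues require substituting a contextual encoder.
- Statuses are limited to two ordered levels per condition by design.
- Entities in irrelevant sections are flagged post-NER (not dropped
  pre-NER) to keep counts auditable.
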