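"""Deterministic generator of French-style clinical notes with gold labels.

The generator emulates the statistical shape the pipeline assumes: stays
with per-condition prevalences, several mentions per positive condition,
negation/hypothesis/family cues wrapped around some mentions, a
family-history section, care-site style generic false positives, and claim
records with configurable under- and over-coding.  Mention phrasings are
drawn verbatim from the condition dictionaries so that, at zero noise, the
rule-based pipeline can recover the gold standard exactly; out-of-vocabulary
phrasings and cues produce controlled, attributable misses.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .aggregation import aggregate_stay
from .preprocessing import normalize_text, tokenize
from .qualifier_ml import LabeledSnippet
from .types import (
    ABSENT,
    ClaimRecord,
    ConditionDefinition,
    Mention,
    Note,
    NoteClass,
    StayType,
)

#: Default per-condition prevalence: fraction of annotated inpatient notes
#: with at least one validated mention in the study cohorts (counts per 150).
DEFAULT_PREVALENCE: dict[str, float] = {
    "myocardial_infarction": 0.19,
    "congestive_heart_failure": 0.39,
    "peripheral_vascular_disease": 0.60,
    "cerebrovascular_disease": 0.16,
    "dementia": 0.17,
    "chronic_pulmonary_disease": 0.22,
    "rheumatologic_disease": 0.11,
    "peptic_ulcer_disease": 0.07,
    "liver_disease": 0.06,
    "diabetes": 0.25,
    "hemiplegia": 0.03,
    "renal_disease": 0.10,
    "solid_tumor": 0.23,
    "leukemia": 0.05,
    "lymphoma": 0.08,
    "aids": 0.01,
    "alcohol_consumption": 0.09,
    "tobacco_consumption": 0.23,
}

#: Out-of-lexicon cue phrasings used when a cue is drawn OOV.
_OOV_CUES = {
    "negated": "exempt de",
    "hypothetical_suffix": "a reevaluer",
    "family_suffix": "chez son papa",
}

_FILLERS = (
    "le sejour s'est deroule normalement.",
    "les constantes sont restées stables.",
    "le patient rentre à domicile.",
    "la prise en charge se poursuit en ville.",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; identical config ⇒ byte-identical corpus."""

    n_stays: int = 200
    inpatient_fraction: float = 0.5
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    mentions_per_stay_mean: float = 2.5
    mentions_per_stay_max: int = 6
    negation_rate: float = 0.15
    hypothesis_rate: float = 0.05
    family_rate: float = 0.05
    generic_fp_rate: float = 0.05
    status_mix: float = 0.5  # probability of the most severe status
    oov_cue_rate: float = 0.0
    claim_undercoding_rate: float = 0.3
    claim_overcoding_rate: float = 0.01
    seed: int = 0

    def validated(self) -> "GeneratorConfig":
        for name in (
            "inpatient_fraction", "negation_rate", "hypothesis_rate", "family_rate",
            "generic_fp_rate", "status_mix", "oov_cue_rate",
            "claim_undercoding_rate", "claim_overcoding_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        return self


@dataclass
class SyntheticTruth:
    """Gold annotations consistent with the generated text."""

    mentions: list[Mention]
    stay_labels: dict[str, dict[str, str]]
    claim_eligible: dict[str, dict[str, str]]  # inpatient stays only


class _NoteBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def add(self, text: str) -> int:
        """Append text; return its start offset."""
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def text(self) -> str:
        return "".join(self.parts)


def _elide(cue_de: str, phrase: str) -> str:
    """'pas de' + 'asthme' -> "pas d'asthme" (French elision)."""
    if phrase[0] in "aeiouh" and cue_de.endswith(" de"):
        return cue_de[:-3] + " d'" + phrase
    return cue_de + " " + phrase


def generate_corpus(
    config: GeneratorConfig,
    definitions: Sequence[ConditionDefinition],
) -> tuple[list[Note], SyntheticTruth, list[ClaimRecord]]:
    """Generate notes, gold standard and claim records.

    Every positive (stay, condition) pair emits >= 1 mention sentence built
    as [optional cue] + dictionary phrase [+ severity phrase]; the cue class
    is recorded as the gold qualifier.  Family mentions may instead be
    placed in an "antecedents familiaux" section.  Claim codes keep each
    true condition with probability 1 - undercoding_rate and add a spurious
    code with probability overcoding_rate.
    """
    config = config.validated()
    unknown = set(config.prevalence) - {d.condition_id for d in definitions}
    if unknown:
        raise ValueError(f"prevalence map names unknown conditions: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    by_id = {d.condition_id: d for d in definitions}

    notes: list[Note] = []
    gold_mentions: list[Mention] = []
    stay_labels: dict[str, dict[str, str]] = {}
    claim_eligible: dict[str, dict[str, str]] = {}
    claims: list[ClaimRecord] = []

    for i in range(config.n_stays):
        stay_id = f"stay{i:05d}"
        note_id = f"note{i:05d}"
        inpatient = rng.random() < config.inpatient_fraction
        planned: list[dict] = []  # mention plans
        fp_plans: list[ConditionDefinition] = []

        for d in definitions:
            prev = config.prevalence.get(d.condition_id, 0.0)
            if rng.random() >= prev:
                continue
            n_mentions = 1 + int(rng.poisson(max(config.mentions_per_stay_mean - 1.0, 0.0)))
            n_mentions = min(n_mentions, config.mentions_per_stay_max)
            if d.statuses:
                status = d.statuses[1] if rng.random() < config.status_mix else d.statuses[0]
            else:
                status = None
            for _ in range(n_mentions):
                u = rng.random()
                if u < config.negation_rate:
                    cue = "negated"
                elif u < config.negation_rate + config.hypothesis_rate:
                    cue = "hypothetical"
                elif u < config.negation_rate + config.hypothesis_rate + config.family_rate:
                    cue = "family"
                else:
                    cue = None
                oov = rng.random() < config.oov_cue_rate
                planned.append({"definition": d, "status": status, "cue": cue, "oov": oov})
        if rng.random() < config.generic_fp_rate:
            fp_plans.append(by_id[list(by_id)[int(rng.integers(len(by_id)))]])
        order = rng.permutation(len(planned))
        planned = [planned[j] for j in order]

        builder = _NoteBuilder()
        builder.add("compte rendu d'hospitalisation.\n" if inpatient
                    else "compte rendu de consultation.\n")
        builder.add("motif d'hospitalisation :\nprise en charge programmée.\n")
        builder.add("antecedents :\n")

        family_section: list[dict] = []
        mention_counter = 0

        def emit(plan: dict, in_family_section: bool) -> None:
            nonlocal mention_counter
            d: ConditionDefinition = plan["definition"]
            status, cue, oov = plan["status"], plan["cue"], plan["oov"]
            if cue is None and oov and d.oov_forms:
                phrase = d.oov_forms[int(rng.integers(len(d.oov_forms)))]
            else:
                phrase = d.surface_forms[int(rng.integers(len(d.surface_forms)))]
            severity = ""
            if status is not None and cue is None:
                severity = d.severity_surface.get(status, "")
            qualifiers: set[str] = set()
            if cue == "negated":
                qualifiers.add("negated")
                head = _elide(_OOV_CUES["negated"] if oov else
                             ("absence de" if rng.random() < 0.5 else "pas de"), phrase)
                sentence, phrase_offset = head + ".", len(head) - len(phrase)
            elif cue == "hypothetical":
                qualifiers.add("hypothetical")
                if oov:
                    sentence, phrase_offset = phrase + " " + _OOV_CUES["hypothetical_suffix"] + ".", 0
                else:
                    head = _elide("suspicion de", phrase)
                    sentence, phrase_offset = head + ".", len(head) - len(phrase)
            elif cue == "family":
                qualifiers.add("family")
                if in_family_section:
                    sentence, phrase_offset = "notion de " + phrase + ".", len("notion de ")
                else:
                    suffix = _OOV_CUES["family_suffix"] if oov else "chez le pere"
                    sentence, phrase_offset = phrase + " " + suffix + ".", 0
            else:
                lead = "le bilan retrouve " if mention_counter % 2 == 0 else "on note "
                sentence = lead + phrase + (" " + severity if severity else "") + "."
                phrase_offset = len(lead)
            start = builder.add(sentence + "\n") + phrase_offset
            end = start + len(phrase)
            snippet = (max(0, start - 60), min(builder.length, end + 60))
            gold_mentions.append(
                Mention(
                    mention_id=f"{note_id}:g{mention_counter}",
                    note_id=note_id,
                    condition_id=d.condition_id,
                    span=(start, end),
                    snippet_span=snippet,
                    status=(status if cue is None else (d.default_status if d.statuses else None)),
                    qualifiers=qualifiers,
                    discarded=bool(qualifiers),
                )
            )
            mention_counter += 1

        for plan in planned:
            if plan["cue"] == "family" and not plan["oov"] and rng.random() < 0.5:
                family_section.append(plan)
            else:
                emit(plan, in_family_section=False)

        for d in fp_plans:
            if d.fp_form:
                sentence = "oriente vers " + d.fp_form + "."
                start = builder.add(sentence + "\n") + len("oriente vers ")
                end = start + len(d.fp_form)
                gold_mentions.append(
                    Mention(
                        mention_id=f"{note_id}:g{mention_counter}",
                        note_id=note_id,
                        condition_id=d.condition_id,
                        span=(start, end),
                        snippet_span=(max(0, start - 60), end + 1),
                        status=d.default_status,
                        qualifiers={"generic_fp"},
                        discarded=True,
                    )
                )
                mention_counter += 1

        if family_section:
            builder.add("antecedents familiaux :\n")
            for plan in family_section:
                emit(plan, in_family_section=True)

        builder.add("histoire de la maladie :\n")
        builder.add(_FILLERS[int(rng.integers(len(_FILLERS)))] + "\n")
        builder.add("conclusion :\n" + _FILLERS[int(rng.integers(len(_FILLERS)))] + "\n")
        builder.add("signature :\ndr patel, service de medecine interne.\n")

        text = builder.text()
        notes.append(
            Note(
                note_id=note_id,
                stay_id=stay_id,
                note_class=NoteClass.discharge_summary if inpatient
                else NoteClass.consultation_report,
                stay_type=StayType.inpatient if inpatient else StayType.outpatient,
                text=text,
            )
        )

        stay_mentions = [m for m in gold_mentions if m.note_id == note_id]
        label_pred = aggregate_stay(stay_id, stay_mentions, definitions, source="gold")
        stay_labels[stay_id] = dict(label_pred.conditions)

        if inpatient:
            truth_set = {
                c: v for c, v in label_pred.conditions.items() if v != ABSENT
            }
            claim_eligible[stay_id] = truth_set
            codes: list[str] = []
            for c, v in truth_set.items():
                if rng.random() < config.claim_undercoding_rate:
                    continue
                d = by_id[c]
                key = v if d.statuses else "any"
                code = d.example_codes.get(key)
                if code:
                    codes.append(code)
            if rng.random() < config.claim_overcoding_rate:
                absent = [c for c in by_id if c not in truth_set]
                if absent:
                    d = by_id[absent[int(rng.integers(len(absent)))]]
                    key = d.statuses[0] if d.statuses else "any"
                    code = d.example_codes.get(key)
                    if code:
                        codes.append(code)
            claims.append(ClaimRecord.from_raw(stay_id, codes))

    truth = SyntheticTruth(
        mentions=gold_mentions, stay_labels=stay_labels, claim_eligible=claim_eligible
    )
    return notes, truth, claims


def raw_to_norm_span(norm_to_raw: Sequence[int], raw_span: tuple[int, int]) -> tuple[int, int]:
    s, e = raw_span
    idx = [i for i, r in enumerate(norm_to_raw) if s <= r < e]
    if not idx:
        raise ValueError(f"raw span {raw_span} maps to no normalized character")
    return (idx[0], idx[-1] + 1)


def make_labeled_snippets(
    notes: Sequence[Note],
    truth: SyntheticTruth,
    window: int = 8,
) -> list[LabeledSnippet]:
    """One labeled snippet per gold mention (discard iff any qualifier)."""
    note_map = {n.note_id: n for n in notes}
    cache: dict[str, tuple] = {}
    snippets: list[LabeledSnippet] = []
    for m in truth.mentions:
        note = note_map[m.note_id]
        if m.note_id not in cache:
            nt = normalize_text(note.text)
            cache[m.note_id] = (nt, tokenize(nt))
        nt, tokens = cache[m.note_id]
        ns = raw_to_norm_span(nt.norm_to_raw, m.span)
        overlapping = [t.index for t in tokens if t.span_norm[0] < ns[1] and ns[0] < t.span_norm[1]]
        first, last = overlapping[0], overlapping[-1]
        lo = max(0, first - window)
        hi = min(len(tokens) - 1, last + window)
        snippets.append(
            LabeledSnippet(
                tokens=tuple(t.surface for t in tokens[lo : hi + 1]),
                entity_range=(first - lo, last - lo),
                label="discard" if m.qualifiers else "keep",
            )
        )
    return snippets


def upsample_selection(
    notes: Sequence[Note],
    preannotation_counts: dict[str, dict[str, int]],
    k: int,
    seed: int = 0,
) -> list[Note]:
    """Pick the k notes most relevant for annotation of rare conditions.

    Ranking is lexicographic: first by the document frequency of the rarest
    condition pre-annotated in the note (so a note holding the corpus's
    rarest condition always comes first), then by the sum of inverse
    document frequencies over its conditions, then by a seeded shuffle.
    """
    df: dict[str, int] = {}
    for counts in preannotation_counts.values():
        for cond, n in counts.items():
            if n > 0:
                df[cond] = df.get(cond, 0) + 1

    def key(j: int, shuffled: list[int]) -> tuple:
        counts = preannotation_counts.get(notes[j].note_id, {})
        hit_dfs = [df[c] for c, n in counts.items() if n > 0 and c in df]
        min_df = min(hit_dfs) if hit_dfs else float("inf")
        idf_sum = sum(1.0 / d for d in hit_dfs)
        return (min_df, -idf_sum, shuffled[j])

    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(len(notes)))
    order = sorted(range(len(notes)), key=lambda j: key(j, shuffled))
    return [notes[j] for j in order[: min(k, len(notes))]]


def perfect_dictionary_config(seed: int, n_stays: int = 200, **overrides) -> GeneratorConfig:
    """Zero-noise configuration under which exact recovery is expected."""
    return replace(
        GeneratorConfig(
            n_stays=n_stays,
            negation_rate=0.0,
            hypothesis_rate=0.0,
            family_rate=0.0,
            generic_fp_rate=0.0,
            oov_cue_rate=0.0,
            claim_undercoding_rate=0.0,
            claim_overcoding_rate=0.0,
            seed=seed,
        ),
        **overrides,
    )
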