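"""NER matching, exclusions and severity-status assignment."""
import re

import pytest

from charlson_nlp.config import load_pipeline_config
from charlson_nlp.matcher import (
    apply_exclusions,
    assign_statuses,
    compile_matchers,
    extract_mentions,
)
from charlson_nlp.preprocessing import detect_sections, normalize_text, tokenize


def _pipeline(text, config, conditions=None):
    nt = normalize_text(text)
    tokens = tokenize(nt)
    matchers = compile_matchers(config.definitions)
    if conditions:
        matchers = [m for m in matchers if m.condition_id in conditions]
    sections = detect_sections(nt, config.section_lexicon)
    mentions = extract_mentions("n1", nt, matchers, tokens)
    mentions = apply_exclusions(mentions, nt, matchers, sections)
    mentions = assign_statuses(mentions, nt, matchers, tokens)
    return nt, mentions


class TestExtraction:
    def test_single_diabetes_mention(self, pipeline_config):
        text = "diabete de type 2"
        nt, mentions = _pipeline(text, pipeline_config, {"diabetes"})
        assert len(mentions) == 1
        s, e = mentions[0].span
        assert "diabet" in text[s:e]

    def test_no_hits_empty(self, pipeline_config):
        _, mentions = _pipeline("rien a signaler aujourd'hui", pipeline_config)
        assert mentions == []

    def test_two_mentions_same_condition(self, pipeline_config):
        text = "infarctus du myocarde ancien ; idm en 2019"
        nt, mentions = _pipeline(text, pipeline_config, {"myocardial_infarction"})
        # brute-force scan: every inclusion hit, overlaps merged
        d = pipeline_config.definition("myocardial_infarction")
        hits = set()
        for pat, _ in d.patterns:
            for m in re.finditer(pat, nt.norm):
                hits.add((m.start(), m.end()))
        assert len(mentions) == 2
        assert all(any(s <= ms < e or ms < e <= me for ms, me in hits)
                   for s, e in [m.span for m in mentions])

    def test_overlapping_matches_merged_to_longest(self, pipeline_config):
        # "tabagisme actif" matches both the bare and the hinted pattern
        nt, mentions = _pipeline("tabagisme actif", pipeline_config, {"tobacco_consumption"})
        assert len(mentions) == 1
        s, e = mentions[0].span
        assert "tabagisme actif"[s:e] == "tabagisme actif"

    def test_determinism(self, pipeline_config):
        text = "diabete et idm ; asthme connu, cancer du sein localise."
        a = _pipeline(text, pipeline_config)[1]
        b = _pipeline(text, pipeline_config)[1]
        assert [(m.mention_id, m.span, m.status) for m in a] == [
            (m.mention_id, m.span, m.status) for m in b
        ]

    def test_adding_inclusion_pattern_never_removes_mentions(self, pipeline_config):
        import copy

        text = "le bilan retrouve un diabete et une glycoregulation anormale."
        base = {m.span for m in _pipeline(text, pipeline_config, {"diabetes"})[1]}
        config2 = copy.deepcopy(pipeline_config)
        config2.definition("diabetes").patterns.append(("glycoregulation", None))
        extended = {m.span for m in _pipeline(text, config2, {"diabetes"})[1]}
        assert base <= extended and len(extended) == len(base) + 1


class TestExclusions:
    def test_care_site_mention_discarded_generic_fp(self, pipeline_config):
        _, mentions = _pipeline(
            "le patient est oriente vers l'institut du cancer.",
            pipeline_config, {"solid_tumor"},
        )
        assert len(mentions) == 1
        assert mentions[0].discarded and "generic_fp" in mentions[0].qualifiers

    def test_clean_mention_unchanged(self, pipeline_config):
        _, mentions = _pipeline("cancer du poumon connu.", pipeline_config, {"solid_tumor"})
        assert len(mentions) == 1
        assert not mentions[0].discarded and not mentions[0].qualifiers

    def test_family_history_section_adds_family_qualifier(self, pipeline_config):
        text = "antecedents familiaux :\nnotion de diabete.\n"
        _, mentions = _pipeline(text, pipeline_config, {"diabetes"})
        assert len(mentions) == 1
        assert "family" in mentions[0].qualifiers

    def test_irrelevant_section_discards(self, pipeline_config):
        text = "signature :\ndr diabete, interne.\n"
        _, mentions = _pipeline(text, pipeline_config, {"diabetes"})
        assert mentions and all("generic_fp" in m.qualifiers for m in mentions)

    def test_adding_exclusion_never_adds_kept_mentions(self, pipeline_config):
        import copy

        text = "suivi a la maison du diabete pour un diabete connu."
        kept_base = {m.span for m in _pipeline(text, pipeline_config, {"diabetes"})[1]
                     if not m.discarded}
        config2 = copy.deepcopy(pipeline_config)
        config2.definition("diabetes").exclusion_patterns.append("diabete connu")
        kept_ext = {m.span for m in _pipeline(text, config2, {"diabetes"})[1]
                    if not m.discarded}
        assert kept_ext <= kept_base


class TestStatus:
    def test_diabetes_complication_in_context(self, pipeline_config):
        _, mentions = _pipeline(
            "diabete complique de retinopathie", pipeline_config, {"diabetes"}
        )
        assert mentions[0].status == "with_end_organ_damage"

    def test_tumor_metastatic_within_window(self, pipeline_config):
        _, mentions = _pipeline(
            "tumeur du colon avec metastases hepatiques", pipeline_config, {"solid_tumor"}
        )
        assert mentions[0].status == "metastatic"

    def test_most_severe_wins_on_conflicting_cues(self, pipeline_config):
        # stopped cue and active cue both in window: Present (most severe) wins
        _, mentions = _pipeline(
            "tabagisme sevre puis actif recemment", pipeline_config, {"tobacco_consumption"}
        )
        assert mentions[0].status == "present"

    def test_default_is_least_severe(self, pipeline_config):
        _, mentions = _pipeline("cirrhose connue", pipeline_config, {"liver_disease"})
        assert mentions[0].status == "mild"

    def test_severity_cue_blocked_by_sentence_boundary(self, pipeline_config):
        _, mentions = _pipeline(
            "cirrhose connue. par ailleurs ascite ancienne", pipeline_config, {"liver_disease"}
        )
        assert mentions[0].status == "mild"

    def test_binary_condition_keeps_status_unset(self, pipeline_config):
        _, mentions = _pipeline("asthme ancien", pipeline_config, {"chronic_pulmonary_disease"})
        assert mentions[0].status is None

    def test_negative_lookbehind_on_complication(self, pipeline_config):
        _, mentions = _pipeline("diabete non complique", pipeline_config, {"diabetes"})
        assert mentions[0].status == "uncomplicated"


class TestDictionaryGeneratorContract:
    """The bundled surface forms must behave as the generator assumes."""

    def test_surface_forms_matched_by_own_patterns_only(self, pipeline_config):
        matchers = compile_matchers(pipeline_config.definitions)
        for d in pipeline_config.definitions:
            for phrase in d.surface_forms:
                nt = normalize_text(phrase)
                for m in matchers:
                    hit = any(rx.search(nt.norm) for rx, _ in m.inclusion)
                    if m.condition_id == d.condition_id:
                        assert hit, f"{d.condition_id}: {phrase!r} not matched"
                    else:
                        assert not hit, (
                            f"{phrase!r} of {d.condition_id} also matches "
                            f"{m.condition_id}"
                        )

    def test_oov_forms_matched_by_no_pattern(self, pipeline_config):
        matchers = compile_matchers(pipeline_config.definitions)
        for d in pipeline_config.definitions:
            for phrase in d.oov_forms:
                nt = normalize_text(phrase)
                for m in matchers:
                    assert not any(rx.search(nt.norm) for rx, _ in m.inclusion), (
                        f"oov {phrase!r} matches {m.condition_id}"
                    )

    def test_fp_forms_hit_both_inclusion_and_exclusion(self, pipeline_config):
        matchers = {m.condition_id: m for m in compile_matchers(pipeline_config.definitions)}
        for d in pipeline_config.definitions:
            if d.fp_form is None:
                continue
            nt = normalize_text(d.fp_form)
            m = matchers[d.condition_id]
            assert any(rx.search(nt.norm) for rx, _ in m.inclusion)
            assert any(rx.search(nt.norm) for rx in m.exclusion)

    def test_example_codes_map_to_own_condition_only(self, pipeline_config):
        from charlson_nlp.claims import map_claim_codes
        from charlson_nlp.types import ABSENT, ClaimRecord

        for d in pipeline_config.definitions:
            for key, code in d.example_codes.items():
                pred = map_claim_codes(
                    ClaimRecord.from_raw("s", [code]), pipeline_config.definitions
                )
                present = {c for c, v in pred.conditions.items() if v != ABSENT}
                assert present == {d.condition_id}, (code, present)
                if d.statuses:
                    assert pred.conditions[d.condition_id] == key
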