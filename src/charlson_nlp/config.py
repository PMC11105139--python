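"""Loading and validating the pipeline configuration.

One YAML file holds the 18 condition dictionaries, the section lexicon and
the qualification cue lexicon.  A starter configuration is bundled with the
package; everything is overridable by pointing the loader at another file.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .preprocessing import SectionLexiconEntry
from .types import CONDITION_IDS, ConditionDefinition, SeverityRule


@dataclass
class CueLexicon:
    """Cue phrases and scope parameters for rule-based qualification."""

    negation_preceding: list[str]
    negation_following: list[str]
    hypothesis: list[str]
    family: list[str]
    scope_window_tokens: dict[str, int] = field(
        default_factory=lambda: {"negation": 5, "hypothesis": 6, "family": 8}
    )
    scope_terminators: list[str] = field(
        default_factory=lambda: [".", ";", ":", "!", "?", "mais"]
    )

    def validate(self) -> None:
        for name in ("negation_preceding", "hypothesis", "family"):
            if not getattr(self, name):
                raise ValueError(f"cue lexicon: {name} may not be empty")
        if not any(t in {".", "!", "?"} for t in self.scope_terminators):
            raise ValueError(
                "cue lexicon: terminators must include sentence-ending punctuation"
            )


@dataclass
class PipelineConfig:
    """Everything the pipeline stages need, plus a provenance hash."""

    definitions: list[ConditionDefinition]
    section_lexicon: list[SectionLexiconEntry]
    cue_lexicon: CueLexicon
    config_hash: str = ""

    def definition(self, condition_id: str) -> ConditionDefinition:
        for d in self.definitions:
            if d.condition_id == condition_id:
                return d
        raise KeyError(condition_id)


def _parse_pattern(item: Union[str, dict]) -> tuple[str, Optional[str]]:
    if isinstance(item, str):
        return (item, None)
    return (item["regex"], item.get("status"))


def _parse_condition(condition_id: str, raw: dict) -> ConditionDefinition:
    rules = [
        SeverityRule(
            pattern=r["regex"],
            status=r["status"],
            window_words=int(r.get("window_words", raw.get("window_tokens", 8))),
        )
        for r in raw.get("severity_rules", [])
    ]
    d = ConditionDefinition(
        condition_id=condition_id,
        display_name=raw.get("display_name", condition_id),
        statuses=list(raw.get("statuses", [])),
        patterns=[_parse_pattern(p) for p in raw.get("patterns", [])],
        exclusion_patterns=list(raw.get("exclusions", [])),
        severity_rules=rules,
        icd10_codes={k: list(v) for k, v in raw.get("icd10", {}).items()},
        cci_weight=(
            {k: int(v) for k, v in raw["cci_weight"].items()}
            if "cci_weight" in raw
            else None
        ),
        ppv_only=bool(raw.get("ppv_only", False)),
        window_tokens=int(raw.get("window_tokens", 8)),
        surface_forms=list(raw.get("surface_forms", [])),
        oov_forms=list(raw.get("oov_forms", [])),
        fp_form=raw.get("fp_form"),
        severity_surface=dict(raw.get("severity_surface", {})),
        example_codes=dict(raw.get("example_codes", {})),
    )
    d.validate()
    return d


def load_condition_definitions(
    config_path: Optional[Union[str, Path]] = None,
) -> list[ConditionDefinition]:
    """Load and validate the 18 condition definitions."""
    return load_pipeline_config(config_path).definitions


def default_config_text() -> str:
    return (
        resources.files("charlson_nlp.resources")
        .joinpath("default_config.yml")
        .read_text(encoding="utf-8")
    )


def load_pipeline_config(
    config_path: Optional[Union[str, Path]] = None,
) -> PipelineConfig:
    """Load the full pipeline config (bundled default if no path given).

    Raises ``ValueError`` naming the offending condition/pattern when a regex
    does not compile, a severity status is unknown, a condition is missing,
    or tobacco/alcohol carry a CCI weight.
    """
    if config_path is None:
        text = default_config_text()
    else:
        text = Path(config_path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)

    cond_raw = raw.get("conditions", {})
    missing = [c for c in CONDITION_IDS if c not in cond_raw]
    if missing:
        raise ValueError(f"config missing conditions: {', '.join(missing)}")
    unknown = [c for c in cond_raw if c not in CONDITION_IDS]
    if unknown:
        raise ValueError(f"config names unknown conditions: {', '.join(unknown)}")
    definitions = [_parse_condition(cid, cond_raw[cid]) for cid in CONDITION_IDS]

    section_lexicon = [
        SectionLexiconEntry(pattern=e["pattern"], relevance=e["relevance"])
        for e in raw.get("sections", [])
    ]
    for e in section_lexicon:
        if e.relevance not in {"relevant", "irrelevant", "family_history"}:
            raise ValueError(f"section lexicon: bad relevance {e.relevance!r}")

    cues_raw = raw.get("cues", {})
    cue_lexicon = CueLexicon(
        negation_preceding=list(cues_raw.get("negation_preceding", [])),
        negation_following=list(cues_raw.get("negation_following", [])),
        hypothesis=list(cues_raw.get("hypothesis", [])),
        family=list(cues_raw.get("family", [])),
        scope_window_tokens=dict(
            cues_raw.get(
                "scope_window_tokens",
                {"negation": 5, "hypothesis": 6, "family": 8},
            )
        ),
        scope_terminators=list(
            cues_raw.get("scope_terminators", [".", ";", ":", "!", "?", "mais"])
        ),
    )
    cue_lexicon.validate()

    return PipelineConfig(
        definitions=definitions,
        section_lexicon=section_lexicon,
        cue_lexicon=cue_lexicon,
        config_hash=hashlib.sha256(text.encode("utf-8")).hexdigest()[:16],
    )
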