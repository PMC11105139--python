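"""Core data types: notes, condition definitions, mentions, claims, predictions.

All character spans are 0-based, half-open, and index the *raw* note text.
ICD-10 codes are normalized to dot-free uppercase form (``I21.4`` → ``I214``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

#: The 18 condition identifiers handled by the pipeline: the 16 comorbidities
#: of the Charlson index plus tobacco and alcohol consumption status.
CONDITION_IDS = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatologic_disease",
    "peptic_ulcer_disease",
    "liver_disease",
    "diabetes",
    "hemiplegia",
    "renal_disease",
    "solid_tumor",
    "leukemia",
    "lymphoma",
    "aids",
    "alcohol_consumption",
    "tobacco_consumption",
)

#: Conditions that do not enter the Charlson comorbidity index.
NON_CCI_CONDITIONS = frozenset({"alcohol_consumption", "tobacco_consumption"})

#: Marker used in stay predictions for a binary condition that is present.
PRESENT = "present"
#: Marker used in stay predictions for an absent condition.
ABSENT = "absent"

ICD10_RE = re.compile(r"[A-Z][0-9]{2}[0-9A-Z]{0,2}$")

QUALIFIERS = frozenset({"negated", "hypothetical", "family", "generic_fp"})


class NoteClass(str, Enum):
    discharge_summary = "discharge_summary"
    consultation_report = "consultation_report"


class StayType(str, Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"


@dataclass(frozen=True)
class Note:
    """One clinical note attached to a hospital stay."""

    note_id: str
    stay_id: str
    note_class: NoteClass
    stay_type: StayType
    text: str

    def __post_init__(self) -> None:
        if self.text is None:
            raise ValueError(f"note {self.note_id}: text may not be None")


@dataclass(frozen=True)
class SeverityRule:
    """Context rule assigning a status when its regex fires near the entity.

    ``window_words`` is the maximum token distance between the context match
    and the entity; the match must also lie in the same sentence.
    """

    pattern: str
    status: str
    window_words: int = 8

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass
class ConditionDefinition:
    """Machine-readable definition of one condition.

    ``statuses`` is ordered least → most severe and is empty for binary
    conditions.  ``patterns`` are inclusion regexes (matched on normalized
    text) with an optional status hint.  ``icd10_codes`` maps a status (or
    ``"any"``) to a list of dot-free code prefixes; ``cci_weight`` maps a
    status (or ``"any"``) to the Charlson weight and is absent for tobacco
    and alcohol.
    """

    condition_id: str
    display_name: str
    statuses: list[str] = field(default_factory=list)
    patterns: list[tuple[str, Optional[str]]] = field(default_factory=list)
    exclusion_patterns: list[str] = field(default_factory=list)
    severity_rules: list[SeverityRule] = field(default_factory=list)
    icd10_codes: dict[str, list[str]] = field(default_factory=dict)
    cci_weight: Optional[dict[str, int]] = None
    ppv_only: bool = False
    window_tokens: int = 8
    # Generator-facing surface realizations (see synthetic module).
    surface_forms: list[str] = field(default_factory=list)
    oov_forms: list[str] = field(default_factory=list)
    fp_form: Optional[str] = None
    severity_surface: dict[str, str] = field(default_factory=dict)
    example_codes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.condition_id not in CONDITION_IDS:
            raise ValueError(f"unknown condition id {self.condition_id!r}")
        if self.statuses and len(self.statuses) != 2:
            raise ValueError(
                f"{self.condition_id}: statuses must be empty or 2 labels, "
                f"got {self.statuses}"
            )
        for pat, hint in self.patterns:
            try:
                re.compile(pat)
            except re.error as exc:
                raise ValueError(
                    f"{self.condition_id}: pattern {pat!r} does not compile: {exc}"
                ) from exc
            if hint is not None and hint not in self.statuses:
                raise ValueError(
                    f"{self.condition_id}: pattern status hint {hint!r} not in "
                    f"statuses {self.statuses}"
                )
        for pat in self.exclusion_patterns:
            try:
                re.compile(pat)
            except re.error as exc:
                raise ValueError(
                    f"{self.condition_id}: exclusion {pat!r} does not compile: {exc}"
                ) from exc
        for rule in self.severity_rules:
            if rule.status not in self.statuses:
                raise ValueError(
                    f"{self.condition_id}: severity rule status {rule.status!r} "
                    f"not in statuses {self.statuses}"
                )
            try:
                re.compile(rule.pattern)
            except re.error as exc:
                raise ValueError(
                    f"{self.condition_id}: severity pattern {rule.pattern!r} "
                    f"does not compile: {exc}"
                ) from exc
        if self.condition_id in NON_CCI_CONDITIONS:
            if self.cci_weight is not None:
                raise ValueError(
                    f"{self.condition_id}: tobacco/alcohol carry no CCI weight"
                )
        elif self.cci_weight is None:
            raise ValueError(f"{self.condition_id}: missing cci_weight")
        else:
            for status, w in self.cci_weight.items():
                if w < 0:
                    raise ValueError(
                        f"{self.condition_id}: negative CCI weight for {status}"
                    )
        for key, prefixes in self.icd10_codes.items():
            if key != "any" and key not in self.statuses:
                raise ValueError(
                    f"{self.condition_id}: icd10 status key {key!r} unknown"
                )
            for p in prefixes:
                if not re.fullmatch(r"[A-Z][0-9]{2}[0-9A-Z]{0,2}", p):
                    raise ValueError(
                        f"{self.condition_id}: bad ICD-10 prefix {p!r}"
                    )

    def severity_index(self, status: Optional[str]) -> int:
        """Rank of a status in the least→most severe order; None ranks least."""
        if status is None:
            return -1
        return self.statuses.index(status)

    @property
    def default_status(self) -> Optional[str]:
        return self.statuses[0] if self.statuses else None


@dataclass
class Mention:
    """A condition mention located as a character span in a note."""

    mention_id: str
    note_id: str
    condition_id: str
    span: tuple[int, int]
    snippet_span: tuple[int, int]
    status: Optional[str] = None
    qualifiers: set[str] = field(default_factory=set)
    discarded: bool = False
    score: Optional[float] = None

    def __post_init__(self) -> None:
        s, e = self.span
        if not (0 <= s < e):
            raise ValueError(f"mention {self.mention_id}: bad span {self.span}")
        ss, se = self.snippet_span
        if not (ss <= s and e <= se):
            raise ValueError(
                f"mention {self.mention_id}: snippet {self.snippet_span} does "
                f"not contain span {self.span}"
            )
        unknown = self.qualifiers - QUALIFIERS
        if unknown:
            raise ValueError(
                f"mention {self.mention_id}: unknown qualifiers {unknown}"
            )


def normalize_icd10(code: str) -> str:
    """Uppercase and strip dots; raise on malformed codes."""
    norm = code.strip().upper().replace(".", "")
    if not ICD10_RE.fullmatch(norm):
        raise ValueError(f"malformed ICD-10 code {code!r}")
    return norm


@dataclass(frozen=True)
class ClaimRecord:
    """ICD-10 diagnosis codes billed for one inpatient stay."""

    stay_id: str
    codes: tuple[str, ...]

    @classmethod
    def from_raw(cls, stay_id: str, codes: list[str]) -> "ClaimRecord":
        return cls(stay_id=stay_id, codes=tuple(normalize_icd10(c) for c in codes))


@dataclass
class StayPrediction:
    """Per-stay condition map produced by a pipeline (or the gold labeling).

    ``conditions`` maps every condition id to ``"absent"``, ``"present"``
    (binary conditions) or a status label (statused conditions).
    """

    stay_id: str
    source: str  # nlp | claim | gold
    conditions: dict[str, str] = field(default_factory=dict)

    def is_present(self, condition_id: str) -> bool:
        return self.conditions.get(condition_id, ABSENT) != ABSENT

    def status_of(self, condition_id: str) -> Optional[str]:
        v = self.conditions.get(condition_id, ABSENT)
        return None if v in (ABSENT, PRESENT) else v


@dataclass
class GoldStandard:
    """Entity-level and stay-level reference labels."""

    mentions: list[Mention]
    stay_labels: dict[str, dict[str, str]]
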