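"""CLAIM comparator: stay predictions from ICD-10 diagnosis codes.

A condition is present iff any billed code starts with one of its
configured prefixes; for statused conditions, the most severe status whose
prefix list matches wins.  Intended for inpatient stays (billing codes are
attached to hospitalizations); the pipeline driver applies that filter.
"""
from __future__ import annotations

from typing import Sequence

from .types import ABSENT, PRESENT, ClaimRecord, ConditionDefinition, StayPrediction


def _matches(codes: Sequence[str], prefixes: Sequence[str]) -> bool:
    return any(code.startswith(p) for code in codes for p in prefixes)


def map_claim_codes(
    record: ClaimRecord, definitions: Sequence[ConditionDefinition]
) -> StayPrediction:
    """Map one stay's normalized codes onto the 18-condition vocabulary."""
    conditions: dict[str, str] = {}
    for d in definitions:
        if d.statuses:
            value = ABSENT
            # statuses are ordered least -> most severe; later wins
            for status in d.statuses:
                if _matches(record.codes, d.icd10_codes.get(status, [])):
                    value = status
            if value == ABSENT and _matches(record.codes, d.icd10_codes.get("any", [])):
                value = PRESENT
            conditions[d.condition_id] = value
        else:
            present = _matches(record.codes, d.icd10_codes.get("any", []))
            conditions[d.condition_id] = PRESENT if present else ABSENT
    return StayPrediction(stay_id=record.stay_id, source="claim", conditions=conditions)


def map_claims(
    records: Sequence[ClaimRecord], definitions: Sequence[ConditionDefinition]
) -> list[StayPrediction]:
    return [map_claim_codes(r, definitions) for r in records]
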