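"""Readers and writers for notes, annotations, claims and predictions.

Interchange formats: JSON-lines for notes, mentions and stay predictions;
BRAT standoff (.ann) as the annotation exchange format; CSV
(``stay_id,code``) for claim records.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .types import (
    ClaimRecord,
    Mention,
    Note,
    NoteClass,
    StayPrediction,
    StayType,
)

PathLike = Union[str, Path]

_NOTE_FIELDS = ("note_id", "stay_id", "note_class", "stay_type", "text")


@dataclass
class ReadReport:
    """Per-file error report for tolerant readers."""

    n_read: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (line, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_notes(
    path: PathLike, dialect: str = "jsonl"
) -> tuple[list[Note], ReadReport]:
    """Read a JSONL note corpus; malformed records go to the error report.

    A duplicate ``note_id`` is a hard failure.
    """
    if dialect != "jsonl":
        raise ValueError(f"unknown notes dialect {dialect!r}")
    notes: list[Note] = []
    report = ReadReport()
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                report.rejected.append((lineno, f"invalid JSON: {exc.msg}"))
                continue
            missing = [f for f in _NOTE_FIELDS if f not in rec]
            if missing:
                report.rejected.append(
                    (lineno, f"missing required field(s): {', '.join(missing)}")
                )
                continue
            if rec["note_id"] in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate note_id {rec['note_id']!r}"
                )
            seen.add(rec["note_id"])
            notes.append(
                Note(
                    note_id=rec["note_id"],
                    stay_id=rec["stay_id"],
                    note_class=NoteClass(rec["note_class"]),
                    stay_type=StayType(rec["stay_type"]),
                    text=rec["text"],
                )
            )
            report.n_read += 1
    return notes, report


def write_notes(notes: Iterable[Note], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "stay_id": n.stay_id,
                        "note_class": n.note_class.value,
                        "stay_type": n.stay_type.value,
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

_QUALIFIER_ATTR = {
    "Negation": "negated",
    "Hypothesis": "hypothetical",
    "Family": "family",
    "GenericFP": "generic_fp",
}
_ATTR_FOR_QUALIFIER = {v: k for k, v in _QUALIFIER_ATTR.items()}


def write_standoff_annotations(
    mentions: Iterable[Mention], notes: dict[str, Note], path: PathLike
) -> None:
    """Write mentions of one or more notes as BRAT standoff.

    Multi-note corpora are serialized into a single .ann file with a
    ``#note`` comment line scoping subsequent T-lines to a note.
    """
    by_note: dict[str, list[Mention]] = {}
    for m in mentions:
        by_note.setdefault(m.note_id, []).append(m)
    with open(path, "w", encoding="utf-8") as fh:
        for note_id in sorted(by_note):
            fh.write(f"#note {note_id}\n")
            text = notes[note_id].text
            a_counter = 1
            for t_counter, m in enumerate(
                sorted(by_note[note_id], key=lambda x: (x.span, x.mention_id)), 1
            ):
                s, e = m.span
                surface = text[s:e].replace("\n", " ")
                fh.write(f"T{t_counter}\t{m.condition_id} {s} {e}\t{surface}\n")
                fh.write(
                    f"#snippet T{t_counter} {m.snippet_span[0]} {m.snippet_span[1]}"
                    f" {m.mention_id}\n"
                )
                if m.status is not None:
                    fh.write(f"A{a_counter}\tStatus T{t_counter} {m.status}\n")
                    a_counter += 1
                for q in sorted(m.qualifiers):
                    fh.write(f"A{a_counter}\t{_ATTR_FOR_QUALIFIER[q]} T{t_counter}\n")
                    a_counter += 1
                if m.score is not None:
                    fh.write(f"A{a_counter}\tScore T{t_counter} {m.score!r}\n")
                    a_counter += 1


def read_standoff_annotations(
    ann_path: PathLike, notes: Iterable[Note]
) -> list[Mention]:
    """Parse a BRAT standoff file back into mentions.

    A T-line whose quoted surface does not equal the note's text slice is a
    hard failure naming the mention.
    """
    note_map = {n.note_id: n for n in notes}
    mentions: list[Mention] = []
    current_note: Optional[str] = None
    by_tid: dict[str, Mention] = {}
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#note "):
                current_note = line[len("#note ") :].strip()
                by_tid = {}
                if current_note not in note_map:
                    raise ValueError(
                        f"{ann_path}:{lineno}: unknown note {current_note!r}"
                    )
                continue
            if line.startswith("#snippet "):
                _tag, tid, ss, se, mention_id = line.split(" ", 4)
                m = by_tid[tid]
                m.mention_id = mention_id
                object.__setattr__(m, "snippet_span", (int(ss), int(se)))
                continue
            if line.startswith("T"):
                tid, body, surface = line.split("\t", 2)
                label, s, e = body.rsplit(" ", 2)
                s, e = int(s), int(e)
                if current_note is None:
                    raise ValueError(f"{ann_path}:{lineno}: T-line before #note")
                text = note_map[current_note].text
                if text[s:e].replace("\n", " ") != surface:
                    raise ValueError(
                        f"{ann_path}:{lineno}: surface mismatch for {tid}: "
                        f"{surface!r} != {text[s:e]!r}"
                    )
                m = Mention(
                    mention_id=f"{current_note}:{tid}",
                    note_id=current_note,
                    condition_id=label,
                    span=(s, e),
                    snippet_span=(s, e),
                )
                by_tid[tid] = m
                mentions.append(m)
                continue
            if line.startswith("A"):
                _aid, body = line.split("\t", 1)
                parts = body.split(" ")
                attr, tid = parts[0], parts[1]
                m = by_tid[tid]
                if attr == "Status":
                    m.status = parts[2]
                elif attr == "Score":
                    m.score = float(parts[2])
                elif attr in _QUALIFIER_ATTR:
                    m.qualifiers.add(_QUALIFIER_ATTR[attr])
                    m.discarded = True
                else:
                    raise ValueError(f"{ann_path}:{lineno}: unknown attribute {attr}")
                continue
            raise ValueError(f"{ann_path}:{lineno}: unparseable line {line!r}")
    ids = [m.mention_id for m in mentions]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{ann_path}: duplicate mention ids")
    return mentions


# ---------------------------------------------------------------------------
# JSONL mentions dialect (round-trip exact)
# ---------------------------------------------------------------------------


def write_mentions(mentions: Iterable[Mention], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"format": "charlson-nlp/mentions", "version": 1}) + "\n")
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "mention_id": m.mention_id,
                        "note_id": m.note_id,
                        "condition_id": m.condition_id,
                        "span": list(m.span),
                        "snippet_span": list(m.snippet_span),
                        "status": m.status,
                        "qualifiers": sorted(m.qualifiers),
                        "discarded": m.discarded,
                        "score": m.score,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_mentions(path: PathLike) -> list[Mention]:
    mentions: list[Mention] = []
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "charlson-nlp/mentions":
            raise ValueError(f"{path}: not a mentions file")
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            mentions.append(
                Mention(
                    mention_id=rec["mention_id"],
                    note_id=rec["note_id"],
                    condition_id=rec["condition_id"],
                    span=tuple(rec["span"]),
                    snippet_span=tuple(rec["snippet_span"]),
                    status=rec["status"],
                    qualifiers=set(rec["qualifiers"]),
                    discarded=rec["discarded"],
                    score=rec["score"],
                )
            )
    ids = [m.mention_id for m in mentions]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: duplicate mention ids")
    return mentions


def write_stay_predictions(preds: Iterable[StayPrediction], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            json.dumps({"format": "charlson-nlp/stay_predictions", "version": 1}) + "\n"
        )
        for p in preds:
            fh.write(
                json.dumps(
                    {"stay_id": p.stay_id, "source": p.source, "conditions": p.conditions},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_stay_predictions(path: PathLike) -> list[StayPrediction]:
    preds: list[StayPrediction] = []
    with open(path, encoding="utf-8") as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "charlson-nlp/stay_predictions":
            raise ValueError(f"{path}: not a stay-predictions file")
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            preds.append(
                StayPrediction(
                    stay_id=rec["stay_id"],
                    source=rec["source"],
                    conditions=dict(rec["conditions"]),
                )
            )
    return preds


# ---------------------------------------------------------------------------
# Claims
# ---------------------------------------------------------------------------


def read_claims(path: PathLike) -> list[ClaimRecord]:
    """Read ``stay_id,code`` CSV rows into one record per stay."""
    codes_by_stay: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"stay_id", "code"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: claim CSV needs columns stay_id, code")
        for row in reader:
            stay = row["stay_id"]
            if stay not in codes_by_stay:
                codes_by_stay[stay] = []
                order.append(stay)
            if row["code"]:
                codes_by_stay[stay].append(row["code"])
    return [ClaimRecord.from_raw(s, codes_by_stay[s]) for s in order]


def write_claims(records: Iterable[ClaimRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["stay_id", "code"])
        for rec in records:
            if not rec.codes:
                writer.writerow([rec.stay_id, ""])
            for code in rec.codes:
                writer.writerow([rec.stay_id, code])
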