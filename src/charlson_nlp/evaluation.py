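"""Entity- and stay-level scoring against gold standards.

Entity level: a prediction is correct iff it overlaps (shares at least one
raw character with) a gold mention of the same condition.  Stay level:
per-stay presence/status confusion with true negatives defined.  Metrics
are percentages; a zero-denominator metric is *undefined* (None), never 0.
Confidence intervals come from a percentile bootstrap resampling stays.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import ConditionDefinition, Mention, StayPrediction

METRICS = ("f1", "ppv", "sensitivity", "specificity")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: Optional[int] = None  # undefined at entity level

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        tn = None if self.tn is None or other.tn is None else self.tn + other.tn
        return ConfusionCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn, tn=tn
        )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def match_entities(
    predicted: Sequence[Mention],
    gold: Sequence[Mention],
    condition_id: str,
    require_status: bool = False,
    status: Optional[str] = None,
) -> ConfusionCounts:
    """Overlap-based entity confusion for one condition.

    Each prediction is judged independently: k predictions overlapping one
    gold mention contribute k true positives and no false negative.  If
    ``status`` is given, both sets are first restricted to that status;
    otherwise ``require_status`` demands status equality on the overlap.
    """

    def eligible(m: Mention) -> bool:
        return m.condition_id == condition_id and (status is None or m.status == status)

    preds = [m for m in predicted if eligible(m)]
    golds = [m for m in gold if eligible(m)]
    gold_by_note: dict[str, list[Mention]] = {}
    for g in golds:
        gold_by_note.setdefault(g.note_id, []).append(g)

    counts = ConfusionCounts()
    matched_gold: set[int] = set()
    for p in preds:
        hit = False
        for g in gold_by_note.get(p.note_id, []):
            if _overlap(p.span, g.span) and (
                not require_status or p.status == g.status
            ):
                hit = True
                matched_gold.add(id(g))
        if hit:
            counts.tp += 1
        else:
            counts.fp += 1
    counts.fn = sum(1 for g in golds if id(g) not in matched_gold)
    return counts


def stay_confusion(
    predictions: Sequence[StayPrediction],
    gold_labels: dict[str, dict[str, str]],
    condition_id: str,
    status: Optional[str] = None,
) -> ConfusionCounts:
    """Per-stay confusion with true negatives.

    ``status=None`` scores presence whatever the status ("Any" scope);
    a specific status scores that status as its own binary problem.
    The stay universe is the gold standard's; stays without a prediction
    count as predicted-absent.
    """
    pred_by_stay = {p.stay_id: p for p in predictions}
    counts = ConfusionCounts(tn=0)
    for stay_id, labels in gold_labels.items():
        gold_value = labels.get(condition_id, "absent")
        p = pred_by_stay.get(stay_id)
        pred_value = p.conditions.get(condition_id, "absent") if p else "absent"
        if status is None:
            gold_pos = gold_value != "absent"
            pred_pos = pred_value != "absent"
        else:
            gold_pos = gold_value == status
            pred_pos = pred_value == status
        if gold_pos and pred_pos:
            counts.tp += 1
        elif gold_pos:
            counts.fn += 1
        elif pred_pos:
            counts.fp += 1
        else:
            counts.tn = (counts.tn or 0) + 1
    return counts


def compute_metrics(counts: ConfusionCounts) -> dict[str, Optional[float]]:
    """PPV, sensitivity, specificity and F1 as percentages (None = undefined)."""
    ppv = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    se = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    if counts.tn is None:
        sp = None
    else:
        denom = counts.tn + counts.fp
        sp = 100.0 * counts.tn / denom if denom else None
    if ppv is None or se is None or ppv + se == 0:
        f1 = None
    else:
        f1 = 2 * ppv * se / (ppv + se)
    return {"f1": f1, "ppv": ppv, "sensitivity": se, "specificity": sp}


@dataclass
class MetricsRow:
    scope: str  # condition | status | any | average
    condition_id: str
    level: str  # entity | stay
    status: Optional[str] = None
    f1: Optional[float] = None
    ppv: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    support: int = 0
    counts: Optional[ConfusionCounts] = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    ppv_only: bool = False

    @classmethod
    def from_counts(
        cls,
        scope: str,
        condition_id: str,
        level: str,
        counts: ConfusionCounts,
        status: Optional[str] = None,
        ppv_only: bool = False,
    ) -> "MetricsRow":
        metrics = compute_metrics(counts)
        if ppv_only:
            metrics = {"f1": None, "ppv": metrics["ppv"], "sensitivity": None, "specificity": None}
        return cls(
            scope=scope,
            condition_id=condition_id,
            level=level,
            status=status,
            support=counts.tp + counts.fn,
            counts=counts,
            ppv_only=ppv_only,
            **metrics,
        )


@dataclass
class MetricsReport:
    rows: list[MetricsRow]
    micro: Optional[MetricsRow] = None
    macro: Optional[MetricsRow] = None
    weighted: Optional[MetricsRow] = None
    excluded_conditions: list[str] = field(default_factory=list)
    level: str = "stay"

    def row_for(self, condition_id: str, status: Optional[str] = None) -> MetricsRow:
        for r in self.rows:
            if r.condition_id == condition_id and r.status == status:
                return r
        raise KeyError((condition_id, status))

    def to_frame(self) -> pd.DataFrame:
        records = []
        all_rows = list(self.rows)
        for name, row in (("micro", self.micro), ("macro", self.macro), ("weighted", self.weighted)):
            if row is not None:
                all_rows.append(row)
        for r in all_rows:
            rec = {
                "condition": r.condition_id,
                "status": r.status or "",
                "scope": r.scope,
                "level": r.level,
                "support": r.support,
                "ppv_only": r.ppv_only,
            }
            for m in METRICS:
                v = getattr(r, m)
                rec[m] = round_display(v) if v is not None else None
                lo_hi = r.ci.get(m)
                rec[f"{m}_ci_low"] = round_display(lo_hi[0]) if lo_hi else None
                rec[f"{m}_ci_high"] = round_display(lo_hi[1]) if lo_hi else None
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_json_dict(self) -> dict:
        def row_dict(r: MetricsRow) -> dict:
            return {
                "condition": r.condition_id,
                "status": r.status,
                "scope": r.scope,
                "level": r.level,
                "support": r.support,
                "ppv_only": r.ppv_only,
                **{m: getattr(r, m) for m in METRICS},
                "ci": {k: list(v) for k, v in r.ci.items()},
            }

        return {
            "level": self.level,
            "rows": [row_dict(r) for r in self.rows],
            "micro": row_dict(self.micro) if self.micro else None,
            "macro": row_dict(self.macro) if self.macro else None,
            "weighted": row_dict(self.weighted) if self.weighted else None,
            "excluded_conditions": self.excluded_conditions,
        }


def round_display(value: float) -> float:
    """Round half-up to one decimal for display (raw values kept in JSON)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def average_metrics(rows: Sequence[MetricsRow], level: str) -> tuple[MetricsRow, MetricsRow, MetricsRow]:
    """Micro (summed counts), macro (unweighted) and support-weighted averages.

    Rows flagged ppv_only must be excluded by the caller.  Undefined per-row
    metrics are skipped from macro/weighted means; the micro average is
    computed on the summed confusion counts.
    """
    total = ConfusionCounts(tn=0 if level == "stay" else None)
    for r in rows:
        assert r.counts is not None
        total = total + r.counts
    micro = MetricsRow.from_counts("average", "micro_average", level, total)

    macro = MetricsRow(scope="average", condition_id="macro_average", level=level)
    weighted = MetricsRow(scope="average", condition_id="weighted_average", level=level)
    for m in METRICS:
        defined = [(getattr(r, m), r.support) for r in rows if getattr(r, m) is not None]
        if defined:
            setattr(macro, m, float(np.mean([v for v, _ in defined])))
            wsum = sum(w for _, w in defined)
            if wsum > 0:
                setattr(weighted, m, sum(v * w for v, w in defined) / wsum)
    macro.support = weighted.support = sum(r.support for r in rows)
    return micro, macro, weighted


def bootstrap_ci(
    units: Sequence,
    metric_fn: Callable[[Sequence], dict[str, Optional[float]]],
    reps: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[dict[str, tuple[float, float]], dict[str, int]]:
    """Percentile bootstrap over resampled units (stays).

    Returns (intervals, skipped) where ``skipped[metric]`` counts resamples
    on which the metric was undefined.  Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(units)
    values: dict[str, list[float]] = {}
    skipped: dict[str, int] = {}
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        sample = [units[i] for i in idx]
        for name, v in metric_fn(sample).items():
            if v is None:
                skipped[name] = skipped.get(name, 0) + 1
            else:
                values.setdefault(name, []).append(v)
    alpha = (1.0 - level) / 2.0
    intervals = {
        name: (
            float(np.percentile(vs, 100 * alpha)),
            float(np.percentile(vs, 100 * (1 - alpha))),
        )
        for name, vs in values.items()
    }
    return intervals, skipped


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def _stay_units(gold_labels: dict[str, dict[str, str]]) -> list[str]:
    return sorted(gold_labels)


def evaluate_pipeline(
    predictions,
    gold,
    definitions: Sequence[ConditionDefinition],
    level: str = "stay",
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> MetricsReport:
    """Full per-condition report at the entity or stay level.

    Entity level: ``predictions`` and ``gold`` are kept (non-discarded)
    mention lists; specificity is undefined (no entity-level TN universe).
    Stay level: ``predictions`` is a list of stay predictions and ``gold``
    a mapping stay_id -> condition -> label; optional percentile-bootstrap
    CIs resample stays.

    Statused conditions expand to one row per status plus an "Any" row;
    PPV-only conditions report PPV alone and are excluded from the averages.
    """
    rows: list[MetricsRow] = []
    average_rows: list[MetricsRow] = []
    excluded: list[str] = []

    def confusion(condition_id: str, status: Optional[str]) -> ConfusionCounts:
        if level == "entity":
            return match_entities(
                predictions, gold, condition_id,
                require_status=status is not None, status=status,
            )
        return stay_confusion(predictions, gold, condition_id, status=status)

    for d in definitions:
        if d.ppv_only:
            excluded.append(d.condition_id)
        if d.statuses:
            for status in d.statuses:
                rows.append(
                    MetricsRow.from_counts(
                        "status", d.condition_id, level,
                        confusion(d.condition_id, status),
                        status=status, ppv_only=d.ppv_only,
                    )
                )
            any_row = MetricsRow.from_counts(
                "any", d.condition_id, level,
                confusion(d.condition_id, None), ppv_only=d.ppv_only,
            )
            rows.append(any_row)
        else:
            any_row = MetricsRow.from_counts(
                "condition", d.condition_id, level,
                confusion(d.condition_id, None), ppv_only=d.ppv_only,
            )
            rows.append(any_row)
        if not d.ppv_only:
            average_rows.append(any_row)

    micro, macro, weighted = average_metrics(average_rows, level)

    if bootstrap_reps > 0 and level == "stay":
        stay_ids = _stay_units(gold)
        pred_by_stay = {p.stay_id: p for p in predictions}

        for row in rows:
            if row.ppv_only:
                continue

            def metric_fn(sample_ids, _c=row.condition_id, _s=row.status):
                labels = {f"s{i}": gold[sid] for i, sid in enumerate(sample_ids)}
                preds = [
                    StayPrediction(
                        stay_id=f"s{i}",
                        source="nlp",
                        conditions=pred_by_stay[sid].conditions
                        if sid in pred_by_stay
                        else {},
                    )
                    for i, sid in enumerate(sample_ids)
                ]
                return compute_metrics(stay_confusion(preds, labels, _c, status=_s))

            row.ci, _ = bootstrap_ci(stay_ids, metric_fn, reps=bootstrap_reps, seed=seed)

    report = MetricsReport(
        rows=rows,
        micro=micro,
        macro=macro,
        weighted=weighted,
        excluded_conditions=excluded,
        level=level,
    )
    return report


def compare_pipelines(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Side-by-side comparison with a per-(row, metric) best-pipeline flag.

    Returns a frame indexed by (condition, status) with one column per
    (metric, pipeline) plus ``<metric>_best`` columns naming the best
    pipeline(s), ties included.
    """
    names = list(reports)
    keys: list[tuple[str, str]] = []
    for rep in reports.values():
        for r in rep.rows:
            key = (r.condition_id, r.status or "")
            if key not in keys:
                keys.append(key)
    records = []
    for cond, status in keys:
        rec: dict = {"condition": cond, "status": status}
        for m in METRICS:
            best_val = None
            for name in names:
                try:
                    row = reports[name].row_for(cond, status or None)
                    v = getattr(row, m)
                except KeyError:
                    v = None
                rec[f"{m}_{name}"] = round_display(v) if v is not None else None
                if v is not None and (best_val is None or v > best_val):
                    best_val = v
            winners = [
                name
                for name in names
                if rec[f"{m}_{name}"] is not None
                and best_val is not None
                and abs((reports[name].row_for(cond, status or None).__getattribute__(m)) - best_val) < 1e-9
            ]
            rec[f"{m}_best"] = "|".join(winners)
        records.append(rec)
    return pd.DataFrame.from_records(records)
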