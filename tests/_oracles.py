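"""Independent brute-force oracles used by several test modules.

These deliberately re-implement contracts in the most literal way possible
(enumerate everything, no shared code with the package) so the tests are a
genuine cross-check.
"""
from __future__ import annotations


def cue_scope_oracle(
    tokens: list[str],
    entity: tuple[int, int],
    cues: list[list[str]],
    window: int,
    terminators: set[str],
    side: str,
) -> bool:
    """Literal enumeration of every (cue occurrence, entity) pair.

    side: 'before', 'after' or 'both'.  A cue is in scope iff the number of
    tokens strictly between cue and entity is <= window and none of those
    tokens is a terminator.
    """
    e_first, e_last = entity
    n = len(tokens)
    for cue in cues:
        k = len(cue)
        for start in range(0, n - k + 1):
            if tokens[start : start + k] != cue:
                continue
            end = start + k - 1
            if side in ("before", "both") and end < e_first:
                between = tokens[end + 1 : e_first]
                if len(between) <= window and not any(t in terminators for t in between):
                    return True
            if side in ("after", "both") and start > e_last:
                between = tokens[e_last + 1 : start]
                if len(between) <= window and not any(t in terminators for t in between):
                    return True
    return False


def entity_match_oracle(predicted, gold):
    """All-pairs overlap enumeration for entity-level confusion.

    ``predicted`` and ``gold`` are lists of (note_id, start, end).  Returns
    (tp, fp, fn) under the judged-independently rule.
    """
    def overlap(a, b):
        return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]

    tp = sum(1 for p in predicted if any(overlap(p, g) for g in gold))
    fp = len(predicted) - tp
    fn = sum(1 for g in gold if not any(overlap(p, g) for p in predicted))
    return tp, fp, fn


def metrics_oracle(tp: int, fp: int, fn: int, tn):
    """Second, independent implementation of the percentage metrics."""
    ppv = None if tp + fp == 0 else 100.0 * tp / (tp + fp)
    se = None if tp + fn == 0 else 100.0 * tp / (tp + fn)
    sp = None
    if tn is not None and tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    f1 = None
    if ppv is not None and se is not None and ppv + se > 0:
        f1 = 2.0 * ppv * se / (ppv + se)
    return {"f1": f1, "ppv": ppv, "sensitivity": se, "specificity": sp}
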