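"""Recall-precision evaluation of ranked candidate regulations.

A prediction at threshold t is the set of candidate pairs with confidence
strictly above t. Against a gold-standard edge set this yields TP/FP/FN and

    recall = TP / (TP + FN),    precision = TP / (TP + FP).

The recall-precision curve takes one point per distinct positive confidence
value (tied pairs enter together); zero-confidence pairs - removed
regulations - are never predicted, which truncates the achievable recall.
The area under the curve (AURPC) integrates precision over recall by the
trapezoidal rule across the recall-increasing points, with the leading
segment extended horizontally from (0, P_first); an optional Davis-Goadrich
mode interpolates TP/FP counts nonlinearly between those points instead.

Self-pairs never exist in a ConfidenceMatrix, and pairs whose regulator is
an indicator element are excluded here (inside evaluation, not inference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import GoldStandardNetwork
from .exceptions import ValidationError

__all__ = ["PRPoint", "confusion_at_threshold", "pr_curve", "aurpc"]


@dataclass
class PRPoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float


def _scores_of(matrix) -> dict:
    """{(regulator, target): confidence} over evaluable candidate pairs."""
    if hasattr(matrix, "gene_pair_scores"):
        return matrix.gene_pair_scores()
    return {(str(r), str(t)): float(c) for (r, t), c in dict(matrix).items()}


def _check_gold(scores: dict, gold: GoldStandardNetwork) -> None:
    universe = set()
    for reg, tgt in scores:
        universe.add(reg)
        universe.add(tgt)
    unknown = gold.genes - universe
    if unknown:
        raise ValidationError(
            f"gold standard references unknown genes: {sorted(unknown)[:5]}"
        )


def confusion_at_threshold(matrix, gold: GoldStandardNetwork, threshold: float):
    """(TP, FP, FN) of the network predicted at ``confidence > threshold``."""
    scores = _scores_of(matrix)
    _check_gold(scores, gold)
    predicted = {pair for pair, c in scores.items() if c > threshold}
    tp = len(predicted & gold.edges)
    fp = len(predicted) - tp
    fn = len(gold.edges) - tp
    return tp, fp, fn


def pr_curve(matrix, gold: GoldStandardNetwork) -> list[PRPoint]:
    """One PRPoint per distinct positive confidence value, descending."""
    scores = _scores_of(matrix)
    _check_gold(scores, gold)
    if len(gold.edges) == 0:
        raise ValidationError("gold standard has no edges")
    n_gold = len(gold.edges)
    ranked = sorted(
        ((c, pair) for pair, c in scores.items() if c > 0), key=lambda x: -x[0]
    )
    points = []
    tp = fp = 0
    i = 0
    while i < len(ranked):
        c = ranked[i][0]
        while i < len(ranked) and ranked[i][0] == c:  # ties enter together
            if ranked[i][1] in gold.edges:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append(
            PRPoint(
                threshold=c,
                tp=tp,
                fp=fp,
                fn=n_gold - tp,
                recall=tp / n_gold,
                precision=tp / (tp + fp),
            )
        )
    return points


def aurpc(matrix, gold: GoldStandardNetwork, davis_goadrich: bool = False) -> float:
    """Area under the recall-precision curve, in [0, 1].

    Integrates over recall from 0 up to the maximum achieved recall (removed
    and zero-confidence pairs are never predicted, so they truncate it).
    """
    points = pr_curve(matrix, gold)
    kept = []
    last_recall = 0.0
    for pt in points:
        if pt.recall > last_recall:
            kept.append(pt)
            last_recall = pt.recall
    if not kept:
        return 0.0
    area = kept[0].recall * kept[0].precision
    n_gold = kept[0].tp + kept[0].fn
    for prev, cur in zip(kept, kept[1:]):
        if not davis_goadrich:
            area += (cur.recall - prev.recall) * (cur.precision + prev.precision) / 2.0
        else:
            # Davis & Goadrich: interpolate TP/FP linearly between the points
            dtp = cur.tp - prev.tp
            dfp = cur.fp - prev.fp
            for step in range(1, dtp + 1):
                tp_i = prev.tp + step
                fp_i = prev.fp + dfp * step / dtp
                area += (1.0 / n_gold) * (tp_i / (tp_i + fp_i))
    return float(area)
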