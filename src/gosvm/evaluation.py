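"""Precision/recall machinery and the per-gene confidence ("gene precision") score.

A prediction rule is "probability ≥ threshold ⇒ predicted positive"; ties
share a fate because thresholds operate on values, not ranks.  Category
performance is the precision attainable at fixed recall (0.2/0.3/0.4),
computed per test fold and averaged over the four folds.  An un-annotated
gene's confidence in a fold is the best precision the classifier can reach
at any threshold not exceeding the gene's probability — the operating points
at which the gene would actually be called positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_RECALL_LEVELS = (0.2, 0.3, 0.4)
#: recall grid used for vertical averaging of fold curves
DEFAULT_RECALL_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass
class PRCurve:
    """One precision/recall point per distinct probability threshold.

    Thresholds are strictly descending; recall is non-decreasing along the
    curve and reaches 1 at the lowest threshold.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray

    def __post_init__(self) -> None:
        if not (np.diff(self.thresholds) < 0).all():
            raise ValueError("thresholds must be strictly descending")
        if self.recall[-1] != 1.0:
            raise ValueError("recall must end at 1")


@dataclass
class CategoryPerformance:
    """Per-fold and fold-averaged precision-at-recall for one category."""

    term_id: str
    per_fold_prec_at: dict[float, list[float]]
    mean_prec_at: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean_prec_at = {
            r: float(np.mean(v)) for r, v in self.per_fold_prec_at.items()
        }


@dataclass
class GenePrecisionRecord:
    """Per-fold and mean gene-precision scores for one (row, category) pair."""

    term_id: str
    row: int
    per_fold_score: list[float]
    per_fold_prob: list[float]
    mean_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_score = float(np.mean(self.per_fold_score))


def pr_points(probs: Sequence[float], labels: Sequence[float]) -> PRCurve:
    """Precision/recall at every distinct probability value.

    At threshold t the predicted-positive set is {i : p_i ≥ t}; precision is
    TP/PP and recall TP/P.  Equal probabilities collapse into one point.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float) > 0
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("fold contains no positives")
    order = np.argsort(-p, kind="stable")
    p_sorted = p[order]
    tp = np.cumsum(y[order])
    pp = np.arange(1, p.size + 1)
    # last index of each tie block = the point where the whole block is in
    distinct = np.flatnonzero(np.r_[p_sorted[1:] != p_sorted[:-1], True])
    thresholds = p_sorted[distinct]
    precision = tp[distinct] / pp[distinct]
    recall = tp[distinct] / n_pos
    return PRCurve(thresholds=thresholds, precision=precision, recall=recall)


def precision_at_recall(curve: PRCurve, r: float, *, mode: str = "max") -> float:
    """Precision attainable at recall ≥ r.

    ``mode="max"`` (default): the maximum precision over all thresholds whose
    recall reaches r.  ``mode="threshold"``: the precision at the largest
    (most conservative) threshold attaining recall ≥ r.
    """
    if not (0.0 < r <= 1.0):
        raise ValueError("recall level must lie in (0, 1]")
    ok = curve.recall >= r
    if mode == "max":
        return float(curve.precision[ok].max())
    if mode == "threshold":
        return float(curve.precision[np.flatnonzero(ok)[0]])
    raise ValueError(f"unknown mode {mode!r}")


def vertical_average(
    curves: Sequence[PRCurve], grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Average fold curves pointwise in precision at common recall values.

    Each curve is evaluated on the recall grid by linear interpolation in
    recall (constant extension below its smallest recall), then precision is
    averaged across curves.  Returns (grid, mean precision).
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves to average")
    grid = DEFAULT_RECALL_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty recall grid")
    stack = np.vstack([
        np.interp(grid, c.recall, c.precision) for c in curves
    ])
    return grid, stack.mean(axis=0)


def gene_precision(p_gene: float, curve: PRCurve) -> float:
    """Best precision at any threshold ≤ the gene's probability estimate.

    A gene enters the predicted-positive set only at thresholds below its
    own probability, so this is the best operating precision under which the
    gene would be called.  If no curve threshold lies at or below p_gene the
    gene is never called and the score is 0.
    """
    if not (0.0 < p_gene < 1.0):
        raise ValueError("probability estimate must lie in (0, 1)")
    ok = curve.thresholds <= p_gene
    if not ok.any():
        return 0.0
    return float(curve.precision[ok].max())


def summarize_category(
    term_id: str,
    fold_probs: Sequence[tuple[Sequence[float], Sequence[float]]],
    unlabeled_fold_probs: Mapping[int, Sequence[float]] | None = None,
    recall_levels: Iterable[float] = DEFAULT_RECALL_LEVELS,
) -> tuple[CategoryPerformance, list[GenePrecisionRecord], list[PRCurve]]:
    """Fold-wise PR analysis for one category.

    ``fold_probs``: per fold, (mean probabilities, ±1 labels) of its test
    genes.  ``unlabeled_fold_probs``: per un-annotated row, its 4 per-fold
    mean probabilities.  Returns the category performance, one gene-precision
    record per un-annotated row, and the 4 fold PR curves.
    """
    if len(fold_probs) != 4:
        raise ValueError("expected exactly 4 folds")
    curves = [pr_points(p, y) for p, y in fold_probs]
    per_fold = {
        float(r): [precision_at_recall(c, r) for c in curves]
        for r in recall_levels
    }
    performance = CategoryPerformance(term_id=term_id, per_fold_prec_at=per_fold)
    records: list[GenePrecisionRecord] = []
    if unlabeled_fold_probs:
        for row in sorted(unlabeled_fold_probs):
            probs = list(unlabeled_fold_probs[row])
            if len(probs) != 4:
                raise ValueError(f"row {row}: expected 4 per-fold probabilities")
            scores = [gene_precision(p, c) for p, c in zip(probs, curves)]
            records.append(GenePrecisionRecord(
                term_id=term_id, row=row, per_fold_score=scores, per_fold_prob=probs,
            ))
    return performance, records, curves
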