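"""Evaluation of ranked edge predictions against a gold standard.

AUROC is computed with the Mann-Whitney rank statistic under the midrank
tie convention (each tied positive-negative pair contributes half a
concordance).  AUPR uses step-wise interpolation over the ranked list,
processing tied scores as a single block.  Eligible pairs missing from a
prediction list are appended below every listed pair as one tied block,
the DREAM convention for truncated submissions.

The DREAM Overall Score is ``-1/2 * log10(P_AUPR * P_AUROC)`` over
geometric-mean p-values; since the challenge's null probability densities
are external artifacts, :func:`overall_score` takes p-values as inputs and
:func:`permutation_pvalues` estimates empirical ones by shuffling edge
labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "GoldStandard",
    "EvaluationResult",
    "evaluate",
    "auroc_from_labels",
    "aupr_from_labels",
    "overall_score",
    "geometric_mean",
    "permutation_pvalues",
]


@dataclass(frozen=True)
class GoldStandard:
    """Known regulator->target interactions.

    ``positives`` is the set of true directed edges.  ``eligible_pairs``,
    when given, is the explicit universe of scorable pairs; otherwise the
    universe defaults to all non-self (regulator, gene) pairs over the ids
    seen in the positives, with regulators the ids that appear as edge
    sources.
    """

    positives: frozenset
    eligible_pairs: frozenset | None = None

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(map(tuple, self.positives)))
        if self.eligible_pairs is not None:
            object.__setattr__(
                self, "eligible_pairs", frozenset(map(tuple, self.eligible_pairs))
            )
        for r, t in self.positives:
            if r == t:
                raise ValidationError(f"gold standard contains self-edge {r!r}")
        if self.eligible_pairs is not None:
            stray = self.positives - self.eligible_pairs
            if stray:
                raise ValidationError(
                    f"{len(stray)} gold positives fall outside the eligible universe"
                )

    def universe(self) -> frozenset:
        """The eligible universe, materializing the default when absent."""
        if self.eligible_pairs is not None:
            return self.eligible_pairs
        regulators = {r for r, _ in self.positives}
        genes = {g for edge in self.positives for g in edge}
        return frozenset(
            (r, g) for r in regulators for g in genes if r != g
        )


@dataclass(frozen=True)
class EvaluationResult:
    """AUPR/AUROC of a ranked edge list, with the underlying curves.

    ``pr_curve`` is ``(recall, precision)`` and ``roc_curve`` is
    ``(fpr, tpr)``, both evaluated at the ends of tied-score blocks in
    rank order.
    """

    aupr: float
    auroc: float
    n_positives: int
    n_negatives: int
    pr_curve: tuple
    roc_curve: tuple


def auroc_from_labels(scores, labels) -> float:
    """Mann-Whitney AUROC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined without both positives and negatives")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _pr_points(scores, labels):
    """Cumulative (tp, fp) at the end of each tied-score block, descending."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    # indices where a block of equal scores ends
    block_end = np.nonzero(np.diff(s) != 0)[0]
    block_end = np.append(block_end, s.size - 1)
    tp = np.cumsum(lab)[block_end].astype(float)
    fp = (block_end + 1) - tp
    return tp, fp


def aupr_from_labels(scores, labels) -> float:
    """Step-wise AUPR; tied scores are processed as one block."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise UndefinedMetricError("AUPR undefined without both positives and negatives")
    tp, fp = _pr_points(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    return float(np.sum(np.diff(recall, prepend=0.0) * precision))


def _scores_and_labels(predictions, gold: GoldStandard):
    """Align a ranked edge list with the eligible universe.

    Listed pairs keep their scores; eligible pairs absent from the list
    form one tied block strictly below every listed score.  Prediction
    pairs outside the universe are rejected.
    """
    if isinstance(predictions, pd.DataFrame):
        rows = predictions[["regulator", "target", "score"]].itertuples(index=False)
    else:
        rows = predictions
    listed = {}
    for r, t, s in rows:
        key = (r, t)
        if key in listed:
            raise ValidationError(f"duplicate prediction for pair {key}")
        listed[key] = float(s)
    universe = gold.universe()
    stray = set(listed) - universe
    if stray:
        raise ValidationError(
            f"{len(stray)} predicted pairs are outside the eligible universe, "
            f"e.g. {sorted(stray)[:3]}"
        )
    floor = min(listed.values()) - 1.0 if listed else 0.0
    pairs = sorted(universe)
    scores = np.array([listed.get(pair, floor) for pair in pairs])
    labels = np.array([pair in gold.positives for pair in pairs])
    return scores, labels


def evaluate(predictions, gold: GoldStandard) -> EvaluationResult:
    """Score a ranked edge list against a gold standard.

    Parameters
    ----------
    predictions : DataFrame or iterable of (regulator, target, score)
        Ranked edges; every pair must lie in the gold standard's eligible
        universe.  Pairs of the universe that are not listed are treated
        as ranked below all listed pairs (tied among themselves).
    gold : GoldStandard

    Raises
    ------
    UndefinedMetricError
        If the universe contains no positive or no negative pair.
    """
    scores, labels = _scores_and_labels(predictions, gold)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"metrics undefined: {n_pos} positives, {n_neg} negatives"
        )
    auroc = auroc_from_labels(scores, labels)
    tp, fp = _pr_points(scores, labels)
    recall = tp / n_pos
    precision = tp / (tp + fp)
    aupr = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    fpr = fp / n_neg
    tpr = recall
    return EvaluationResult(
        aupr=aupr,
        auroc=auroc,
        n_positives=n_pos,
        n_negatives=n_neg,
        pr_curve=(recall, precision),
        roc_curve=(fpr, tpr),
    )


def overall_score(p_aupr: float, p_auroc: float) -> float:
    """DREAM Overall Score: ``-1/2 * log10(p_aupr * p_auroc)``.

    Both p-values must lie in (0, 1]; the score is monotone decreasing in
    each argument.
    """
    for name, v in (("p_aupr", p_aupr), ("p_auroc", p_auroc)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    return -0.5 * (math.log10(p_aupr) + math.log10(p_auroc))


def geometric_mean(values) -> float:
    """Geometric mean of positive reals: ``exp(mean(log(values)))``."""
    vals = list(values)
    if not vals:
        raise ValueError("geometric mean of an empty sequence is undefined")
    if any(v <= 0 for v in vals):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(vals))))


def permutation_pvalues(
    predictions, gold: GoldStandard, n_permutations: int = 1000, random_state=None
):
    """Empirical one-sided p-values for AUPR and AUROC by label shuffling.

    The observed metrics are compared against ``n_permutations`` draws in
    which the same number of positives is planted uniformly at random
    among the eligible pairs (scores kept fixed).  Returns
    ``(p_aupr, p_auroc)`` with the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    scores, labels = _scores_and_labels(predictions, gold)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == labels.size:
        raise UndefinedMetricError("p-values undefined without both classes")
    obs_auroc = auroc_from_labels(scores, labels)
    obs_aupr = aupr_from_labels(scores, labels)
    rng = np.random.default_rng(random_state)
    ge_aupr = 0
    ge_auroc = 0
    null_labels = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(null_labels)
        if auroc_from_labels(scores, null_labels) >= obs_auroc:
            ge_auroc += 1
        if aupr_from_labels(scores, null_labels) >= obs_aupr:
            ge_aupr += 1
    denom = n_permutations + 1
    return (1 + ge_aupr) / denom, (1 + ge_auroc) / denom
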