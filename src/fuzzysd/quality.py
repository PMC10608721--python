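"""Rule quality measures for subgroup discovery.

All measures derive from the crisp 2x2 confusion matrix of a rule
against a binary-labelled table (positives = the rule's target class):

===========  ==================  ==================
             predicted positive  predicted negative
===========  ==================  ==================
positive     TP                  FN
negative     FP                  TN
===========  ==================  ==================

Coverage is crisp (compatibility > 0); only fuzzy confidence uses the
membership degrees themselves.  Unusualness is weighted relative
accuracy (WRAcc) mapped affinely from its attainable range
``[-p0(1-p0), +p0(1-p0)]`` onto [0, 1], so 0.5 means "confidence equal
to the class prior" and values above 0.8 mark strongly emerging
subgroups.  The screening statistic is the exact two-sided Fisher test
on the same matrix, computed in exact rational arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from .fuzzy import FuzzyPartition, Rule
from .io import BucketTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def p0(self) -> float:
        """Class prior of the positive class."""
        return self.n_pos / self.n


@dataclass
class QualityReport:
    """One row of a rule quality table."""

    n_vars: int
    unusualness: float
    wracc: float
    tp_rate: float
    fp_rate: float
    confidence: float
    fuzzy_confidence: float
    tef: float
    accuracy: float
    auroc: float


def confusion_counts(rule: Rule, table: BucketTable, partition: FuzzyPartition) -> ConfusionCounts:
    """Crisp counts under zero-cut coverage; positives = rule's target class."""
    covered = partition.covers(rule, table.intensities)
    pos = np.array([c == rule.target for c in table.class_labels])
    return ConfusionCounts(
        tp=int(np.sum(covered & pos)),
        fp=int(np.sum(covered & ~pos)),
        fn=int(np.sum(~covered & pos)),
        tn=int(np.sum(~covered & ~pos)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / N — misleading under imbalance but reported for reference."""
    return (counts.tp + counts.tn) / counts.n


def rates(counts: ConfusionCounts) -> tuple[float, float]:
    """(TPrate, FPrate) = (TP / n_pos, FP / n_neg)."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise ValueError("rates need both classes non-empty")
    return counts.tp / counts.n_pos, counts.fp / counts.n_neg


def auroc(tp_rate: float, fp_rate: float) -> float:
    """Single-operating-point AUROC: (1 + TPrate - FPrate) / 2."""
    if not (0.0 <= tp_rate <= 1.0 and 0.0 <= fp_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    return (1.0 + tp_rate - fp_rate) / 2.0


def wracc(counts: ConfusionCounts) -> float:
    """Weighted relative accuracy: coverage x (confidence - prior)."""
    covered = counts.tp + counts.fp
    if covered == 0:
        return 0.0
    return (covered / counts.n) * (counts.tp / covered - counts.p0)


def unusualness(counts: ConfusionCounts) -> float:
    """WRAcc normalized onto [0, 1]; 0.5 iff confidence equals the prior."""
    p0 = counts.p0
    if not 0.0 < p0 < 1.0:
        raise ValueError("degenerate class prior")
    half_range = p0 * (1.0 - p0)
    return (wracc(counts) + half_range) / (2.0 * half_range)


def crisp_confidence(counts: ConfusionCounts) -> float:
    covered = counts.tp + counts.fp
    return counts.tp / covered if covered else 0.0


def fuzzy_confidence(rule: Rule, table: BucketTable, partition: FuzzyPartition) -> float:
    """Sum of compatibilities over target-class samples / sum over all.

    Reduces to the crisp confidence TP/(TP+FP) when all compatibilities
    are 0/1.
    """
    comp = partition.rule_compatibility(rule, table.intensities)
    total = comp.sum()
    if total <= 0.0:
        raise ValueError("rule has zero total compatibility")
    pos = np.array([c == rule.target for c in table.class_labels])
    return float(comp[pos].sum() / total)


def fisher_exact_two_sided(counts: ConfusionCounts) -> float:
    """Exact two-sided Fisher p-value, minimum-likelihood definition.

    With both margins fixed, the first cell follows a hypergeometric
    distribution; the two-sided p sums the probabilities of every table
    whose point probability does not exceed that of the observed one.
    Integer binomial coefficients keep every comparison and the final
    sum exact, so ties are resolved without floating-point slack.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    n = counts.n
    row1 = tp + fp
    col1 = tp + fn
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0  # a zero margin admits a single table
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    # weight(x) proportional to the hypergeometric pmf at first cell x
    obs_w = comb(col1, tp) * comb(n - col1, row1 - tp)
    total = comb(n, row1)
    acc = sum(
        w
        for x in range(lo, hi + 1)
        if (w := comb(col1, x) * comb(n - col1, row1 - x)) <= obs_w
    )
    return float(Fraction(acc, total))


def reconstruct_counts_from_rates(
    tp_rate: float, fp_rate: float, n_pos: int, n_neg: int
) -> ConfusionCounts:
    """Recover integer counts from printed rates and class sizes.

    Published tables print TPrate/FPrate to 3 decimals; nearest-integer
    rounding (half away from zero) of ``rate * class size`` restores the
    underlying counts exactly for class sizes this small.
    """
    if not (0.0 <= tp_rate <= 1.0 and 0.0 <= fp_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    tp = math.floor(tp_rate * n_pos + 0.5)
    fp = math.floor(fp_rate * n_neg + 0.5)
    return ConfusionCounts(tp=tp, fp=fp, fn=n_pos - tp, tn=n_neg - fp)


def quality_report(rule: Rule, table: BucketTable, partition: FuzzyPartition) -> QualityReport:
    """Assemble the full per-rule quality row."""
    counts = confusion_counts(rule, table, partition)
    tpr, fpr = rates(counts)
    return QualityReport(
        n_vars=rule.n_vars,
        unusualness=unusualness(counts),
        wracc=wracc(counts),
        tp_rate=tpr,
        fp_rate=fpr,
        confidence=crisp_confidence(counts),
        fuzzy_confidence=fuzzy_confidence(rule, table, partition),
        tef=fisher_exact_two_sided(counts),
        accuracy=accuracy(counts),
        auroc=auroc(tpr, fpr),
    )
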