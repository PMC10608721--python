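"""Stratified cross-validation, AUROC aggregation and ROC-space filtering.

The engine is validated as a predictor with stratified k-fold CV
(default 5 folds, preserving class proportions per fold).  Within each
fold the training data may first be rebalanced with Safe-Level-SMOTE,
rule sets are mined for both classes, test samples are classified by
maximal rule compatibility, and the fold AUROC is the single-point form
(1 + TPrate - FPrate)/2.  Fuzzy domains are always rebuilt from the
training fold alone so no test information leaks into the partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .engine import EvolutionConfig, classify, evolve
from .fuzzy import build_partitions
from .io import BucketTable
from .quality import QualityReport, auroc
from .smote import SmoteConfig, generate_synthetic

logger = logging.getLogger("fuzzysd")


@dataclass
class CvPlan:
    n_folds: int
    test_indices: list[list[int]]
    seed: int | None

    def __post_init__(self) -> None:
        flat = sorted(i for fold in self.test_indices for i in fold)
        if flat != list(range(len(flat))):
            raise ValueError("folds must partition the samples exactly once")

    def train_indices(self, fold: int) -> list[int]:
        test = set(self.test_indices[fold])
        n = sum(len(f) for f in self.test_indices)
        return [i for i in range(n) if i not in test]


@dataclass
class CvResult:
    folds: pd.DataFrame  # fold, TPrate, FPrate, AUROC
    mean_auroc: float


def stratified_kfold(table: BucketTable, k: int = 5, seed: int | None = None) -> CvPlan:
    """Class-stratified partition into k folds (80/20 train/test at k=5)."""
    labels = np.asarray(table.class_labels)
    counts = {c: int(np.sum(labels == c)) for c in set(table.class_labels)}
    small = min(counts, key=lambda c: counts[c])
    if counts[small] < k:
        raise ValueError(f"class {small!r} has {counts[small]} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    test = [sorted(int(i) for i in te) for _, te in skf.split(table.intensities, labels)]
    return CvPlan(n_folds=k, test_indices=test, seed=seed)


def cv_auroc(
    table: BucketTable,
    evolution: EvolutionConfig | None = None,
    n_folds: int = 5,
    smote: SmoteConfig | None = None,
    seed: int | None = None,
) -> CvResult:
    """Mean single-point AUROC over stratified folds.

    Per fold: (optional) Safe-Level-SMOTE on the training part, mine
    rules for both classes, classify the held-out samples, and apply
    the single-point AUROC formula with the table's positive class as
    the positive.  Engine and SMOTE seeds are derived from *seed* and
    the fold number so the whole procedure is reproducible.
    """
    evolution = evolution or EvolutionConfig()
    plan = stratified_kfold(table, n_folds, seed)
    pos_class, neg_class = table.classes
    rows = []
    for fold in range(plan.n_folds):
        train = table.subset_samples(plan.train_indices(fold))
        test = table.subset_samples(plan.test_indices[fold])
        test_labels = np.asarray(test.class_labels)
        if len(set(test.class_labels)) < 2:
            raise ValueError(f"fold {fold} test set has a single class")

        if smote is not None:
            fold_smote = SmoteConfig(
                k=smote.k, target_ratio=smote.target_ratio,
                seed=None if seed is None else (seed * 1009 + fold) % (2**31),
            )
            train, _ = generate_synthetic(train, fold_smote)

        fold_cfg = EvolutionConfig(
            **{**evolution.__dict__,
               "seed": None if seed is None else (seed * 7919 + fold) % (2**31)}
        )
        partition = build_partitions(train, n_labels=fold_cfg.n_labels, t_norm=fold_cfg.t_norm)
        rule_sets = {
            cls: evolve(train, cls, fold_cfg, partition)
            for cls in (pos_class, neg_class)
        }
        priors = {
            cls: train.class_size(cls) / train.n_samples
            for cls in (pos_class, neg_class)
        }
        if any(rule_sets.values()):
            predicted = np.asarray(classify(rule_sets, partition, test.intensities, priors))
        else:
            # screening can reject every rule (e.g. uninformative data);
            # the degenerate classifier predicts the majority class
            majority = max(priors, key=lambda c: priors[c])
            predicted = np.full(test.n_samples, majority, dtype=object)

        pos = test_labels == pos_class
        tpr = float(np.mean(predicted[pos] == pos_class))
        fpr = float(np.mean(predicted[~pos] == pos_class))
        rows.append({"fold": fold, "TPrate": tpr, "FPrate": fpr,
                     "AUROC": auroc(tpr, fpr)})
        logger.info("fold %d: TPrate=%.3f FPrate=%.3f AUROC=%.3f",
                    fold, tpr, fpr, rows[-1]["AUROC"])

    df = pd.DataFrame(rows)
    return CvResult(folds=df, mean_auroc=float(df["AUROC"].mean()))


def roc_space_filter(reports: list[QualityReport], delta: float = 0.1) -> list[int]:
    """Indices of rules at least *delta* above the ROC diagonal.

    Rules with TPrate - FPrate < delta sit too close to chance
    behaviour to be descriptively interesting and are discarded.
    """
    return [i for i, rep in enumerate(reports) if rep.tp_rate - rep.fp_rate >= delta]


def roc_scatter(reports: list[QualityReport]) -> pd.DataFrame:
    """(FPrate, TPrate) pairs for ROC-space plots of a rule set."""
    return pd.DataFrame(
        {"FPrate": [r.fp_rate for r in reports], "TPrate": [r.tp_rate for r in reports]}
    )
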