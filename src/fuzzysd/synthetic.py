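"""Synthetic imbalanced bucket tables with planted fuzzy subgroups.

The generator emulates the shape of a small urinary NMR case/control
study: 12 minority ("NPC1") versus 40 majority ("Heterozygote")
samples over 54 positive-valued bucket features, with a handful of
features carrying class-dependent structure expressible as fuzzy-label
rules.  Ground truth is expressed directly in label space ({low,
normal, high} cells of each feature's domain), so rule recovery is
well defined without inverting fitted partitions.

For a planted rule, a fixed fraction (*penetrance*) of target-class
samples is placed inside the antecedent's label cells — the third of
each feature's range where that label dominates — and a smaller
fraction (*background leak*) of the other class is placed there too.
The remaining samples are placed so the planted rule's compatibility
with them is exactly zero.  All other features are i.i.d. log-normal
across classes, mimicking right-skewed creatinine-normalised bucket
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fuzzy import DEFAULT_LABELS, FuzzyPartition, Rule, build_partitions
from .io import BucketTable
from .quality import quality_report


@dataclass(frozen=True)
class PlantedRule:
    antecedent: dict[str, str]
    target: str
    penetrance: float = 0.9
    background_leak: float = 0.2

    def __post_init__(self) -> None:
        if not self.penetrance > self.background_leak:
            raise ValueError("penetrance must exceed background leak")
        for lab in self.antecedent.values():
            if lab not in DEFAULT_LABELS:
                raise ValueError(f"unknown label {lab!r}")

    def as_rule(self) -> Rule:
        return Rule(antecedent=self.antecedent, target=self.target)


@dataclass
class GeneratorConfig:
    n_min: int = 12
    n_maj: int = 40
    n_features: int = 54
    minority_class: str = "NPC1"
    majority_class: str = "Heterozygote"
    lognorm_sigma: float = 0.5   # spread of baseline bucket intensities
    noise_scale: float = 0.0     # extra multiplicative noise on all cells
    planted_rules: list[PlantedRule] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_min < 2 or self.n_maj < 2:
            raise ValueError("need at least 2 samples per class")


def _default_planted(config: GeneratorConfig, feature_names: list[str]) -> list[PlantedRule]:
    """One 2-conjunct minority rule on the first two buckets."""
    return [
        PlantedRule(
            antecedent={feature_names[0]: "high", feature_names[1]: "low"},
            target=config.minority_class,
        )
    ]


def _ppm_names(n_features: int, low: float = 6.71, high: float = 9.43) -> list[str]:
    """Contiguous ppm-range bucket names spanning the aromatic region."""
    edges = np.round(np.linspace(low, high, n_features + 1), 3)
    return [f"{edges[i]:.2f}-{edges[i + 1]:.2f}" for i in range(n_features)]


def generate(config: GeneratorConfig) -> tuple[BucketTable, list[PlantedRule]]:
    """Generate a table plus the ground-truth planted rules.

    Planted features are drawn on a per-feature positive range split
    into three equal label cells (low | normal | high).  Exact-count
    class-conditional placement: ``round(penetrance * n_target)``
    target samples land jointly inside all antecedent cells;
    ``round(leak * n_other)`` of the other class land inside; everyone
    else is placed with zero compatibility (one antecedent feature
    forced into the label's zero-membership region).  "normal" cells
    have full-domain support under triangular labels, so planting a
    normal label makes zero-compatibility placement impossible and is
    rejected for middle labels only when no zero region exists.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_min + config.n_maj
    names = _ppm_names(config.n_features)
    planted = (
        config.planted_rules
        if config.planted_rules is not None
        else _default_planted(config, names)
    )
    for pr in planted:
        for feat in pr.antecedent:
            if feat not in names:
                raise ValueError(f"planted feature {feat!r} outside generated features")

    labels = [config.minority_class] * config.n_min + [config.majority_class] * config.n_maj
    order = rng.permutation(n)
    labels = [labels[i] for i in order]
    label_arr = np.asarray(labels)

    # baseline: i.i.d. log-normal intensities, feature-specific scale
    scales = np.exp(rng.normal(0.0, 0.5, size=config.n_features))
    X = rng.lognormal(mean=0.0, sigma=config.lognorm_sigma, size=(n, config.n_features)) * scales

    cell_edges = np.array([0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])

    for pr in planted:
        target_idx = np.where(label_arr == pr.target)[0]
        other_idx = np.where(label_arr != pr.target)[0]
        n_in_t = int(round(pr.penetrance * target_idx.size))
        n_in_o = int(round(pr.background_leak * other_idx.size))
        in_t = rng.choice(target_idx, size=n_in_t, replace=False)
        in_o = rng.choice(other_idx, size=n_in_o, replace=False)
        inside = np.zeros(n, dtype=bool)
        inside[in_t] = True
        inside[in_o] = True
        outside = np.where(~inside)[0]

        feats = list(pr.antecedent.items())
        # each outside sample gets one antecedent feature forced to zero
        # membership for the planted label; others stay unconstrained
        zero_feat = rng.integers(0, len(feats), size=outside.size)

        for fpos, (feat, lab) in enumerate(feats):
            j = names.index(feat)
            t = DEFAULT_LABELS.index(lab)
            lo, hi = 0.5 * scales[j], 1.5 * scales[j]
            span = hi - lo
            col = np.empty(n)
            # unconstrained values: uniform over the whole range
            col[:] = lo + rng.uniform(0.0, 1.0, size=n) * span
            # inside samples: uniform within the label's third
            col[inside] = lo + (t + rng.uniform(0.0, 1.0, size=int(inside.sum()))) * span / 3.0
            # forced-zero samples: the label's membership vanishes there
            forced = outside[zero_feat == fpos]
            if forced.size:
                if lab == "low":       # zero for x >= midpoint
                    u = rng.uniform(0.5, 1.0, size=forced.size)
                elif lab == "high":    # zero for x <= midpoint
                    u = rng.uniform(0.0, 0.5, size=forced.size)
                else:
                    raise ValueError(
                        "cannot plant a 'normal' label: its support covers the "
                        "whole domain, so zero-compatibility placement is impossible"
                    )
                col[forced] = lo + u * span
            X[:, j] = col

    if config.noise_scale > 0:
        X *= np.exp(rng.normal(0.0, config.noise_scale, size=X.shape))
    X = np.abs(X)

    table = BucketTable(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        feature_names=names,
        intensities=X,
        class_labels=labels,
        positive_class=config.minority_class,
    )
    return table, list(planted)


# ---------------------------------------------------------------------
# recovery scoring


def antecedent_jaccard(a: Rule, b: Rule) -> float:
    """Jaccard similarity of (feature, label) pair sets."""
    pa, pb = a.pairs(), b.pairs()
    union = pa | pb
    return len(pa & pb) / len(union) if union else 1.0


def evaluate_recovery(
    found: list[Rule],
    truth: list[PlantedRule],
    table: BucketTable,
    partition: FuzzyPartition | None = None,
) -> list[dict]:
    """Best-matching found rule per planted rule, with its realised rates.

    Matching is by antecedent Jaccard on (feature, label) pairs among
    found rules for the same target class; the matched rule's TPrate
    and FPrate on *table* are reported so callers can judge whether the
    planted subgroup was functionally recovered.
    """
    if partition is None:
        partition = build_partitions(table)
    out = []
    for pr in truth:
        planted_rule = pr.as_rule()
        candidates = [r for r in found if r.target == pr.target]
        if not candidates:
            out.append({"planted": planted_rule, "match": None, "jaccard": 0.0,
                        "tp_rate": 0.0, "fp_rate": 0.0})
            continue
        # ties on Jaccard break toward the rule farthest above the ROC diagonal
        scored = [
            (antecedent_jaccard(planted_rule, r), quality_report(r, table, partition), r)
            for r in candidates
        ]
        jac, rep, best = max(scored, key=lambda t: (t[0], t[1].tp_rate - t[1].fp_rate))
        out.append({
            "planted": planted_rule,
            "match": best,
            "jaccard": jac,
            "tp_rate": rep.tp_rate,
            "fp_rate": rep.fp_rate,
        })
    return out
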