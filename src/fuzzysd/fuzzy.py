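"""Uniform triangular linguistic partitions and fuzzy rule semantics.

Each continuous bucket variable is covered by a uniform triangular
partition — by default three linguistic labels, *low*, *normal*,
*high* — whose apexes are equally spaced between the observed minimum
and maximum of the variable.  Adjacent memberships sum to one
everywhere in the domain (a Ruspini partition), so a value is never
"lost" between labels.  A rule is a conjunction of (feature, label)
pairs with a class consequent; its compatibility with a sample is the
t-norm (minimum by default) of the antecedent memberships, and a sample
counts as *covered* whenever that compatibility is strictly positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import BucketTable, BucketTableError

DEFAULT_LABELS = ("low", "normal", "high")


@dataclass(frozen=True)
class Rule:
    """``R: Cond -> Target_value`` with at most one label per feature."""

    antecedent: Mapping[str, str]
    target: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", dict(self.antecedent))

    @property
    def n_vars(self) -> int:
        return len(self.antecedent)

    def key(self) -> tuple:
        """Canonical identity: antecedent pairs (order-free) plus class."""
        return (frozenset(self.antecedent.items()), self.target)

    def pairs(self) -> frozenset:
        return frozenset(self.antecedent.items())

    def __str__(self) -> str:
        from .io import format_rule

        return format_rule(self)


@dataclass
class FuzzyPartition:
    """Per-feature uniform triangular partitions over observed domains."""

    feature_names: list[str]
    domains: np.ndarray  # (n_features, 2) observed [min, max]
    n_labels: int = 3
    label_names: tuple[str, ...] = DEFAULT_LABELS
    t_norm: str = "min"  # "min" or "product"

    def __post_init__(self) -> None:
        self.domains = np.asarray(self.domains, dtype=float)
        if self.n_labels < 2:
            raise ValueError("need at least 2 labels")
        if len(self.label_names) != self.n_labels:
            raise ValueError("label_names length must equal n_labels")
        if self.t_norm not in {"min", "product"}:
            raise ValueError(f"unknown t-norm {self.t_norm!r}")

    # -- geometry ------------------------------------------------------

    def centers(self, feature: str | int) -> np.ndarray:
        j = self._findex(feature)
        lo, hi = self.domains[j]
        return np.linspace(lo, hi, self.n_labels)

    def vertices(self, feature: str | int, label: str | int) -> tuple[float, float, float]:
        """(left foot, apex, right foot); end triangles shoulder at the edges."""
        c = self.centers(feature)
        t = self._lindex(label)
        left = c[t - 1] if t > 0 else c[0]
        right = c[t + 1] if t < self.n_labels - 1 else c[-1]
        return float(left), float(c[t]), float(right)

    def _findex(self, feature: str | int) -> int:
        if isinstance(feature, (int, np.integer)):
            return int(feature)
        try:
            return self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None

    def _lindex(self, label: str | int) -> int:
        if isinstance(label, (int, np.integer)):
            return int(label)
        try:
            return self.label_names.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    # -- membership ----------------------------------------------------

    def membership(self, feature: str | int, label: str | int, value) -> np.ndarray | float:
        """Triangular membership; values outside the domain clamp to the edge."""
        j = self._findex(feature)
        t = self._lindex(label)
        lo, hi = self.domains[j]
        x = np.clip(np.asarray(value, dtype=float), lo, hi)
        c = np.linspace(lo, hi, self.n_labels)
        step = (hi - lo) / (self.n_labels - 1)
        deg = np.maximum(0.0, 1.0 - np.abs(x - c[t]) / step)
        if np.isscalar(value) or np.ndim(value) == 0:
            return float(deg)
        return deg

    def membership_tensor(self, X: np.ndarray) -> np.ndarray:
        """All memberships at once: ``(n_samples, n_features, n_labels)``.

        The workhorse for evolutionary search, where the same samples
        are evaluated against thousands of candidate rules.
        """
        X = np.asarray(X, dtype=float)
        lo = self.domains[:, 0]
        hi = self.domains[:, 1]
        step = (hi - lo) / (self.n_labels - 1)
        Xc = np.clip(X, lo, hi)
        idx = np.arange(self.n_labels)
        centers = lo[:, None] + idx[None, :] * step[:, None]  # (F, L)
        deg = 1.0 - np.abs(Xc[:, :, None] - centers[None, :, :]) / step[None, :, None]
        return np.maximum(0.0, deg)

    # -- rule semantics ------------------------------------------------

    def rule_compatibility(self, rule: Rule, X: np.ndarray) -> np.ndarray:
        """Compatibility degree of each sample with *rule*.

        Minimum (or product) t-norm over antecedent memberships.  An
        empty antecedent — legal only for candidates during search —
        has compatibility 1 everywhere (identity of the t-norm).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        comp = np.ones(X.shape[0])
        for feat, lab in rule.antecedent.items():
            m = self.membership(feat, lab, X[:, self._findex(feat)])
            comp = np.minimum(comp, m) if self.t_norm == "min" else comp * m
        return comp

    def covers(self, rule: Rule, X: np.ndarray) -> np.ndarray:
        """Crisp coverage: compatibility strictly greater than zero."""
        return self.rule_compatibility(rule, X) > 0.0

    # -- audit dump ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_labels": self.n_labels,
            "label_names": list(self.label_names),
            "t_norm": self.t_norm,
            "features": {
                name: {
                    "domain": [float(a) for a in self.domains[j]],
                    "vertices": {
                        lab: list(self.vertices(j, t))
                        for t, lab in enumerate(self.label_names)
                    },
                }
                for j, name in enumerate(self.feature_names)
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def build_partitions(
    table: BucketTable, n_labels: int = 3,
    label_names: Sequence[str] | None = None, t_norm: str = "min",
) -> FuzzyPartition:
    """Fit uniform partitions to the observed per-feature domains.

    During cross-validation this is called on training folds only, so
    test samples may fall outside a domain; membership then clamps to
    the nearest edge.
    """
    lo = table.intensities.min(axis=0)
    hi = table.intensities.max(axis=0)
    const = np.where(hi <= lo)[0]
    if const.size:
        raise BucketTableError(
            "constant feature(s), cannot partition: "
            + ", ".join(table.feature_names[k] for k in const)
        )
    if label_names is None:
        label_names = DEFAULT_LABELS if n_labels == 3 else tuple(
            f"L{i}" for i in range(n_labels)
        )
    return FuzzyPartition(
        feature_names=list(table.feature_names),
        domains=np.column_stack([lo, hi]),
        n_labels=n_labels,
        label_names=tuple(label_names),
        t_norm=t_norm,
    )
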