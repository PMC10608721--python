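"""Bucket-table and rule-set I/O.

A *bucket table* is the standard interchange object in NMR metabolomics:
one row per urine (or serum) sample, one column per integrated spectral
bucket, plus a single categorical class column.  This module reads such
tables from delimited text, validates them, and writes discovered rule
sets together with their quality reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import re
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fuzzysd")


class BucketTableError(ValueError):
    """Raised when a bucket table violates its structural contract."""


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix with binary class labels.

    Parameters
    ----------
    sample_ids
        One identifier per row.
    feature_names
        Bucket labels, conventionally ppm ranges such as ``"6.71-6.75"``
        or metabolite/proton annotations; treated as opaque strings.
    intensities
        ``(n_samples, n_features)`` float matrix.  Non-negative on
        loading; preprocessing (e.g. Pareto scaling) may later introduce
        negative values, flagged via :attr:`processed`.
    class_labels
        One class name per sample; exactly two distinct values.
    positive_class
        The class treated as the target/positive class.  Named
        explicitly per run and never inferred from minority status,
        since rules are mined for both classes in turn.
    processed
        True once the preprocessing chain has been applied.
    """

    sample_ids: list[str]
    feature_names: list[str]
    intensities: np.ndarray
    class_labels: list[str]
    positive_class: str
    processed: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise BucketTableError("intensities must be a 2-D matrix")
        n, f = self.intensities.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise BucketTableError(
                f"row count {n} does not match sample_ids "
                f"({len(self.sample_ids)}) / class_labels ({len(self.class_labels)})"
            )
        if len(self.feature_names) != f:
            raise BucketTableError(
                f"column count {f} does not match feature_names ({len(self.feature_names)})"
            )
        classes = sorted(set(self.class_labels))
        if len(classes) != 2:
            raise BucketTableError(
                f"exactly two classes required, found {len(classes)}: {classes}"
            )
        if self.positive_class not in classes:
            raise BucketTableError(
                f"positive class {self.positive_class!r} not among {classes}"
            )
        if not np.all(np.isfinite(self.intensities)):
            bad = np.argwhere(~np.isfinite(self.intensities))[0]
            raise BucketTableError(
                f"non-finite intensity at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> tuple[str, str]:
        """(positive_class, negative_class)."""
        other = next(c for c in set(self.class_labels) if c != self.positive_class)
        return self.positive_class, other

    @property
    def negative_class(self) -> str:
        return self.classes[1]

    def class_mask(self, class_name: str) -> np.ndarray:
        return np.array([c == class_name for c in self.class_labels])

    def class_size(self, class_name: str) -> int:
        return int(self.class_mask(class_name).sum())

    @property
    def minority_class(self) -> str:
        a, b = self.classes
        return a if self.class_size(a) <= self.class_size(b) else b

    @property
    def majority_class(self) -> str:
        a, b = self.classes
        return b if self.minority_class == a else a

    @property
    def imbalance_ratio(self) -> float:
        """Majority class size divided by minority class size."""
        return self.class_size(self.majority_class) / self.class_size(self.minority_class)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"unknown feature {name!r}") from None

    def feature_values(self, name: str) -> np.ndarray:
        return self.intensities[:, self.feature_index(name)]

    def with_intensities(
        self, intensities: np.ndarray, feature_names: Sequence[str] | None = None,
        processed: bool | None = None,
    ) -> "BucketTable":
        """Copy with replaced matrix (and optionally feature names)."""
        return BucketTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(feature_names if feature_names is not None else self.feature_names),
            intensities=np.asarray(intensities, dtype=float),
            class_labels=list(self.class_labels),
            positive_class=self.positive_class,
            processed=self.processed if processed is None else processed,
        )

    def subset_samples(self, indices: Sequence[int]) -> "BucketTable":
        idx = list(indices)
        return BucketTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=list(self.feature_names),
            intensities=self.intensities[idx, :],
            class_labels=[self.class_labels[i] for i in idx],
            positive_class=self.positive_class,
            processed=self.processed,
        )

    def to_frame(self, class_column: str = "Class") -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, index=self.sample_ids, columns=self.feature_names)
        df[class_column] = self.class_labels
        return df


@dataclass
class RunConfig:
    """All run parameters in one place, echoed into every output."""

    class_column: str = "Class"
    positive_class: str = ""
    reference_feature: str | None = None
    apply_cube_root: bool = True
    apply_pareto: bool = True
    ppm_window: tuple[float, float] | None = None
    smote: dict = field(default_factory=dict)
    evolution: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        if data.get("ppm_window") is not None:
            data["ppm_window"] = tuple(data["ppm_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_bucket_table(
    path: str | Path,
    class_column: str,
    positive_class: str,
    sep: str = ",",
) -> BucketTable:
    """Load a delimited samples x buckets table.

    The first column is used as the sample identifier when unnamed or
    named ``sample``/``id`` (case-insensitive); otherwise row numbers
    serve as identifiers.  All non-class columns must be numeric and
    non-negative.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if class_column not in df.columns:
        raise BucketTableError(f"class column {class_column!r} not found in {path.name}")

    first = df.columns[0]
    if first.lower() in {"sample", "sampleid", "sample_id", "id", "unnamed: 0"}:
        sample_ids = [str(v) for v in df[first]]
        df = df.drop(columns=[first])
    else:
        sample_ids = [str(i) for i in range(len(df))]

    class_labels = [str(v) for v in df[class_column]]
    feat = df.drop(columns=[class_column])
    if len(df) < 2 or len(set(class_labels)) < 2:
        raise BucketTableError("need at least two samples and two classes")
    if len(set(class_labels)) > 2:
        raise BucketTableError(f"more than two classes: {sorted(set(class_labels))}")

    matrix = np.empty((len(df), feat.shape[1]), dtype=float)
    for j, col in enumerate(feat.columns):
        converted = pd.to_numeric(feat[col], errors="coerce")
        bad = converted.isna() & feat[col].notna()
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy() | bad.to_numpy()))
            raise BucketTableError(
                f"non-numeric or missing value at row {sample_ids[i]!r}, column {col!r}"
            )
        matrix[:, j] = converted.to_numpy()
    if np.any(matrix < 0):
        i, j = np.argwhere(matrix < 0)[0]
        raise BucketTableError(
            f"negative intensity at row {sample_ids[i]!r}, column {feat.columns[j]!r}"
        )

    table = BucketTable(
        sample_ids=sample_ids,
        feature_names=[str(c) for c in feat.columns],
        intensities=matrix,
        class_labels=class_labels,
        positive_class=positive_class,
    )
    logger.info(
        "loaded %s: %d samples x %d buckets, classes %s, imbalance ratio %.2f",
        path.name, table.n_samples, table.n_features,
        dict(zip(*np.unique(table.class_labels, return_counts=True))),
        table.imbalance_ratio,
    )
    return table


def write_bucket_table(
    table: BucketTable, path: str | Path, class_column: str = "Class",
    synthetic_flags: Sequence[bool] | None = None,
) -> None:
    """Write a table as CSV; optional provenance column for synthetic rows."""
    df = table.to_frame(class_column)
    if synthetic_flags is not None:
        df["synthetic"] = [bool(v) for v in synthetic_flags]
    df.to_csv(path, index_label="sample")


# -- rule reports ------------------------------------------------------

_REPORT_COLUMNS = ["Class", "Rule", "Vars", "Unus", "TPrate", "FPrate", "FCnf", "TEF"]


def _truncate3(x: float) -> float:
    return math.floor(x * 1000.0) / 1000.0


def format_rule(rule) -> str:
    """Render ``IF f=label AND ... THEN class``."""
    conj = " AND ".join(f"{f}={lab}" for f, lab in rule.antecedent.items())
    return f"IF {conj} THEN {rule.target}"


def parse_rule_line(line: str):
    """Inverse of :func:`format_rule`."""
    from .fuzzy import Rule

    m = re.match(r"^IF (.+) THEN (.+)$", line.strip())
    if m is None:
        raise ValueError(f"not a rule line: {line!r}")
    antecedent = {}
    for pair in m.group(1).split(" AND "):
        feat, _, lab = pair.rpartition("=")
        antecedent[feat] = lab
    return Rule(antecedent=antecedent, target=m.group(2))


def write_rules(rules: Sequence, reports: Sequence, path: str | Path) -> None:
    """Write aligned rules and quality reports.

    Produces three files from the stem of *path*: the CSV quality table
    (columns ``Class, Rule, Vars, Unus, TPrate, FPrate, FCnf, TEF``;
    TEF truncated to 3 decimals, all other measures rounded), a
    ``.rules.txt`` human-readable block, and a ``.json`` sidecar with
    full-precision values.
    """
    if len(rules) != len(reports):
        raise ValueError(f"{len(rules)} rules but {len(reports)} reports")
    path = Path(path)
    rows = []
    side = []
    for i, (rule, rep) in enumerate(zip(rules, reports), start=1):
        rows.append({
            "Class": rule.target,
            "Rule": f"R{i}",
            "Vars": rep.n_vars,
            "Unus": round(rep.unusualness, 3),
            "TPrate": round(rep.tp_rate, 3),
            "FPrate": round(rep.fp_rate, 3),
            "FCnf": round(rep.fuzzy_confidence, 3),
            "TEF": _truncate3(rep.tef),
        })
        side.append({
            "rule": format_rule(rule),
            "antecedent": dict(rule.antecedent),
            "class": rule.target,
            **{k: getattr(rep, k) for k in (
                "n_vars", "unusualness", "wracc", "tp_rate", "fp_rate",
                "confidence", "fuzzy_confidence", "tef", "accuracy", "auroc")},
        })
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)
    txt = path.with_suffix(".rules.txt")
    txt.write_text("".join(format_rule(r) + "\n" for r in rules))
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_rules(path: str | Path) -> list:
    """Re-parse a ``.rules.txt`` block written by :func:`write_rules`."""
    lines = Path(path).read_text().splitlines()
    return [parse_rule_line(ln) for ln in lines if ln.strip()]


def setup_logging(seed: int | None = None, level: int = logging.INFO) -> None:
    """Log to stderr; echo the run seed so outputs are attributable."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
    if seed is not None:
        logger.info("run seed = %d", seed)
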