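"""Safe-Level-SMOTE oversampling for the minority class.

Plain SMOTE interpolates between a minority seed and a random minority
neighbour with a uniform gap, which can place synthetic points deep in
majority territory when the seed sits near the class boundary or in
noise.  Safe-Level-SMOTE first measures how "safe" each endpoint is —
the number of minority samples among its k nearest neighbours — and
then biases the interpolation gap toward the safer endpoint:

========================  ==========================================
safe levels               gap for synthetic = p + gap * (n - p)
========================  ==========================================
sl_p = 0 and sl_n = 0     skip the pair (both points are noise)
sl_p > 0 and sl_n = 0     gap = 0 (duplicate the seed)
sl_p = sl_n > 0           gap ~ U(0, 1)
sl_p > sl_n > 0           gap ~ U(0, sl_n / sl_p)   (stay near seed)
sl_p < sl_n, sl_n > 0     gap ~ U(1 - sl_p/sl_n, 1) (move to neighbour)
========================  ==========================================

Safe levels are measured against ALL samples (both classes); synthesis
partners are drawn from the seed's k nearest minority neighbours.
Oversampling belongs inside training folds only — never applied to
held-out test data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import BucketTable

logger = logging.getLogger("fuzzysd")


@dataclass
class SmoteConfig:
    k: int = 5
    target_ratio: float = 1.0  # desired minority : majority size ratio
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def safe_level(X: np.ndarray, minority_mask: np.ndarray, index: int, k: int) -> int:
    """Minority count among the k nearest neighbours of sample *index*.

    The sample itself is excluded; Euclidean distance on the feature
    matrix as given (callers preprocess first).
    """
    X = np.asarray(X, dtype=float)
    if k >= X.shape[0]:
        raise ValueError(f"k={k} must be smaller than the number of samples {X.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X[index : index + 1])
    neighbours = [j for j in idx[0] if j != index][:k]
    return int(np.sum(minority_mask[neighbours]))


def generate_synthetic(
    table: BucketTable, config: SmoteConfig, rng: np.random.Generator | None = None
) -> tuple[BucketTable, np.ndarray]:
    """Balance the minority class; returns (superset table, synthetic flags).

    Original rows appear first and unchanged.  Synthetic rows carry the
    minority label and lie on the segment between their seed and the
    chosen neighbour.  If every candidate pair is skipped in a full pass
    over the minority class, a warning is issued and the partial result
    returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = table.intensities
    n = table.n_samples
    if config.k >= n:
        raise ValueError(f"k={config.k} must be smaller than the number of samples {n}")

    minority = table.minority_class
    min_mask = table.class_mask(minority)
    min_idx = np.where(min_mask)[0]
    n_min, n_maj = len(min_idx), n - len(min_idx)
    needed = max(0, int(round(config.target_ratio * n_maj)) - n_min)

    # safe levels against all samples, precomputed once
    nn_all = NearestNeighbors(n_neighbors=config.k + 1).fit(X)
    _, all_idx = nn_all.kneighbors(X)
    sl = np.array([
        int(np.sum(min_mask[[j for j in all_idx[i] if j != i][: config.k]]))
        for i in range(n)
    ])

    # synthesis partners: k nearest minority neighbours of each minority seed
    k_part = min(config.k, n_min - 1)
    partners: dict[int, np.ndarray] = {}
    if k_part >= 1:
        nn_min = NearestNeighbors(n_neighbors=k_part + 1).fit(X[min_idx])
        _, pidx = nn_min.kneighbors(X[min_idx])
        for row, i in enumerate(min_idx):
            partners[i] = min_idx[[j for j in pidx[row] if min_idx[j] != i][:k_part]]

    new_rows: list[np.ndarray] = []
    while len(new_rows) < needed:
        made_progress = False
        for p in rng.permutation(min_idx):
            if len(new_rows) >= needed:
                break
            if p not in partners or len(partners[p]) == 0:
                continue
            q = int(rng.choice(partners[p]))
            sl_p, sl_n = int(sl[p]), int(sl[q])
            if sl_p == 0 and sl_n == 0:
                continue  # both endpoints are noise
            if sl_n == 0:
                gap = 0.0
            elif sl_p == sl_n:
                gap = float(rng.uniform(0.0, 1.0))
            elif sl_p > sl_n:
                gap = float(rng.uniform(0.0, sl_n / sl_p))
            else:  # sl_p < sl_n, including sl_p = 0
                gap = float(rng.uniform(1.0 - sl_p / sl_n, 1.0))
            new_rows.append(X[p] + gap * (X[q] - X[p]))
            made_progress = True
        if not made_progress:
            warnings.warn(
                f"Safe-Level-SMOTE: all candidate pairs skipped; produced "
                f"{len(new_rows)} of {needed} synthetic rows",
                stacklevel=2,
            )
            break

    n_new = len(new_rows)
    matrix = np.vstack([X] + new_rows) if n_new else X.copy()
    out = BucketTable(
        sample_ids=list(table.sample_ids) + [f"synthetic_{i}" for i in range(n_new)],
        feature_names=list(table.feature_names),
        intensities=matrix,
        class_labels=list(table.class_labels) + [minority] * n_new,
        positive_class=table.positive_class,
        processed=table.processed,
    )
    flags = np.zeros(out.n_samples, dtype=bool)
    flags[n:] = True
    logger.info("SLSMOTE: %d synthetic %s rows appended (k=%d)", n_new, minority, config.k)
    return out, flags
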