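import numpy as np
import pytest

from fuzzysd import BucketTable, EvolutionConfig

# Published quality table for the seven urinary NPC1/heterozygote rules:
# (rule, target class, n_pos, n_neg, n_vars, Unus, TPrate, FPrate, TEF printed)
TABLE4 = [
    ("R1", "Heterozygote", 40, 12, 4, 0.671, 0.925, 0.583, 0.011),
    ("R2", "Heterozygote", 40, 12, 4, 0.796, 0.675, 0.083, 0.000),
    ("R3", "Heterozygote", 40, 12, 3, 0.708, 0.750, 0.333, 0.014),
    ("R4", "Heterozygote", 40, 12, 3, 0.767, 0.700, 0.167, 0.001),
    ("R5", "Heterozygote", 40, 12, 4, 0.737, 0.725, 0.250, 0.005),
    ("R6", "NPC1", 12, 40, 7, 0.800, 1.000, 0.400, 0.000),
    ("R7", "NPC1", 12, 40, 6, 0.808, 0.917, 0.300, 0.000),
]

# compact engine settings for toy problems in tests
SMALL_EVO = dict(population_size=20, max_evaluations=400)


@pytest.fixture
def toy_table() -> BucketTable:
    """10 samples x 3 buckets, 4 cases vs 6 controls, feature 0 informative."""
    X = np.array([
        [0.9, 0.2, 1.1], [0.8, 0.5, 0.9], [0.95, 0.7, 1.3], [0.85, 0.3, 0.7],
        [0.1, 0.6, 1.0], [0.2, 0.4, 1.2], [0.15, 0.8, 0.8], [0.05, 0.1, 1.1],
        [0.12, 0.9, 0.95], [0.18, 0.2, 1.05],
    ])
    return BucketTable(
        sample_ids=[f"s{i}" for i in range(10)],
        feature_names=["7.00-7.10", "7.10-7.20", "7.20-7.30"],
        intensities=X,
        class_labels=["case"] * 4 + ["ctrl"] * 6,
        positive_class="case",
    )


def separable_table(seed: int = 0, separable: bool = True,
                    n_pos: int = 10, n_neg: int = 15) -> BucketTable:
    """Toy with (optionally) one perfectly separating bucket plus noise."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n_pos + n_neg, 4))
    if separable:
        X[:n_pos, 0] = rng.uniform(0.8, 1.0, n_pos)
        X[n_pos:, 0] = rng.uniform(0.0, 0.2, n_neg)
    names = [f"{7 + 0.1 * i:.2f}-{7.1 + 0.1 * i:.2f}" for i in range(4)]
    return BucketTable(
        sample_ids=[f"s{i}" for i in range(n_pos + n_neg)],
        feature_names=names,
        intensities=X,
        class_labels=["case"] * n_pos + ["ctrl"] * n_neg,
        positive_class="case",
    )
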