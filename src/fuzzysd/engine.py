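"""Multi-objective evolutionary fuzzy subgroup-discovery engine.

Searches the space of fuzzy conjunctive rules for one target class at a
time.  An individual is one candidate rule encoded as an integer genome
with one gene per feature: either a linguistic-label index or
NOT_PARTICIPATING.  Fitness is a vector of subgroup quality measures
(default: normalized unusualness and fuzzy confidence, the
generality/precision trade-off), optimised with NSGA-II machinery —
fast non-dominated sorting, crowding distance, binary tournament,
two-point crossover, and a mutation operator biased toward generality
(half of mutations drop a variable from the rule).

Initialisation is also biased toward general rules, and a stall
detector reinitialises the non-elite population seeded from so-far
uncovered target examples, pushing the search toward diverse
subgroups.  The final Pareto front is decoded and screened with the
exact two-sided Fisher test: only rules significant at ``p < alpha``
(default 0.10) are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fuzzy import FuzzyPartition, Rule, build_partitions
from .io import BucketTable
from .quality import (
    ConfusionCounts,
    confusion_counts,
    fisher_exact_two_sided,
    unusualness,
)

logger = logging.getLogger("fuzzysd")

NOT_PARTICIPATING = -1

_OBJECTIVES = ("unusualness", "fuzzy_confidence", "tp_rate")


@dataclass
class EvolutionConfig:
    population_size: int = 100
    max_evaluations: int = 10000
    objectives: tuple[str, str] = ("unusualness", "fuzzy_confidence")
    crossover_prob: float = 0.6
    mutation_prob: float = 0.1  # per gene
    biased_init_fraction: float = 0.75
    biased_init_max_vars: float = 0.25  # fraction of features participating
    stall_fraction: float = 0.05  # of max_evaluations, without new coverage
    alpha: float = 0.10
    n_labels: int = 3
    t_norm: str = "min"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for p in (self.crossover_prob, self.mutation_prob,
                  self.biased_init_fraction, self.biased_init_max_vars):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 individuals")
        for obj in self.objectives:
            if obj not in _OBJECTIVES:
                raise ValueError(f"unknown objective {obj!r}; choose from {_OBJECTIVES}")


# ---------------------------------------------------------------------
# NSGA-II machinery


def nondominated_sort(fitness: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fast non-dominated sort (maximisation) plus crowding distances.

    Returns ``(ranks, crowding)`` where rank 0 is the Pareto-optimal
    front and boundary points of each front receive infinite crowding.
    """
    F = np.asarray(fitness, dtype=float)
    n = F.shape[0]
    # dominates[i, j]: i weakly better everywhere and strictly better somewhere
    ge = np.all(F[:, None, :] >= F[None, :, :], axis=2)
    gt = np.any(F[:, None, :] > F[None, :, :], axis=2)
    dom = ge & gt
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.where(n_dominators == 0)[0]
    r = 0
    remaining = n_dominators.copy()
    while current.size:
        ranks[current] = r
        remaining[current] = -1
        freed = remaining - dom[current].sum(axis=0)
        nxt = np.where((freed == 0) & (ranks == -1))[0]
        remaining = freed
        current = nxt
        r += 1

    crowding = np.zeros(n)
    for front in range(r):
        idx = np.where(ranks == front)[0]
        if idx.size <= 2:
            crowding[idx] = np.inf
            continue
        for m in range(F.shape[1]):
            order = idx[np.argsort(F[idx, m], kind="stable")]
            fmin, fmax = F[order[0], m], F[order[-1], m]
            crowding[order[0]] = crowding[order[-1]] = np.inf
            if np.isfinite(fmin) and np.isfinite(fmax) and fmax > fmin:
                crowding[order[1:-1]] += (F[order[2:], m] - F[order[:-2], m]) / (fmax - fmin)
    return ranks, crowding


# ---------------------------------------------------------------------
# Engine


class SubgroupDiscovery:
    """Evolutionary search for one target class on one (training) table."""

    def __init__(
        self,
        table: BucketTable,
        target_class: str,
        config: EvolutionConfig | None = None,
        partition: FuzzyPartition | None = None,
    ) -> None:
        self.table = table
        self.target = target_class
        self.config = config or EvolutionConfig()
        if target_class not in set(table.class_labels):
            raise ValueError(f"no examples of target class {target_class!r}")
        self.partition = partition or build_partitions(
            table, n_labels=self.config.n_labels, t_norm=self.config.t_norm
        )
        # memberships precomputed once: (n_samples, n_features, n_labels)
        self.M = self.partition.membership_tensor(table.intensities)
        self.pos = table.class_mask(target_class)
        self.n_pos = int(self.pos.sum())
        self.n = table.n_samples
        self.p0 = self.n_pos / self.n
        self.n_features = table.n_features
        self.rng = np.random.default_rng(self.config.seed)
        self.evaluations = 0

    # -- genome <-> rule ----------------------------------------------

    def decode(self, genome: np.ndarray) -> Rule:
        ant = {
            self.partition.feature_names[j]: self.partition.label_names[genome[j]]
            for j in np.where(genome != NOT_PARTICIPATING)[0]
        }
        return Rule(antecedent=ant, target=self.target)

    # -- evaluation ----------------------------------------------------

    def _compatibility(self, genome: np.ndarray) -> np.ndarray:
        j = np.where(genome != NOT_PARTICIPATING)[0]
        if j.size == 0:
            return np.ones(self.n)
        memberships = self.M[:, j, genome[j]]
        if self.config.t_norm == "min":
            return memberships.min(axis=1)
        return memberships.prod(axis=1)

    def _fuzzy_unusualness(self, comp: np.ndarray) -> float:
        """Normalized WRAcc on compatibility-degree sums.

        During search the quality measures are evaluated fuzzily (sums
        of membership degrees instead of crisp counts): the min t-norm
        erodes compatibility with every added conjunct, so fuzzy WRAcc
        carries an intrinsic generality pressure that keeps overfitted
        deep conjunctions off the Pareto front.  Reporting and
        screening use the crisp measures of :mod:`fuzzysd.quality`.
        """
        s_all = comp.sum()
        if s_all <= 0.0:
            w = 0.0
        else:
            w = (s_all / self.n) * (comp[self.pos].sum() / s_all - self.p0)
        hr = self.p0 * (1 - self.p0)
        return (w + hr) / (2 * hr)

    def evaluate(self, genome: np.ndarray) -> np.ndarray:
        """Objective vector; empty antecedents score worst on all axes."""
        self.evaluations += 1
        if np.all(genome == NOT_PARTICIPATING):
            return np.full(len(self.config.objectives), -np.inf)
        comp = self._compatibility(genome)
        out = np.empty(len(self.config.objectives))
        for i, name in enumerate(self.config.objectives):
            if name == "unusualness":
                out[i] = self._fuzzy_unusualness(comp)
            elif name == "fuzzy_confidence":
                total = comp.sum()
                out[i] = comp[self.pos].sum() / total if total > 0 else 0.0
            else:  # tp_rate, fuzzy form: mean compatibility over positives
                out[i] = comp[self.pos].sum() / self.n_pos
        return out

    def _covered_targets(self, genome: np.ndarray) -> np.ndarray:
        return (self._compatibility(genome) > 0.0) & self.pos

    # -- initialisation ------------------------------------------------

    def _random_genome(self) -> np.ndarray:
        return self.rng.integers(
            NOT_PARTICIPATING, self.config.n_labels, size=self.n_features
        ).astype(np.int64)

    def _biased_genome(self) -> np.ndarray:
        g = np.full(self.n_features, NOT_PARTICIPATING, dtype=np.int64)
        max_vars = max(1, int(np.ceil(self.config.biased_init_max_vars * self.n_features)))
        k = int(self.rng.integers(1, max_vars + 1))
        sites = self.rng.choice(self.n_features, size=k, replace=False)
        g[sites] = self.rng.integers(0, self.config.n_labels, size=k)
        return g

    def _example_seeded_genome(self, example_index: int) -> np.ndarray:
        """Rule whose labels best fit one uncovered target example."""
        g = np.full(self.n_features, NOT_PARTICIPATING, dtype=np.int64)
        max_vars = max(1, int(np.ceil(self.config.biased_init_max_vars * self.n_features)))
        k = int(self.rng.integers(1, max_vars + 1))
        sites = self.rng.choice(self.n_features, size=k, replace=False)
        g[sites] = np.argmax(self.M[example_index, sites, :], axis=1)
        return g

    def initialize_population(self) -> np.ndarray:
        pop = []
        n_biased = int(round(self.config.biased_init_fraction * self.config.population_size))
        for i in range(self.config.population_size):
            pop.append(self._biased_genome() if i < n_biased else self._random_genome())
        return np.array(pop)

    # -- variation -----------------------------------------------------

    def _tournament(self, ranks, crowding) -> int:
        a, b = self.rng.integers(0, len(ranks), size=2)
        if ranks[a] != ranks[b]:
            return a if ranks[a] < ranks[b] else b
        if crowding[a] != crowding[b]:
            return a if crowding[a] > crowding[b] else b
        return int(a)

    def _crossover(self, g1: np.ndarray, g2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.rng.random() >= self.config.crossover_prob or self.n_features < 2:
            return g1.copy(), g2.copy()
        i, j = sorted(self.rng.choice(self.n_features + 1, size=2, replace=False))
        c1, c2 = g1.copy(), g2.copy()
        c1[i:j], c2[i:j] = g2[i:j], g1[i:j]
        return c1, c2

    def _mutate(self, g: np.ndarray) -> np.ndarray:
        mask = self.rng.random(self.n_features) < self.config.mutation_prob
        for j in np.where(mask)[0]:
            if self.rng.random() < 0.5:
                g[j] = NOT_PARTICIPATING  # generality-biased: drop the variable
            else:
                g[j] = self.rng.integers(0, self.config.n_labels)
        return g

    # -- main loop -----------------------------------------------------

    def run(self) -> list[Rule]:
        cfg = self.config
        pop = self.initialize_population()
        fit = np.array([self.evaluate(g) for g in pop])
        ranks, crowding = nondominated_sort(fit)

        covered = np.zeros(self.n, dtype=bool)
        for g in pop[ranks == 0]:
            covered |= self._covered_targets(g)
        stall_budget = max(1, int(cfg.stall_fraction * cfg.max_evaluations))
        last_progress = self.evaluations

        while self.evaluations < cfg.max_evaluations:
            children = []
            while len(children) < cfg.population_size:
                p1 = pop[self._tournament(ranks, crowding)]
                p2 = pop[self._tournament(ranks, crowding)]
                c1, c2 = self._crossover(p1, p2)
                children.append(self._mutate(c1))
                if len(children) < cfg.population_size:
                    children.append(self._mutate(c2))
            children = np.array(children)
            child_fit = np.array([self.evaluate(g) for g in children])

            combined = np.vstack([pop, children])
            combined_fit = np.vstack([fit, child_fit])
            ranks_c, crowd_c = nondominated_sort(combined_fit)
            order = np.lexsort((-crowd_c, ranks_c))[: cfg.population_size]
            pop, fit = combined[order], combined_fit[order]
            ranks, crowding = nondominated_sort(fit)

            front_cover = np.zeros(self.n, dtype=bool)
            for g in pop[ranks == 0]:
                front_cover |= self._covered_targets(g)
            if np.any(front_cover & ~covered):
                covered |= front_cover
                last_progress = self.evaluations
            elif self.evaluations - last_progress >= stall_budget:
                # reinitialise non-elite individuals from uncovered targets
                uncovered = np.where(self.pos & ~covered)[0]
                non_elite = np.where(ranks > 0)[0]
                for i in non_elite:
                    if uncovered.size:
                        ex = int(self.rng.choice(uncovered))
                        pop[i] = self._example_seeded_genome(ex)
                    else:
                        pop[i] = self._biased_genome()
                    fit[i] = self.evaluate(pop[i])
                ranks, crowding = nondominated_sort(fit)
                last_progress = self.evaluations

        final: list[Rule] = []
        for g in pop[ranks == 0]:
            if np.any(g != NOT_PARTICIPATING):
                final.extend(self._generalization_path(g))
        return screen_rules(final, self.table, cfg.alpha, self.partition)

    def _generalization_path(self, genome: np.ndarray) -> list[Rule]:
        """Greedy pruning of one front rule into its generalizations.

        Evolutionary rule search tends to append conjuncts that are
        neutral or marginal on the training data; the candidate pool
        therefore also contains every rule obtained by repeatedly
        dropping the conjunct whose removal least degrades
        unusualness.  Fisher screening then decides which survive, so
        general (parsimonious) subgroups are never lost to overfitted
        specialisations of themselves.
        """
        def unus_of(g: np.ndarray) -> float:
            return self._fuzzy_unusualness(self._compatibility(g))

        path = [self.decode(genome)]
        g = genome.copy()
        while np.sum(g != NOT_PARTICIPATING) > 1:
            sites = np.where(g != NOT_PARTICIPATING)[0]
            best_site, best_u = None, -np.inf
            for j in sites:
                trial = g.copy()
                trial[j] = NOT_PARTICIPATING
                u = unus_of(trial)
                if u > best_u:
                    best_site, best_u = j, u
            g[best_site] = NOT_PARTICIPATING
            path.append(self.decode(g))
        return path


def evolve(
    table: BucketTable,
    target_class: str,
    config: EvolutionConfig | None = None,
    partition: FuzzyPartition | None = None,
) -> list[Rule]:
    """Mine significant fuzzy subgroup rules for one target class."""
    engine = SubgroupDiscovery(table, target_class, config, partition)
    rules = engine.run()
    logger.info(
        "evolve(target=%s): %d rules after Fisher screening (%d evaluations)",
        target_class, len(rules), engine.evaluations,
    )
    return rules


def screen_rules(
    rules: list[Rule], table: BucketTable, alpha: float, partition: FuzzyPartition
) -> list[Rule]:
    """Collapse duplicates, then keep rules with Fisher p strictly below alpha."""
    seen = set()
    unique = []
    for r in rules:
        if r.key() not in seen:
            seen.add(r.key())
            unique.append(r)
    return [
        r
        for r in unique
        if fisher_exact_two_sided(confusion_counts(r, table, partition)) < alpha
    ]


def classify(
    rule_sets: dict[str, list[Rule]],
    partition: FuzzyPartition,
    X: np.ndarray,
    priors: dict[str, float],
) -> list[str]:
    """Assign each sample the class of its maximally compatible rule.

    Ties go to the class with the larger training prior; samples firing
    no rule fall back to the majority (highest-prior) class.
    """
    if not any(rule_sets.values()):
        raise ValueError("no rules in any class")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    majority = max(priors, key=lambda c: priors[c])
    best = np.zeros((X.shape[0],))
    labels = [majority] * X.shape[0]
    per_class = {
        cls: (
            np.max([partition.rule_compatibility(r, X) for r in rules], axis=0)
            if rules else np.zeros(X.shape[0])
        )
        for cls, rules in rule_sets.items()
    }
    # iterate classes by descending prior so exact ties keep the higher prior
    for cls in sorted(per_class, key=lambda c: -priors[c]):
        comp = per_class[cls]
        better = comp > best
        for i in np.where(better)[0]:
            labels[i] = cls
        best = np.maximum(best, comp)
    return labels
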