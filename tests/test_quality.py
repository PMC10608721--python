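import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from fuzzysd import Rule, build_partitions
from fuzzysd.quality import (
    ConfusionCounts,
    accuracy,
    auroc,
    confusion_counts,
    crisp_confidence,
    fisher_exact_two_sided,
    fuzzy_confidence,
    quality_report,
    rates,
    reconstruct_counts_from_rates,
    unusualness,
    wracc,
)
from conftest import TABLE4


def enumeration_fisher(c: ConfusionCounts) -> Fraction:
    """Independent oracle: enumerate all 2x2 tables with the observed margins.

    Uses the row-wise factorisation of the hypergeometric pmf, a
    different decomposition from the implementation's column-wise one,
    and exact rationals throughout.
    """
    r1, r2 = c.tp + c.fp, c.fn + c.tn
    c1 = c.tp + c.fn
    n = c.n
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)

    def pmf(a: int) -> Fraction:
        # table [[a, r1-a], [c1-a, r2-(c1-a)]]
        if a < 0 or a > r1 or c1 - a < 0 or c1 - a > r2:
            return Fraction(0)
        return Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1))

    observed = pmf(c.tp)
    return sum(
        (p for a in range(0, min(r1, c1) + 1) if (p := pmf(a)) <= observed),
        Fraction(0),
    )


class TestConfusionCounts:
    def test_planted_toy_counts(self):
        # 5 pos, 5 neg on one feature; rule "high" covers 4 pos, 1 neg
        from fuzzysd import BucketTable

        X = np.array([[0.9], [0.8], [0.95], [0.7], [0.2],
                      [0.9], [0.1], [0.15], [0.2], [0.3]])
        t = BucketTable([f"s{i}" for i in range(10)], ["5.00-5.10"], X,
                        ["p"] * 5 + ["n"] * 5, "p")
        part = build_partitions(t)
        c = confusion_counts(Rule({"5.00-5.10": "high"}, "p"), t, part)
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 1, 1, 4)

    def test_rule_covering_nothing(self, toy_table):
        part = build_partitions(toy_table)
        # cases sit high on feature 0; a 'ctrl'-target rule on 'high' values
        rule = Rule({"7.00-7.10": "high"}, "ctrl")
        c = confusion_counts(rule, toy_table, part)
        assert c.tp + c.fp == np.sum(
            part.membership("7.00-7.10", "high", toy_table.intensities[:, 0]) > 0
        )
        assert c.n == toy_table.n_samples

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)


class TestScalarMeasures:
    @pytest.mark.parametrize("c,expected", [
        (ConfusionCounts(5, 0, 0, 5), 1.0),
        (ConfusionCounts(0, 5, 5, 0), 0.0),
        (ConfusionCounts(37, 7, 3, 5), 42 / 52),
    ])
    def test_accuracy(self, c, expected):
        assert accuracy(c) == pytest.approx(expected)

    def test_rates_from_table4_counts(self):
        assert rates(ConfusionCounts(12, 16, 0, 24)) == pytest.approx((1.0, 0.4))
        tpr, fpr = rates(ConfusionCounts(37, 7, 3, 5))
        assert (round(tpr, 3), round(fpr, 3)) == (0.925, 0.583)

    @pytest.mark.parametrize("tpr,fpr,expected", [
        (1.0, 0.0, 1.0), (0.3, 0.3, 0.5), (0.7, 0.2, 0.75),
    ])
    def test_auroc_single_point(self, tpr, fpr, expected):
        assert auroc(tpr, fpr) == pytest.approx(expected)

    def test_auroc_diagonal_property(self):
        for r in np.linspace(0, 1, 11):
            assert auroc(r, r) == pytest.approx(0.5)

    def test_auroc_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            auroc(1.2, 0.0)

    def test_wracc_hand_values(self):
        assert wracc(ConfusionCounts(12, 16, 0, 24)) == pytest.approx(
            (28 / 52) * (12 / 28 - 12 / 52)
        )
        assert wracc(ConfusionCounts(37, 7, 3, 5)) == pytest.approx(0.0606, abs=5e-4)

    def test_wracc_whole_dataset_rule_is_zero(self):
        assert wracc(ConfusionCounts(12, 40, 0, 0)) == pytest.approx(0.0)

    def test_empty_coverage_wracc_zero(self):
        assert wracc(ConfusionCounts(0, 0, 12, 40)) == 0.0


class TestUnusualness:
    @pytest.mark.parametrize("name,cls,n_pos,n_neg,_v,unus_printed,tpr,fpr,_t", TABLE4)
    def test_all_published_rows_reconstruct(self, name, cls, n_pos, n_neg,
                                            _v, unus_printed, tpr, fpr, _t):
        c = reconstruct_counts_from_rates(tpr, fpr, n_pos, n_neg)
        assert round(unusualness(c), 3) == unus_printed

    def test_midpoint_when_confidence_equals_prior(self):
        assert unusualness(ConfusionCounts(12, 40, 0, 0)) == pytest.approx(0.5)

    def test_above_half_iff_confidence_exceeds_prior(self):
        enriched = ConfusionCounts(10, 5, 2, 35)     # conf 2/3 > prior 12/52
        depleted = ConfusionCounts(2, 30, 10, 10)    # conf 1/16 < prior
        assert unusualness(enriched) > 0.5 > unusualness(depleted)

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            unusualness(ConfusionCounts(3, 0, 2, 0))


class TestReconstructCounts:
    @pytest.mark.parametrize("tpr,fpr,n_pos,n_neg,tp,fp", [
        (0.925, 0.583, 40, 12, 37, 7),
        (0.675, 0.083, 40, 12, 27, 1),
        (1.0, 0.0, 12, 40, 12, 0),
    ])
    def test_rounding_recovers_integers(self, tpr, fpr, n_pos, n_neg, tp, fp):
        c = reconstruct_counts_from_rates(tpr, fpr, n_pos, n_neg)
        assert (c.tp, c.fp) == (tp, fp)
        assert (c.n_pos, c.n_neg) == (n_pos, n_neg)


class TestFuzzyConfidence:
    def test_reduces_to_crisp_confidence_on_binary_memberships(self, toy_table):
        part = build_partitions(toy_table)
        rule = Rule({"7.00-7.10": "high"}, "case")
        comp = part.rule_compatibility(rule, toy_table.intensities)
        crisp = (comp > 0).astype(float)
        pos = toy_table.class_mask("case")
        expected_crisp = crisp[pos].sum() / crisp.sum()
        c = confusion_counts(rule, toy_table, part)
        assert crisp_confidence(c) == pytest.approx(expected_crisp)

    def test_hand_summed_memberships(self):
        from fuzzysd import BucketTable
        from fuzzysd.fuzzy import FuzzyPartition

        part = FuzzyPartition(feature_names=["f"], domains=np.array([[0.0, 1.0]]))
        # memberships of 'high': pos {1.0, 0.5}, neg {0.5}
        X = np.array([[1.0], [0.75], [0.75]])
        t = BucketTable(["a", "b", "c"], ["f"], X, ["p", "p", "n"], "p")
        assert fuzzy_confidence(Rule({"f": "high"}, "p"), t, part) == pytest.approx(0.75)

    def test_pure_target_coverage_gives_one(self, toy_table):
        part = build_partitions(toy_table)
        rule = Rule({"7.00-7.10": "high"}, "case")
        comp = part.rule_compatibility(rule, toy_table.intensities)
        if np.all(comp[~toy_table.class_mask("case")] == 0):
            assert fuzzy_confidence(rule, toy_table, part) == pytest.approx(1.0)


class TestFisherExact:
    @pytest.mark.parametrize("c,expected", [
        (ConfusionCounts(1, 1, 1, 1), 1.0),
        (ConfusionCounts(0, 0, 3, 4), 1.0),   # zero margin: single table
        (ConfusionCounts(5, 0, 0, 0), 1.0),
    ])
    def test_trivial_tables(self, c, expected):
        assert fisher_exact_two_sided(c) == expected

    @pytest.mark.parametrize("name,cls,n_pos,n_neg,_v,_u,tpr,fpr,tef", TABLE4)
    def test_published_tef_values_by_truncation(self, name, cls, n_pos, n_neg,
                                                _v, _u, tpr, fpr, tef):
        c = reconstruct_counts_from_rates(tpr, fpr, n_pos, n_neg)
        p = fisher_exact_two_sided(c)
        assert math.floor(p * 1000) / 1000 == tef

    def test_rows_printed_zero_are_below_half_a_thousandth(self):
        for name, cls, n_pos, n_neg, _v, _u, tpr, fpr, tef in TABLE4:
            if tef == 0.0:
                c = reconstruct_counts_from_rates(tpr, fpr, n_pos, n_neg)
                assert fisher_exact_two_sided(c) < 0.0005

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 61))
            cells = rng.multinomial(n, [0.25] * 4)
            c = ConfusionCounts(*map(int, cells))
            mine = fisher_exact_two_sided(c)
            oracle = float(enumeration_fisher(c))
            assert mine == pytest.approx(oracle, rel=1e-12, abs=1e-300)

    def test_agrees_with_scipy_away_from_ties(self):
        # scipy compares point probabilities with a small relative slack,
        # so exact agreement can only be demanded when no other table's
        # pmf sits within that slack of the observed one
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(200):
            cells = rng.multinomial(int(rng.integers(4, 50)), [0.25] * 4)
            c = ConfusionCounts(*map(int, cells))
            r1, c1, n = c.tp + c.fp, c.tp + c.fn, c.n
            if r1 in (0, n) or c1 in (0, n):
                continue
            pmfs = {
                a: math.comb(c1, a) * math.comb(n - c1, r1 - a)
                for a in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
            }
            obs = pmfs[c.tp]
            near_tie = any(
                a != c.tp and w != obs and abs(w - obs) <= 1e-6 * obs
                for a, w in pmfs.items()
            )
            if near_tie:
                continue
            p_scipy = scipy_fisher([[c.tp, c.fp], [c.fn, c.tn]]).pvalue
            assert fisher_exact_two_sided(c) == pytest.approx(p_scipy, rel=1e-7)
            checked += 1
        assert checked > 100


class TestQualityReport:
    def test_full_report_fields_in_range(self, toy_table):
        part = build_partitions(toy_table)
        rep = quality_report(Rule({"7.00-7.10": "high"}, "case"), toy_table, part)
        for field in ("unusualness", "tp_rate", "fp_rate", "confidence",
                      "fuzzy_confidence", "tef", "accuracy", "auroc"):
            assert 0.0 <= getattr(rep, field) <= 1.0
        assert rep.n_vars == 1
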