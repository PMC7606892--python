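"""Stratum labelling and the contingency/correlation statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iesretention import (
    ExpressionTable,
    TerminalPWM,
    ValidationError,
    assign_size_class,
    classify_expression,
    count_ratio_by_size_class,
    epi_enrichment,
    exclusive_overlap,
    fisher_one_tail,
    kendall_tau,
    label_strata,
    median_irs_by_size_class,
    ptc_fold,
    two_proportion_test,
    wilcoxon_rank_sum,
)
from iesretention.irs import IRSRecord
from iesretention.strata import StratumLabel

from conftest import make_locus


class TestClassifyExpression:
    def test_monotone_transform_invariance(self):
        vals = {f"g{i}": float(v) for i, v in enumerate(np.random.default_rng(0).uniform(1, 100, 60))}
        cubed = {g: v**3 for g, v in vals.items()}
        assert classify_expression(ExpressionTable(vals)) == classify_expression(
            ExpressionTable(cubed)
        )

    def test_identical_values_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            classify_expression(ExpressionTable({f"g{i}": 5.0 for i in range(10)}))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            classify_expression(ExpressionTable({"a": 1.0, "b": 2.0}))

    def test_zero_expression_never_labelled(self):
        vals = {f"g{i}": float(i + 1) for i in range(20)}
        vals["gz"] = 0.0
        labels = classify_expression(ExpressionTable(vals))
        assert "gz" not in labels


class TestSizeClasses:
    @pytest.mark.parametrize(
        "length,expected",
        [(26, "26-30"), (28, "26-30"), (30, "26-30"), (35, "unbinned"),
         (44, "44-45"), (60, "54-60"), (100, "94-100"), (101, "unbinned")],
    )
    def test_assignment(self, length, expected):
        assert assign_size_class(length) == expected

    def test_below_minimum_rejected(self):
        with pytest.raises(ValidationError):
            assign_size_class(25)

    def test_label_strata_small_large_boundary(self):
        loci = [
            make_locus("s", interior="G" * 28),  # length 30: small
            make_locus("l", interior="G" * 42),  # length 44: large
        ]
        labels = label_strata(loci)
        assert labels["s"].small_or_large == "small"
        assert labels["l"].small_or_large == "large"


class TestTwoProportion:
    def test_swap_symmetry(self):
        assert two_proportion_test(12, 100, 40, 200) == pytest.approx(
            two_proportion_test(40, 200, 12, 100)
        )

    def test_equal_proportions_p_one(self):
        assert two_proportion_test(5, 100, 5, 100) == pytest.approx(1.0)

    def test_one_sided_halves_symmetric_two_sided(self):
        p_two = two_proportion_test(30, 100, 15, 100)
        p_greater = two_proportion_test(30, 100, 15, 100, alternative="greater")
        p_less = two_proportion_test(30, 100, 15, 100, alternative="less")
        assert p_greater == pytest.approx(p_two / 2, rel=1e-6)
        assert p_greater + p_less == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            two_proportion_test(1, 0, 1, 10)
        with pytest.raises(ValidationError):
            two_proportion_test(11, 10, 1, 10)


class TestFisherOneTail:
    def test_enrichment_free_table_p_one(self):
        """Cell a empty: the greater alternative can never be enriched."""
        assert fisher_one_tail(0, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Exact enumeration oracle via binomial coefficients, N <= 40 grid."""

        def oracle(a, b, c, d):
            # P(X >= a) for X ~ Hypergeom(N, a+b, a+c)
            n1, m, N = a + b, a + c, a + b + c + d
            num = 0.0
            den = 0.0
            for x in range(max(0, m - (N - n1)), min(n1, m) + 1):
                w = math.comb(n1, x) * math.comb(N - n1, m - x)
                den += w
                if x >= a:
                    num += w
            return num / den

        rng = np.random.default_rng(2)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_one_tail(int(a), int(b), int(c), int(d)) == pytest.approx(
                oracle(int(a), int(b), int(c), int(d)), rel=1e-9, abs=1e-12
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_one_tail(0, 0, 0, 0)


class TestRankStatistics:
    def test_kendall_perfect_concordance(self):
        x = list(range(10))
        tau, _ = kendall_tau(x, x)
        assert tau == pytest.approx(1.0)
        tau_rev, _ = kendall_tau(x, x[::-1])
        assert tau_rev == pytest.approx(-1.0)

    def test_kendall_matches_pair_enumeration(self):
        """tau-b from O(n^2) pair counting with tie corrections, n=50."""
        rng = np.random.default_rng(9)
        x = rng.integers(0, 8, 50).astype(float)  # ties on purpose
        y = (x + rng.normal(0, 2, 50)).round()
        conc = disc = tx = ty = 0
        for i, j in itertools.combinations(range(50), 2):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
        denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx((conc - disc) / denom, rel=1e-9)

    def test_kendall_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            kendall_tau([1, 1, 1], [1, 2, 3])

    def test_wilcoxon_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert wilcoxon_rank_sum(a, a) > 0.9

    def test_wilcoxon_matches_permutation_oracle(self):
        """Disjoint-support samples: normal approximation within 2% of the
        exact permutation distribution of the rank sum."""
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        b = [10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0]
        pooled = a + b
        obs = sum(sorted(pooled).index(v) + 1 for v in a)
        count = 0
        total = 0
        for comb in itertools.combinations(range(14), 7):
            rs = sum(c + 1 for c in comb)
            total += 1
            if rs <= obs or rs >= (sum(range(1, 15)) - obs):
                count += 1
        exact = count / total
        approx = wilcoxon_rank_sum(a, b)
        assert approx == pytest.approx(exact, abs=0.02)

    def test_wilcoxon_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0, 4.0])


def _labels_for(records, size, location="exon"):
    return {
        r.ies_id: StratumLabel(
            ies_id=r.ies_id,
            expression_class="mid",
            size_class=size,
            small_or_large="small" if int(size.split("-")[1]) <= 32 else "large",
            location_class=location,
            epi_class="none",
        )
        for r in records
    }


class TestSizeClassProcedures:
    @staticmethod
    def _records(values, prefix="r"):
        return [IRSRecord(f"{prefix}{i}", v, 100) for i, v in enumerate(values)]

    def test_identical_tables_all_ratios_one(self):
        recs = self._records([0.3] * 5 + [0.05] * 5)
        labels = _labels_for(recs, "26-30")
        out = count_ratio_by_size_class(recs, recs, labels)
        assert out["per_class"]["26-30"]["ratio"] == pytest.approx(1.0)
        assert out["pooled_small"]["ratio"] == pytest.approx(1.0)

    def test_class_below_minimum_dropped(self):
        f0 = self._records([0.3] * 5)
        f1 = self._records([0.3, 0.3] + [0.05] * 3)  # only 2 retained
        labels = _labels_for(f0, "26-30")
        out = count_ratio_by_size_class(f0, f1, labels)
        assert "26-30" not in out["per_class"]

    def test_median_single_and_pair(self):
        recs = self._records([0.4])
        labels = _labels_for(recs, "44-45")
        med = median_irs_by_size_class(recs, labels, min_per_class=1)
        assert med["44-45"] == pytest.approx(0.4)
        recs2 = self._records([0.2, 0.4])
        med2 = median_irs_by_size_class(recs2, _labels_for(recs2, "44-45"), min_per_class=1)
        assert med2["44-45"] == pytest.approx(0.3)

    def test_filtered_records_ignored(self):
        recs = self._records([0.5] * 4)
        recs.append(IRSRecord("bad", 0.5, 5, passed_filters=False, filter_reasons=["low_coverage"]))
        labels = _labels_for(recs, "26-30")
        out = count_ratio_by_size_class(recs, recs, labels)
        assert out["per_class"]["26-30"]["f0"] == 4


class TestEnrichmentAndOverlap:
    def test_epi_observed_equals_expected_when_sets_equal(self):
        recs = [IRSRecord(f"i{k}", 0.5, 50) for k in range(10)]
        labels = _labels_for(recs, "26-30")
        for k in (0, 1, 2):
            labels[f"i{k}"] = StratumLabel(f"i{k}", "mid", "26-30", "small", "exon", "DCL2/3")
        ids = [r.ies_id for r in recs]
        obs, exp, _ = epi_enrichment(ids, ids, labels, "DCL2/3")
        assert obs == pytest.approx(exp) == pytest.approx(0.3)

    def test_epi_enrichment_detects_planted_excess(self):
        labels = {}
        for k in range(100):
            epi = "DCL5" if k < 20 else "none"
            labels[f"i{k}"] = StratumLabel(f"i{k}", "mid", "44-45", "large", "exon", epi)
        retained = [f"i{k}" for k in range(15)] + ["i50"]  # 15/16 epi
        obs, exp, p = epi_enrichment(retained, list(labels), labels, "DCL5")
        assert obs > exp and p < 0.001

    def test_empty_retained_rejected(self):
        labels = {"a": StratumLabel("a", "mid", "26-30", "small", "exon", "none")}
        with pytest.raises(ValidationError):
            epi_enrichment([], ["a"], labels, "DCL5")

    def test_ptc_fold_values(self):
        assert ptc_fold(348, 147)["rounded"] == pytest.approx(2.4)
        assert ptc_fold(14, 1)["fold"] == pytest.approx(14.0)
        assert ptc_fold(80, 41)["fold"] <= 2.0
        inf = ptc_fold(3, 0)
        assert inf["infinite"] and math.isinf(inf["fold"])

    def test_exclusive_overlap_set_algebra(self):
        rng = np.random.default_rng(4)
        universe = [f"x{i}" for i in range(200)]
        named = {
            "A": set(rng.choice(universe, 80, replace=False)),
            "B": set(rng.choice(universe, 80, replace=False)),
        }
        excluded = {"C": set(rng.choice(universe, 60, replace=False))}
        out = exclusive_overlap(named, excluded)
        brute = (named["A"] & named["B"]) - excluded["C"]
        assert set(out["shared_ids"]) == brute

    def test_exclusivity_and_errors(self):
        assert exclusive_overlap({"A": {"x"}, "B": {"y"}})["n_shared"] == 0
        out = exclusive_overlap({"A": {"x"}, "B": {"x"}}, {"C": {"x"}})
        assert out["n_shared"] == 0  # present in an excluded set
        with pytest.raises(ValidationError):
            exclusive_overlap({"A": {"x"}})
        with pytest.raises(ValidationError):
            exclusive_overlap({"A": {"x"}, "B": {"y"}}, {"A": {"z"}})


class TestTerminalPWM:
    TRAIN = [
        "TATTGCAA" + "G" * 20 + "TTGCAATA",
        "TATTGCAA" + "C" * 20 + "TTGCAATA",
        "TATTGCAT" + "G" * 20 + "ATGCAATA",
        "TATTGCAT" + "C" * 20 + "ATGCAATA",
        "TAATGCAA" + "G" * 20 + "TTGCATTA",
    ]

    def test_consensus_scores_one(self):
        pwm = TerminalPWM.fit(self.TRAIN[:2], w=8)  # identical termini
        assert pwm.score(self.TRAIN[0]) == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        """Score equals the hand-average of per-position normalized freqs."""
        pwm = TerminalPWM.fit(self.TRAIN, w=8)
        # left terminus of TRAIN[4]: differs at positions 2 (A, freq 1/5)
        # and 7 (A, freq 3/5); max freqs are 4/5 and 3/5 there
        seq = self.TRAIN[4]
        vals = []
        for i, base in enumerate(seq[:8]):
            col = [s[:8][i] for s in self.TRAIN]
            f = col.count(base) / 5
            vals.append(f / (max(col.count(b) for b in "ACGT") / 5))
        for i, base in enumerate(seq[-8:]):
            col = [s[-8:][i] for s in self.TRAIN]
            f = col.count(base) / 5
            vals.append(f / (max(col.count(b) for b in "ACGT") / 5))
        assert pwm.score(seq) == pytest.approx(float(np.mean(vals)))

    def test_score_in_unit_interval(self):
        pwm = TerminalPWM.fit(self.TRAIN, w=8)
        for s in self.TRAIN:
            assert 0.0 <= pwm.score(s) <= 1.0

    def test_short_sequence_rejected(self):
        pwm = TerminalPWM.fit(self.TRAIN, w=8)
        with pytest.raises(ValidationError):
            pwm.score("TATTGCAATA")
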