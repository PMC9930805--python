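"""MD/MAD accuracy statistics, normality-gated tests, Wilcoxon, kappa."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dentage.errors import InsufficientDataError, OutOfRangeError
from dentage.evaluation import (
    AGE_GROUPS,
    accuracy_stats,
    assign_age_group,
    cohens_kappa,
    evaluate_method,
    normality_test,
    paired_location_test,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(differences):
    """Exact two-sided signed-rank p by brute-force over all 2^n sign patterns.

    Independent of the implementation: recomputes W+ for every pattern and
    uses the same two-sided convention 2*min(P<=, P>=) capped at 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= w_obs + 1e-12)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestAssignAgeGroup:
    @pytest.mark.parametrize(
        "ca, label",
        [
            (6.74, "6.01-7.00"),
            (7.00, "6.01-7.00"),
            (7.005, "7.01-8.00"),  # rounds to 7.01 before binning
            (14.99, "14.01-15.00"),
            (6.01, "6.01-7.00"),
        ],
    )
    def test_binning(self, ca, label):
        assert assign_age_group(ca).label == label

    @pytest.mark.parametrize("ca", [5.9, 6.0, 15.01, 20.0])
    def test_out_of_range_rejected(self, ca):
        with pytest.raises(OutOfRangeError):
            assign_age_group(ca)

    def test_groups_partition_six_to_fifteen(self):
        assert len(AGE_GROUPS) == 9
        for lo, hi in zip(AGE_GROUPS, AGE_GROUPS[1:]):
            assert lo.upper == hi.lower


class TestAccuracyStats:
    def test_symmetric_pair_has_zero_md_unit_mad(self):
        rep = accuracy_stats([(10.0, 11.0), (10.0, 9.0)])
        assert rep.md == pytest.approx(0.0)
        assert rep.mad == pytest.approx(1.0)
        assert rep.mad > abs(rep.md)

    def test_perfect_agreement(self):
        rep = accuracy_stats([(8.0, 8.0), (9.0, 9.0), (10.0, 10.0)])
        assert rep.md == 0.0 and rep.mad == 0.0

    def test_md_is_mean_da_minus_mean_ca(self, rng):
        ca = rng.uniform(6, 15, 50)
        da = ca + rng.normal(0.3, 0.5, 50)
        rep = accuracy_stats(list(zip(ca, da)))
        assert rep.md == pytest.approx(rep.mean_da - rep.mean_ca, abs=1e-12)

    def test_ci_uses_t_quantile(self):
        d = [0.2, -0.1, 0.4, 0.3, 0.0]
        pairs = [(10.0, 10.0 + x) for x in d]
        rep = accuracy_stats(pairs)
        half = stats.t.ppf(0.975, 4) * np.std(d, ddof=1) / np.sqrt(5)
        assert rep.ci_high - rep.md == pytest.approx(half, abs=1e-12)
        assert rep.md - rep.ci_low == pytest.approx(half, abs=1e-12)

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            accuracy_stats([(10.0, 11.0)])

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=6, max_value=15),
                st.floats(min_value=3, max_value=18),
            ),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_mad_dominates_absolute_md(self, pairs):
        rep = accuracy_stats(pairs)
        assert rep.mad >= abs(rep.md) - 1e-12
        d = np.array([da - ca for ca, da in pairs])
        one_signed = np.all(d >= 0) or np.all(d <= 0)
        if one_signed:
            assert rep.mad == pytest.approx(abs(rep.md), abs=1e-12)


class TestNormalityGate:
    def test_normal_sample_passes(self, rng):
        assert normality_test(rng.normal(0, 1, 100)) > 0.05

    def test_bimodal_sample_fails(self):
        d = np.array([-1.0] * 50 + [1.0] * 50)
        assert normality_test(d) < 0.05

    def test_constant_sample_is_degenerate(self):
        assert normality_test([0.5] * 10) == 0.0

    def test_gate_switches_test_used(self, rng):
        normal = rng.normal(0.2, 1.0, 60)
        assert paired_location_test(normal).test_used == "paired_t"
        bimodal = np.array([-1.0] * 30 + [1.001] * 30)
        assert paired_location_test(bimodal).test_used == "wilcoxon"


class TestPairedLocationTest:
    def test_symmetric_two_point_sample_gives_p_one(self):
        res = paired_location_test([-1.0, 1.0])
        assert res.test_used == "paired_t"
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_convention(self):
        assert paired_location_test([0.0] * 10).p_value == 1.0


class TestWilcoxonSignedRank:
    def test_balanced_ranks_give_p_one(self):
        assert wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0]) == pytest.approx(1.0)

    def test_all_positive_attains_minimum_p(self):
        p = wilcoxon_signed_rank([0.5] * 10)
        assert p == pytest.approx(2.0 / 2**10)

    @pytest.mark.parametrize(
        "d",
        [
            [1.0, -2.0, 3.0, -4.0, 5.0],
            [0.5, 0.5, -0.5, 1.5, 2.5, -2.5],  # ties across signs
            [1, 1, 1, -1, 2, -2, 3],
            [0.3, -0.3, 0.3, 0.7, -0.1, 0.2, -0.6, 0.4],
            [2.0, 0.0, -1.0, 3.0, 0.0, 1.0],  # zeros dropped
        ],
    )
    def test_matches_sign_pattern_enumeration(self, d):
        assert wilcoxon_signed_rank(d) == pytest.approx(
            wilcoxon_enumeration_oracle(d), abs=1e-12
        )

    def test_matches_scipy_exact_when_tie_free(self, rng):
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 12)
            expected = stats.wilcoxon(d, method="exact").pvalue
            assert wilcoxon_signed_rank(d) == pytest.approx(expected, abs=1e-12)

    def test_large_sample_normal_approximation_is_close(self, rng):
        d = rng.normal(0.1, 1.0, 60)
        approx = wilcoxon_signed_rank(d)
        expected = stats.wilcoxon(d, method="approx", correction=False).pvalue
        assert approx == pytest.approx(expected, rel=1e-6)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(list("ABCDABCD"), list("ABCDABCD")) == pytest.approx(1.0)

    def test_binary_four_one_one_four_table(self):
        a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        b = [1, 1, 1, 1, 0, 1, 0, 0, 0, 0]
        assert cohens_kappa(a, b) == pytest.approx(0.6)

    def test_independent_ratings_near_zero(self, rng):
        a = rng.integers(0, 8, 20000)
        b = rng.integers(0, 8, 20000)
        assert abs(cohens_kappa(a, b)) < 0.02

    def test_invariant_under_category_relabeling(self, rng):
        a = rng.integers(0, 4, 500)
        b = np.where(rng.random(500) < 0.7, a, rng.integers(0, 4, 500))
        relabel = {0: "D", 1: "C", 2: "B", 3: "A"}
        ra = [relabel[x] for x in a]
        rb = [relabel[x] for x in b]
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(ra, rb), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(0, 5, 300)
        b = np.where(rng.random(300) < 0.6, a, rng.integers(0, 5, 300))
        assert cohens_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_identical_constant_raters_undefined(self):
        assert np.isnan(cohens_kappa([1, 1, 1], [1, 1, 1]))


class TestEvaluateMethod:
    @staticmethod
    def _cohort(rng, n_per_cell=6):
        rows = []
        for sex in ("male", "female"):
            for lo in range(6, 15):
                for _ in range(n_per_cell):
                    ca = float(rng.integers(lo * 100 + 1, lo * 100 + 101)) / 100
                    rows.append({"sex": sex, "ca_years": ca})
        return pd.DataFrame(rows)

    def test_constant_shift_propagates_to_every_group(self, rng):
        frame = self._cohort(rng)
        frame["da_years"] = frame["ca_years"] + 0.5
        report = evaluate_method(frame)
        assert np.allclose(report["md"], 0.5)
        assert np.allclose(report["mad"], 0.5)

    def test_report_layout_has_twenty_one_rows(self, rng):
        frame = self._cohort(rng)
        frame["da_years"] = frame["ca_years"]
        report = evaluate_method(frame)
        assert len(report) == 9 * 2 + 2 + 1
        assert (report["age_group"] == "total").sum() == 3

    def test_grand_total_md_is_count_weighted_group_mean(self, rng):
        frame = self._cohort(rng)
        frame["da_years"] = frame["ca_years"] + rng.normal(0.2, 0.6, len(frame))
        report = evaluate_method(frame)
        groups = report[(report["age_group"] != "total")]
        grand = report[(report["sex"] == "all")].iloc[0]
        weighted = (groups["md"] * groups["n"]).sum() / groups["n"].sum()
        assert grand["md"] == pytest.approx(weighted, abs=1e-12)

    def test_perfect_estimator_gives_null_report(self, rng):
        frame = self._cohort(rng)
        frame["da_years"] = frame["ca_years"]
        report = evaluate_method(frame)
        assert np.allclose(report["md"], 0.0)
        assert np.allclose(report["mad"], 0.0)
        assert np.allclose(report["p_value"], 1.0)
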