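"""Unit and property tests for the threshold-ladder core."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrfdr import (
    ConfigurationError,
    InvalidArgumentError,
    SortedScreenInput,
    adjust_pvalues,
    build_ladder,
    harmonic_constant,
    increment,
    reject,
    screen_sorted,
)
from corrfdr.procedures import M_PROCEDURES, PROCEDURES

from conftest import random_sorted_input

# ---------------------------------------------------------------------------
# reference values for the eight-test worked example (alpha = 0.1), at the
# 4-decimal display precision of the published comparison table
# ---------------------------------------------------------------------------
EXAMPLE_THRESHOLDS = {
    "BF": [0.0125, 0.0125, 0.0125, 0.0125, 0.0125, 0.0125, 0.0125, 0.0125],
    "BH": [0.0125, 0.0250, 0.0375, 0.0500, 0.0625, 0.0750, 0.0875, 0.1000],
    "BY": [0.0046, 0.0092, 0.0138, 0.0184, 0.0230, 0.0276, 0.0322, 0.0368],
    "M1": [0.0125, 0.0227, 0.0269, 0.0276, 0.0298, 0.0311, 0.0395, 0.0401],
    "M2": [0.0125, 0.0238, 0.0300, 0.0312, 0.0350, 0.0375, 0.0475, 0.0488],
    "M3": [0.0125, 0.0249, 0.0343, 0.0366, 0.0430, 0.0475, 0.0595, 0.0619],
}
EXAMPLE_ADJUSTED = {
    "BF": [0.0184, 0.0784, 0.1112, 0.1768, 0.2784, 0.3368, 0.3704, 0.4160],
    "BH": [0.0184, 0.0392, 0.0371, 0.0442, 0.0557, 0.0561, 0.0529, 0.0520],
    "BY": [0.0500, 0.1065, 0.1007, 0.1201, 0.1513, 0.1526, 0.1438, 0.1413],
    "M1": [0.0184, 0.0431, 0.0517, 0.0802, 0.1169, 0.1352, 0.1173, 0.1296],
    "M2": [0.0184, 0.0413, 0.0463, 0.0707, 0.0994, 0.1123, 0.0975, 0.1067],
    "M3": [0.0184, 0.0394, 0.0406, 0.0603, 0.0809, 0.0886, 0.0778, 0.0840],
}
# largest rank satisfying p_(i) <= threshold_i, per procedure
EXAMPLE_K = {"BF": 2, "BH": 8, "BY": 1, "M1": 4, "M2": 7, "M3": 8}


class TestHarmonicConstant:
    @pytest.mark.parametrize("P, expected", [(1, 1.0), (2, 1.5), (8, 2.717857142857143)])
    def test_small_values(self, P, expected):
        assert harmonic_constant(P) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("P", [3, 17, 50, 1000])
    def test_matches_exact_rational_sum(self, P):
        exact = float(sum(Fraction(1, i) for i in range(1, P + 1)))
        assert abs(harmonic_constant(P) - exact) < 1e-12

    @pytest.mark.parametrize("bad", [0, -3, 2.5, "8", True])
    def test_rejects_non_positive_or_non_integer(self, bad):
        with pytest.raises(InvalidArgumentError):
            harmonic_constant(bad)


class TestIncrement:
    @pytest.mark.parametrize("mode", ["strong", "moderate", "mild"])
    def test_independence_gives_full_information(self, mode):
        assert increment(0.0, mode) == 1.0

    @pytest.mark.parametrize("mode", ["strong", "moderate", "mild"])
    @pytest.mark.parametrize("r", [1.0, -1.0])
    def test_collinearity_gives_zero_information(self, r, mode):
        assert increment(r, mode) == 0.0

    def test_worked_values_at_r_01(self):
        assert increment(0.1, "strong") == pytest.approx(0.9 / 1.1)
        assert increment(0.1, "moderate") == pytest.approx(0.9)
        assert increment(0.1, "mild") == pytest.approx(0.99)

    @given(st.floats(-1.0, 1.0, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_strength_ordering_and_range(self, r):
        strong = increment(r, "strong")
        moderate = increment(r, "moderate")
        mild = increment(r, "mild")
        assert 0.0 <= strong <= moderate <= mild <= 1.0

    def test_clamps_floating_error_but_rejects_real_violations(self):
        assert increment(1.0 + 5e-13, "mild") == 0.0
        with pytest.raises(InvalidArgumentError):
            increment(1.001, "mild")
        with pytest.raises(InvalidArgumentError):
            increment(float("nan"), "strong")
        with pytest.raises(InvalidArgumentError):
            increment(0.5, "severe")


class TestBuildLadder:
    @pytest.mark.parametrize("proc", PROCEDURES)
    def test_worked_example_thresholds_to_4dp(self, example, proc):
        inp, alpha = example
        ladder = build_ladder(inp, alpha, proc)
        # python round() is correctly rounded from the binary value, which
        # is what the published 4-dp table reflects (np.round rescales and
        # can flip ties like 0.03425)
        assert [round(float(t), 4) for t in ladder.thresholds] == EXAMPLE_THRESHOLDS[proc]

    def test_bh_and_by_closed_forms(self, rng):
        inp = random_sorted_input(rng, P=25)
        bh = build_ladder(inp, 0.05, "BH")
        by = build_ladder(inp, 0.05, "BY")
        ranks = np.arange(1, 26)
        np.testing.assert_allclose(bh.thresholds, ranks * 0.05 / 25, rtol=0, atol=0)
        np.testing.assert_allclose(
            by.thresholds, bh.thresholds / harmonic_constant(25), atol=1e-16
        )

    @pytest.mark.parametrize("proc", ["M1", "M2", "M3"])
    def test_zero_correlation_reduces_to_bh_exactly(self, rng, proc):
        p = np.sort(rng.uniform(0, 1, 30))
        inp = SortedScreenInput.from_pvalues(p, np.zeros(29))
        m = build_ladder(inp, 0.05, proc)
        bh = build_ladder(inp, 0.05, "BH")
        assert np.abs(m.thresholds - bh.thresholds).max() < 1e-12
        assert np.abs(m.multipliers - bh.multipliers).max() < 1e-12

    @pytest.mark.parametrize("proc", ["M1", "M2", "M3"])
    def test_full_collinearity_reduces_to_bonferroni(self, rng, proc):
        p = np.sort(rng.uniform(0, 1, 30))
        signs = np.where(rng.uniform(size=29) < 0.5, -1.0, 1.0)
        inp = SortedScreenInput.from_pvalues(p, signs)
        m = build_ladder(inp, 0.05, proc)
        bf = build_ladder(inp, 0.05, "BF")
        assert np.abs(m.multipliers - 1.0).max() == 0.0
        np.testing.assert_array_equal(m.thresholds, bf.thresholds)
        assert reject(inp, m).k == reject(inp, bf).k

    def test_multipliers_match_bruteforce_cumulative_sums(self, rng):
        """Recurrence l_i = l_{i-1} + inc equals a fresh per-rank summation."""
        for _ in range(50):
            inp = random_sorted_input(rng)
            for proc, mode in M_PROCEDURES.items():
                ladder = build_ladder(inp, 0.05, proc)
                for i in range(inp.P):
                    expected = 1.0 + math.fsum(
                        increment(float(r), mode) for r in inp.r_consecutive[:i]
                    )
                    assert abs(ladder.multipliers[i] - expected) < 1e-12

    def test_multiplier_bounds_and_step_sizes(self, rng):
        for _ in range(50):
            inp = random_sorted_input(rng)
            for proc in M_PROCEDURES:
                l = build_ladder(inp, 0.05, proc).multipliers
                ranks = np.arange(1, inp.P + 1)
                assert (l >= 1.0 - 1e-12).all() and (l <= ranks + 1e-12).all()
                steps = np.diff(l)
                assert ((steps >= -1e-15) & (steps <= 1.0 + 1e-15)).all()

    def test_thresholds_monotone_in_rank(self, rng):
        for _ in range(30):
            inp = random_sorted_input(rng)
            for proc in ("BH", "BY", "M1", "M2", "M3"):
                thr = build_ladder(inp, 0.05, proc).thresholds
                assert (np.diff(thr) >= -1e-15).all()

    def test_errors(self, rng):
        inp = random_sorted_input(rng, P=5, with_r=False)
        with pytest.raises(ConfigurationError):
            build_ladder(inp, 0.05, "M1")
        full = random_sorted_input(rng, P=5)
        for bad_alpha in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(InvalidArgumentError):
                build_ladder(full, bad_alpha, "BH")
        with pytest.raises(InvalidArgumentError):
            build_ladder(full, 0.05, "XX")


class TestAdjustedPvalues:
    @pytest.mark.parametrize("proc", PROCEDURES)
    def test_worked_example_adjusted_to_4dp(self, example, proc):
        inp, alpha = example
        adj = adjust_pvalues(inp, proc, alpha)
        assert [round(float(a), 4) for a in adj] == EXAMPLE_ADJUSTED[proc]

    def test_single_hypothesis_is_identity(self):
        inp = SortedScreenInput.from_pvalues([0.031])
        for proc in PROCEDURES:
            r_needed = proc in M_PROCEDURES
            one = SortedScreenInput.from_pvalues([0.031], np.empty(0) if r_needed else None)
            assert adjust_pvalues(one, proc, 0.05)[0] == pytest.approx(0.031)

    def test_duality_with_thresholds(self, rng):
        """adjusted_p <= alpha exactly when p_(i) <= threshold_i, every rank."""
        for _ in range(200):
            inp = random_sorted_input(rng)
            alpha = float(rng.uniform(0.01, 0.2))
            for proc in PROCEDURES:
                ladder = build_ladder(inp, alpha, proc)
                adj = adjust_pvalues(inp, proc, alpha)
                np.testing.assert_array_equal(
                    adj <= alpha + 1e-15, inp.p_sorted <= ladder.thresholds + 1e-15
                )

    def test_monotone_variant_is_running_min_capped(self, example):
        inp, alpha = example
        for proc in PROCEDURES:
            raw = adjust_pvalues(inp, proc, alpha)
            mono = adjust_pvalues(inp, proc, alpha, monotone=True)
            assert (np.diff(mono) >= 0).all()
            assert (mono <= 1.0).all()
            assert (mono <= raw + 1e-15).all()
            # running minimum from the largest rank downward
            expected = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
            np.testing.assert_array_equal(mono, expected)

    def test_pointwise_adjustment_is_uncapped_and_non_monotone(self, example):
        inp, alpha = example
        bf = adjust_pvalues(inp, "BF", alpha)
        assert bf.max() > alpha  # 0.4160 > 0.1: deliberately uncapped
        bh = adjust_pvalues(inp, "BH", alpha)
        assert bh[2] < bh[1]  # rank 3 below rank 2: no monotone enforcement


class TestReject:
    @pytest.mark.parametrize("proc", PROCEDURES)
    def test_worked_example_k(self, example, proc):
        inp, alpha = example
        res = reject(inp, build_ladder(inp, alpha, proc))
        assert res.k == EXAMPLE_K[proc]
        assert res.rejected_ids.tolist() == list(inp.feature_ids[: EXAMPLE_K[proc]])

    def test_no_rejection_returns_k_zero(self):
        inp = SortedScreenInput.from_pvalues([0.9, 0.95], [0.0])
        for proc in PROCEDURES:
            assert reject(inp, build_ladder(inp, 0.05, proc)).k == 0

    def test_step_up_rejects_through_intermediate_failures(self):
        # rank 2 exceeds its own BH threshold but rank 3 does not: all
        # of ranks 1..3 are rejected by the max-k rule
        inp = SortedScreenInput.from_pvalues([0.001, 0.04, 0.05])
        ladder = build_ladder(inp, 0.1, "BH")  # thresholds 0.0333, 0.0667, 0.1
        res = reject(inp, ladder)
        assert inp.p_sorted[1] > ladder.thresholds[0]
        assert res.k == 3

    def test_length_mismatch_rejected(self, rng):
        a = random_sorted_input(rng, P=5)
        b = random_sorted_input(rng, P=6)
        with pytest.raises(InvalidArgumentError):
            reject(a, build_ladder(b, 0.05, "BH"))


class TestOrderingSandwich:
    def test_thresholds_and_k_ordered_across_procedures(self):
        """BF <= M1 <= M2 <= M3 <= BH per rank, BY <= BH; same for k."""
        rng = np.random.default_rng(777)
        for _ in range(1000):
            inp = random_sorted_input(rng)
            alpha = float(rng.uniform(0.01, 0.2))
            res = screen_sorted(inp, alpha)
            thr = {p: r.ladder.thresholds for p, r in res.items()}
            tol = 1e-12
            assert (thr["BF"] <= thr["M1"] + tol).all()
            assert (thr["M1"] <= thr["M2"] + tol).all()
            assert (thr["M2"] <= thr["M3"] + tol).all()
            assert (thr["M3"] <= thr["BH"] + tol).all()
            assert (thr["BY"] <= thr["BH"] + tol).all()
            k = {p: r.k for p, r in res.items()}
            assert k["BF"] <= k["M1"] <= k["M2"] <= k["M3"] <= k["BH"]
            assert k["BY"] <= k["BH"]


class TestAgainstIndependentStepUpImplementations:
    def test_bh_by_rejection_counts_match_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            P = int(rng.integers(2, 60))
            p = np.sort(rng.uniform(0, 1, P) ** rng.uniform(0.5, 3))
            inp = SortedScreenInput.from_pvalues(p)
            alpha = float(rng.uniform(0.01, 0.25))
            for proc, method in (("BH", "fdr_bh"), ("BY", "fdr_by")):
                ours = reject(inp, build_ladder(inp, alpha, proc)).k
                theirs = int(multipletests(p, alpha=alpha, method=method)[0].sum())
                assert ours == theirs


class TestInputValidation:
    def test_rejects_unsorted_or_out_of_range_pvalues(self):
        with pytest.raises(InvalidArgumentError):
            SortedScreenInput.from_pvalues([0.5, 0.1])
        with pytest.raises(InvalidArgumentError):
            SortedScreenInput.from_pvalues([-0.1, 0.5])
        with pytest.raises(InvalidArgumentError):
            SortedScreenInput.from_pvalues([0.1, float("nan")])

    def test_rejects_wrong_correlation_length_or_duplicate_ids(self):
        with pytest.raises(InvalidArgumentError):
            SortedScreenInput.from_pvalues([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(InvalidArgumentError):
            SortedScreenInput(np.array([0.1, 0.2]), np.array(["a", "a"]))
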