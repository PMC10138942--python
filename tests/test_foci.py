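"""Focus-count statistics: shares, the artificial population, rank tests."""

import itertools
import math

import numpy as np
import pytest

from chiasmetry import (
    FociRecord,
    artificial_population,
    compare_counts,
    fdr_adjust,
    marker_means,
    slide_consistency_check,
    weighted_mean_ratio,
)


def recs(sample, marker, counts):
    return [
        FociRecord(sample, f"slide_{marker}", f"{marker}_c{i}", marker, c)
        for i, c in enumerate(counts)
    ]


def spread(total, cells):
    base, extra = divmod(total, cells)
    return [base + 1 if i < extra else base for i in range(cells)]


class TestMarkerMeans:
    def test_published_cepa_row(self):
        records = recs("A_cepa", "MLH1", spread(409, 37)) + recs(
            "A_cepa", "MUS81", spread(158, 39)
        )
        share = marker_means(records, "A_cepa")
        assert share.mlh1_mean == 11.1
        assert share.mus81_mean == 4.1
        assert (share.mlh1_share, share.mus81_share) == (73, 27)

    def test_published_diploid_share(self):
        records = recs("F1", "MLH1", spread(320, 38)) + recs(
            "F1", "MUS81", spread(136, 37)
        )
        share = marker_means(records, "F1")
        assert (share.mlh1_share, share.mus81_share) == (70, 30)

    def test_equal_means_split_evenly(self):
        records = recs("S", "MLH1", [6, 6, 6]) + recs("S", "MUS81", [6, 6, 6])
        share = marker_means(records, "S")
        assert (share.mlh1_share, share.mus81_share) == (50, 50)

    def test_missing_marker_named(self):
        records = recs("S", "MLH1", [3, 4])
        with pytest.raises(ValueError, match="MUS81"):
            marker_means(records, "S")


class TestArtificialPopulation:
    def test_cross_product_enumeration(self):
        pop = artificial_population([2, 3], [1, 2])
        assert sorted(pop.ratios) == [1.0, 1.5, 2.0, 3.0]
        assert pop.n_pairs == 4
        assert pop.n_excluded == 0

    def test_single_pair(self):
        pop = artificial_population([5], [5])
        assert list(pop.ratios) == [1.0]

    def test_zero_denominators_excluded_and_tallied(self):
        pop = artificial_population([4, 4], [0, 2])
        assert sorted(pop.ratios) == [2.0, 2.0]
        assert pop.n_excluded == 2
        assert pop.n_pairs + pop.n_excluded == 2 * 2

    def test_all_excluded_is_an_error(self):
        with pytest.raises(ValueError, match="zero MUS81"):
            artificial_population([1, 2], [0, 0])

    def test_pair_count_identity_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.poisson(8, size=rng.integers(1, 12))
            b = rng.poisson(4, size=rng.integers(1, 12))
            if not (b > 0).any():
                continue
            pop = artificial_population(a, b)
            assert pop.n_pairs + pop.n_excluded == a.size * b.size


class TestWeightedMeanRatio:
    def test_inverse_ratio_hand_example(self):
        est = weighted_mean_ratio([1.0, 2.0, 4.0], "inverse_ratio")
        assert est.estimate == pytest.approx(3 / (1 + 0.5 + 0.25))

    def test_inverse_ratio_equals_harmonic_mean(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ratios = rng.uniform(0.1, 10.0, size=rng.integers(2, 40))
            est = weighted_mean_ratio(ratios, "inverse_ratio")
            harmonic = len(ratios) / np.sum(1.0 / ratios)
            assert est.estimate == pytest.approx(harmonic, rel=1e-12)

    def test_unweighted_hand_example(self):
        est = weighted_mean_ratio([2.0, 1.0, 3.0, 1.5], "unweighted")
        assert est.estimate == pytest.approx(1.875)

    @pytest.mark.parametrize(
        "scheme", ["inverse_ratio", "inverse_abs_deviation", "unweighted"]
    )
    def test_constant_ratios_give_the_constant(self, scheme):
        est = weighted_mean_ratio([2.5] * 10, scheme)
        assert est.estimate == pytest.approx(2.5)

    def test_harmonic_never_exceeds_arithmetic(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            ratios = rng.lognormal(0.5, 0.8, size=25)
            h = weighted_mean_ratio(ratios, "inverse_ratio").estimate
            a = weighted_mean_ratio(ratios, "unweighted").estimate
            assert h < a  # strict: ratios differ almost surely

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(13)
        ratios = rng.uniform(0.5, 4.0, size=100)
        for scheme in ("inverse_ratio", "inverse_abs_deviation", "unweighted"):
            est = weighted_mean_ratio(ratios, scheme)
            assert ratios.min() <= est.estimate <= ratios.max()

    def test_empty_and_bad_scheme_errors(self):
        with pytest.raises(ValueError):
            weighted_mean_ratio([], "unweighted")
        with pytest.raises(ValueError, match="weighting"):
            weighted_mean_ratio([1.0], "geometric")


class TestSlideConsistency:
    def test_constant_counts_consistent(self):
        records = recs("S", "MLH1", [8] * 5) + recs("S", "MUS81", [4] * 5)
        share = marker_means(records, "S")
        pop = artificial_population([8] * 5, [4] * 5)
        est = weighted_mean_ratio(pop, sample_id="S")
        ok, report = slide_consistency_check(share, est)
        assert ok
        assert "inside" in report

    def test_adversarial_slide_ratio_flagged(self):
        # shares computed from very different cells than the population
        records = recs("S", "MLH1", [100] * 4) + recs("S", "MUS81", [1] * 4)
        share = marker_means(records, "S")
        pop = artificial_population([4, 5, 6], [4, 5, 6])
        est = weighted_mean_ratio(pop, sample_id="S")
        ok, report = slide_consistency_check(share, est)
        assert not ok
        assert "OUTSIDE" in report

    def test_label_swap_inverts_ratio_same_verdict(self):
        mlh1, mus81 = [9, 10, 11, 12], [3, 4, 5, 6]
        fwd_share = marker_means(
            recs("S", "MLH1", mlh1) + recs("S", "MUS81", mus81), "S"
        )
        fwd = slide_consistency_check(
            fwd_share,
            weighted_mean_ratio(artificial_population(mlh1, mus81), sample_id="S"),
        )
        swapped_share = marker_means(
            recs("S", "MLH1", mus81) + recs("S", "MUS81", mlh1), "S"
        )
        swapped = slide_consistency_check(
            swapped_share,
            weighted_mean_ratio(artificial_population(mus81, mlh1), sample_id="S"),
        )
        assert fwd[0] == swapped[0]


def rank_sum_oracle(a, b):
    """Full-enumeration two-sided rank-sum p (symmetric tie-free null)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n_a * (n_a + 1) / 2
    centre = n_a * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = sum(sorted(ranks[pooled[i]] for i in combo)) - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - centre) >= abs(u_obs - centre) - 1e-12:
            count += 1
    return count / total


class TestCompareCounts:
    def test_separated_groups_exact_p(self):
        res = compare_counts([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = compare_counts([1, 2, 3], [1, 2, 3])
        # pooled ties force the corrected normal approximation
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        # a maximally central tie-free arrangement on the exact path
        res = compare_counts([1, 4, 5], [2, 3, 6])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        done = 0
        while done < 25:
            n_a = int(rng.integers(2, 6))
            n_b = int(rng.integers(2, 11 - n_a))
            pooled = rng.choice(200, size=n_a + n_b, replace=False)
            a, b = list(pooled[:n_a]), list(pooled[n_a:])
            res = compare_counts(a, b)
            assert res.p_value == pytest.approx(rank_sum_oracle(a, b), rel=1e-9)
            done += 1

    def test_published_mean_difference(self):
        a = [409 // 37 + (1 if i < 409 % 37 else 0) for i in range(37)]
        b = [257 // 40 + (1 if i < 257 % 40 else 0) for i in range(40)]
        res = compare_counts(a, b)
        assert res.mean_difference == pytest.approx(409 / 37 - 257 / 40)
        assert res.mean_difference_display == 4.6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_counts([], [1, 2])


class TestFdrAdjust:
    def test_hand_computed_step_up(self):
        adjusted = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_equal_ps_unchanged(self):
        assert np.allclose(fdr_adjust([0.5] * 7), 0.5)

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=40)
        q = fdr_adjust(p)
        assert (q <= 1.0).all()
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.2, 1.3])
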