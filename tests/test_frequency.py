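"""Frequency arithmetic, group summaries and the exact Mann-Whitney test."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from rloopmut.frequency import (
    PlatingMeasurement,
    UndefinedFrequencyError,
    fold_change,
    frequency_report,
    group_median,
    mann_whitney_exact,
    mutation_frequency,
    rank_correlation,
    read_plating,
    write_plating,
)


def plating(n_sel, d_sel, n_non, d_non, cid="c1", group="g"):
    return PlatingMeasurement(cid, group, n_sel, d_sel, n_non, d_non)


class TestMutationFrequency:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((30, 1e2, 150, 1e5), 2e-4),
            ((0, 1e3, 100, 1e5), 0.0),
            ((10, 1, 10, 1), 1.0),
        ],
    )
    def test_examples(self, args, expected):
        assert mutation_frequency(plating(*args)) == pytest.approx(expected)

    def test_zero_nonselective_names_culture(self):
        with pytest.raises(UndefinedFrequencyError, match="c7"):
            mutation_frequency(plating(5, 10, 0, 10, cid="c7"))

    def test_scale_invariance_in_dilutions(self):
        base = mutation_frequency(plating(30, 100, 150, 1e5))
        for k in (2, 10, 1000):
            assert mutation_frequency(plating(30, 100 * k, 150, 1e5 * k)) == pytest.approx(base)

    def test_invalid_measurements_rejected(self):
        with pytest.raises(ValueError):
            plating(-1, 10, 5, 10)
        with pytest.raises(ValueError):
            plating(1, 0.5, 5, 10)


class TestGroupSummaries:
    def test_median_even_n_is_central_mean(self):
        ms = [plating(n, 1, 1, 1, cid=f"c{i}") for i, n in enumerate([1, 2, 3, 10])]
        res = group_median(ms)["g"]
        assert res.median == pytest.approx(2.5)
        assert min(res.frequencies) <= res.median <= max(res.frequencies)

    def test_fold_change_of_identical_groups_is_one(self):
        ms = [plating(5, 1, 10, 1, cid=f"c{i}") for i in range(4)]
        res = group_median(ms)["g"]
        assert fold_change(res, res) == 1.0

    def test_constructed_hundredfold(self):
        a = [plating(200, 100, 100, 1e6, cid=f"a{i}", group="a") for i in range(3)]
        b = [plating(2, 100, 100, 1e6, cid=f"b{i}", group="b") for i in range(3)]
        groups = group_median(a + b)
        assert fold_change(groups["a"], groups["b"]) == pytest.approx(100.0)

    def test_zero_reference_median_flagged_infinite(self):
        a = [plating(5, 1, 10, 1, cid="a1", group="a")]
        b = [plating(0, 1, 10, 1, cid="b1", group="b")]
        groups = group_median(a + b)
        assert fold_change(groups["a"], groups["b"]) == float("inf")


def _oracle_mwu(x, y, alternative="two-sided"):
    """Brute-force exact MWU p over all C(n+m, n) group labelings.

    U is computed by pair counting (wins + half-ties), independently of the
    rank-based implementation under test.
    """

    def u_of(xs, ys):
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    pooled = list(x) + list(y)
    n = len(x)
    u_obs = u_of(x, y)
    total = ge = le = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(xs, ys)
        total += 1
        ge += u >= u_obs - 1e-9
        le += u <= u_obs + 1e-9
    p_ge, p_le = Fraction(ge, total), Fraction(le, total)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1, 2 * min(p_ge, p_le)))


class TestMannWhitneyExact:
    def test_complete_separation_six_vs_six(self):
        res = mann_whitney_exact([7, 8, 9, 10, 11, 12], [1, 2, 3, 4, 5, 6])
        assert res.p == pytest.approx(2 / 924)
        assert round(res.p, 4) == 0.0022
        assert res.method == "exact_dp"

    def test_complete_separation_three_vs_three(self):
        res = mann_whitney_exact([4, 5, 6], [1, 2, 3])
        assert res.p == pytest.approx(2 / 20)

    def test_identical_constant_samples(self):
        res = mann_whitney_exact([5.0] * 4, [5.0] * 4)
        assert res.p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_two_sided_at_least_one_sided(self):
        x, y = [3, 9, 4, 8], [1, 2, 7, 5]
        two = mann_whitney_exact(x, y).p
        one = min(
            mann_whitney_exact(x, y, "greater").p, mann_whitney_exact(x, y, "less").p
        )
        assert 0 < one <= two <= 1

    def test_agrees_with_enumeration_all_small_sizes(self):
        """Oracle equivalence for every (n_x, n_y) with n_x + n_y <= 10."""
        rng = np.random.default_rng(7)
        for n in range(1, 10):
            for m in range(1, 11 - n):
                for tie_prone in (False, True):
                    if tie_prone:
                        x = list(rng.integers(0, 4, n).astype(float))
                        y = list(rng.integers(0, 4, m).astype(float))
                    else:
                        vals = rng.permutation(n + m).astype(float)
                        x, y = list(vals[:n]), list(vals[n:])
                    for alt in ("two-sided", "greater", "less"):
                        res = mann_whitney_exact(x, y, alt)
                        assert res.p == pytest.approx(
                            _oracle_mwu(x, y, alt), abs=1e-12
                        ), (x, y, alt)

    def test_agrees_with_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(11)
        for n, m in [(5, 5), (6, 6), (4, 8)]:
            vals = rng.permutation(n + m).astype(float)
            x, y = list(vals[:n]), list(vals[n:])
            ours = mann_whitney_exact(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.U == pytest.approx(float(ref.statistic))
            assert ours.p == pytest.approx(float(ref.pvalue))

    def test_large_tied_samples_fall_back_to_normal_approx(self):
        rng = np.random.default_rng(13)
        x = list(rng.integers(0, 3, 60).astype(float))
        y = list(rng.integers(0, 3, 60).astype(float))
        res = mann_whitney_exact(x, y)
        assert res.method == "normal_approx"
        assert 0 < res.p <= 1


class TestRankCorrelation:
    def test_monotone_pairs(self):
        assert rank_correlation([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert rank_correlation([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_random_permutation_near_zero(self):
        rng = np.random.default_rng(3)
        x = np.arange(500, dtype=float)
        y = rng.permutation(x)
        assert abs(rank_correlation(x, y)) < 0.1  # ~ 2 sd for n = 500

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 1, 1], [1, 2, 3])


class TestReport:
    def test_round_trip_and_report(self, tmp_path):
        a = [plating(200 + i, 100, 100, 1e6, cid=f"a{i}", group="treated") for i in range(6)]
        b = [plating(2 + i, 100, 100, 1e6, cid=f"b{i}", group="control") for i in range(6)]
        path = tmp_path / "plating.tsv"
        write_plating(a + b, path)
        report = frequency_report(read_plating(path), reference_group="control")
        assert report["groups"]["treated"]["fold_vs_reference"] == pytest.approx(45.0, rel=0.02)
        (pair,) = report["pairwise"]
        assert pair["p"] == 0.0022 and pair["method"] == "exact_dp"

    def test_tie_heavy_input_records_method(self):
        a = [plating(1, 1, 10, 1, cid=f"a{i}", group="a") for i in range(4)]
        b = [plating(1, 1, 10, 1, cid=f"b{i}", group="b") for i in range(4)]
        report = frequency_report(a + b)
        (pair,) = report["pairwise"]
        assert pair["method"] in ("exact_permutation", "normal_approx")
        assert pair["p"] == 1.0

    def test_single_group_no_tests(self):
        a = [plating(5, 1, 10, 1, cid="a1", group="a")]
        report = frequency_report(a)
        assert report["pairwise"] == []
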