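"""The distancing test itself: subsets, permutation p-values, aggregation."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdt import (
    PDTConfig,
    build_subsets,
    classify_effect_size,
    effect_size,
    fit_p_curve,
    pdt_k_row,
    run_pdt,
    select_favored_k,
    subset_permutation_p,
    subset_statistic,
)
from pdt.distancing import PDTKRow, auto_k_max
from pdt.dependence import LjungBoxSummary

from conftest import make_series


def brute_force_p(values, n_a, sided="two"):
    """Exhaustive two-group permutation p by direct enumeration."""
    values = np.asarray(values, float)
    idx = range(len(values))
    obs = values[:n_a].mean() - values[n_a:].mean()
    count = total = 0
    for c in combinations(idx, n_a):
        mask = np.zeros(len(values), bool)
        mask[list(c)] = True
        s = values[mask].mean() - values[~mask].mean()
        total += 1
        if sided == "two":
            count += abs(s) >= abs(obs) - 1e-12
        elif sided == "greater":
            count += s >= obs - 1e-12
        else:
            count += s <= obs + 1e-12
    return count / total


class TestBuildSubsets:
    def test_worked_example_k3_first_offset(self, fitnet):
        subs = build_subsets(fitnet, 3)
        finite = subs[0].values[np.isfinite(subs[0].values)]
        assert list(finite[:4]) == [48, 43, 44, 47]

    def test_k3_offsets_are_global_not_per_phase(self, fitnet):
        subs = build_subsets(fitnet, 3)
        assert list(subs[1].values[:3]) == [43, 42, 46]
        assert list(subs[2].values[:3]) == [35, 47, 47]

    def test_k1_is_original_series(self, fitnet):
        (sub,) = build_subsets(fitnet, 1)
        assert np.array_equal(sub.values, fitnet.y, equal_nan=True)

    @given(k=st.integers(1, 8))
    @settings(max_examples=20, deadline=None)
    def test_subsets_partition_series(self, fitnet, k):
        subs = build_subsets(fitnet, k)
        pooled = np.concatenate([s.positions for s in subs])
        assert sorted(pooled) == list(range(1, len(fitnet) + 1))
        values = np.concatenate([s.values for s in subs])
        assert sorted(values[np.isfinite(values)]) == sorted(
            fitnet.y[np.isfinite(fitnet.y)]
        )

    def test_spacing_within_subset(self, fitnet):
        for sub in build_subsets(fitnet, 4):
            assert set(np.diff(sub.positions)) == {4}


class TestSubsetStatistic:
    def test_worked_example_mean_difference(self, fitnet):
        (sub,) = build_subsets(fitnet, 1)
        assert subset_statistic(sub, "mean") == pytest.approx(9.727, abs=5e-4)

    def test_identical_phases_give_zero(self):
        s = make_series([2, 2], [2, 2])
        assert subset_statistic(build_subsets(s, 1)[0]) == 0

    def test_small_arithmetic_case(self):
        s = make_series([1, 3], [2])
        assert subset_statistic(build_subsets(s, 1)[0]) == pytest.approx(0.0)


class TestPermutationP:
    def test_exhaustive_two_sided_separated_groups(self):
        s = make_series([1, 2, 3], [4, 5, 6])
        (sub,) = build_subsets(s, 1)
        p = subset_permutation_p(sub, "mean", n_permutations=10_000, sided="two")
        assert p == pytest.approx(2 / 20)

    def test_symmetric_data_give_p_one(self):
        s = make_series([1, 3], [3, 1])
        (sub,) = build_subsets(s, 1)
        assert subset_permutation_p(sub, "mean", 1000, "two") == 1.0

    def test_degenerate_constant_data_give_p_one(self):
        s = make_series([5, 5, 5], [5, 5, 5])
        (sub,) = build_subsets(s, 1)
        assert subset_permutation_p(sub) == 1.0

    @pytest.mark.parametrize("sided", ["two", "greater", "less"])
    def test_exhaustive_matches_brute_force(self, sided):
        rng = np.random.default_rng(4)
        for _ in range(5):
            y = rng.normal(size=9).round(2)
            s = make_series(y[:4], y[4:])
            (sub,) = build_subsets(s, 1)
            p = subset_permutation_p(sub, "mean", 10_000, sided)
            assert p == pytest.approx(brute_force_p(y, 4, sided))

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=10).round(2)
        s = make_series(y[:5], y[5:])
        (sub,) = build_subsets(s, 1)
        exact = brute_force_p(y, 5)
        # force Monte Carlo by capping permutations below C(10,5)=252
        p_mc = subset_permutation_p(sub, "mean", 250, "two", np.random.default_rng(1))
        # 99% binomial bound on 250 draws
        bound = 2.576 * math.sqrt(exact * (1 - exact) / 250)
        assert abs(p_mc - exact) <= bound + 1e-9

    def test_median_statistic_supported(self):
        s = make_series([1, 2, 9], [4, 5, 6])
        (sub,) = build_subsets(s, 1)
        p = subset_permutation_p(sub, "median", 10_000, "two")
        assert 0 <= p <= 1


class TestEffectSize:
    def test_worked_example_uses_averaged_sd_denominator(self):
        assert effect_size(44.727, 35.0, 4.052, 7.228) == pytest.approx(1.725, abs=5e-4)

    def test_zero_difference(self):
        assert effect_size(3, 3, 1, 2) == 0

    def test_scale_and_shift_invariance(self):
        d0 = effect_size(10, 4, 2, 4)
        assert effect_size(10 * 3, 4 * 3, 2 * 3, 4 * 3) == pytest.approx(d0)
        assert effect_size(10 + 7, 4 + 7, 2, 4) == pytest.approx(d0)

    def test_zero_variability_rejected(self):
        with pytest.raises(ValueError, match="zero variability"):
            effect_size(1, 2, 0, 0)

    @pytest.mark.parametrize(
        "d,label",
        [(0.0, "small"), (0.99, "small"), (1.0, "medium"), (1.691, "medium"),
         (2.49, "medium"), (2.50, "large"), (5.0, "large")],
    )
    def test_classification_boundaries(self, d, label):
        assert classify_effect_size(d) == label

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            classify_effect_size(-0.1)


def row(k, lb_p, raw_p=0.5, es=1.0):
    return PDTKRow(
        k=k,
        dependence=LjungBoxSummary(k=k, mean_r1=0.1, mean_Q=1.0, combined_p=lb_p),
        raw_p=raw_p,
        effect_size=es,
        n_subsets_used=k,
    )


class TestFitPCurve:
    def test_three_or_fewer_rows_interpolate_exactly(self):
        rows = [row(1, 0.5, 0.0), row(2, 0.5, 0.006), row(3, 0.5, 0.026)]
        fitted = fit_p_curve(rows)
        assert [r.fitted_p for r in fitted] == [r.raw_p for r in rows]
        (single,) = fit_p_curve([row(1, 0.5, 0.123)])
        assert single.fitted_p == 0.123

    def test_least_squares_prediction_clamped(self):
        raws = [0.0, 0.0, 0.0, 0.5, 0.0]
        rows = [row(k, 0.5, p) for k, p in enumerate(raws, 1)]
        fitted = fit_p_curve(rows)
        ks = np.arange(1, 6)
        expected = np.clip(np.polyval(np.polyfit(ks, raws, 2), ks), 0, 1)
        assert [r.fitted_p for r in fitted] == pytest.approx(list(expected))
        assert all(r.fitted_p >= 0 for r in fitted)


class TestFavoredK:
    def test_worked_example_gate(self):
        rows = [row(1, 0.000), row(2, 0.007), row(3, 0.074)]
        assert select_favored_k(rows, 0.05) == (3, False)

    def test_first_k_clears_gate(self):
        assert select_favored_k([row(1, 0.30), row(2, 0.50)], 0.05) == (1, False)

    def test_fallback_to_k_max_with_warning(self):
        rows = [row(1, 0.001), row(2, 0.002), row(3, 0.003)]
        assert select_favored_k(rows, 0.05) == (3, True)


class TestRunPDT:
    def test_worked_example_end_to_end(self, fitnet):
        res = run_pdt(fitnet, PDTConfig(sided="greater", seed=7))
        assert res.observed_statistic == pytest.approx(9.727, abs=5e-4)
        assert res.favored_k == 3
        assert not res.favored_k_warning
        assert res.favored_row.effect_size == pytest.approx(1.691, abs=5e-3)
        assert res.effect_size_label == "medium"

    def test_auto_k_max_keeps_two_observations_per_phase(self, fitnet):
        # baseline has 11 observations, so distances beyond 5 would leave a
        # subset with a single phase-A value
        assert auto_k_max(fitnet) == 5

    def test_observed_statistic_independent_of_k_rows(self, fitnet):
        res3 = run_pdt(fitnet, PDTConfig(k_max=3, n_permutations=200, seed=0))
        res5 = run_pdt(fitnet, PDTConfig(k_max=5, n_permutations=200, seed=0))
        assert res3.observed_statistic == res5.observed_statistic

    def test_seed_gives_bitwise_identical_results(self, fitnet):
        cfg = PDTConfig(n_permutations=2000, seed=123, sided="greater")
        a = run_pdt(fitnet, cfg)
        b = run_pdt(fitnet, cfg)
        assert a == b

    def test_phase_swap_negates_statistic_same_two_sided_p(self, fitnet):
        swapped = make_series(
            fitnet.y[fitnet.phase == "A"], fitnet.y[fitnet.phase == "B"]
        )
        mirrored = make_series(
            fitnet.y[fitnet.phase == "B"][::-1], fitnet.y[fitnet.phase == "A"][::-1]
        )
        cfg = PDTConfig(n_permutations=4000, sided="two", seed=5, k_max=1)
        res_a = run_pdt(swapped, cfg)
        res_b = run_pdt(mirrored, cfg)
        assert res_b.observed_statistic == pytest.approx(-res_a.observed_statistic)
        assert res_b.favored_row.raw_p == pytest.approx(res_a.favored_row.raw_p, abs=0.02)

    def test_k1_raw_p_is_single_subset_p(self, fitnet):
        res = run_pdt(fitnet, PDTConfig(n_permutations=3000, seed=11, k_max=1))
        (sub,) = build_subsets(fitnet, 1)
        p = subset_permutation_p(sub, "mean", 3000, "two", np.random.default_rng(11))
        assert res.rows[0].raw_p == pytest.approx(p, abs=0.02)

    def test_pooled_variant_runs(self, fitnet):
        cfg = PDTConfig(n_permutations=300, pooling="pooled", seed=2, k_max=2)
        res = run_pdt(fitnet, cfg)
        assert 0 <= res.rows[1].raw_p <= 1

    def test_empty_phase_subsets_are_dropped_with_warning(self):
        # phase A has two observations; at k=3 one subset has no A values
        s = make_series([1.0, 2.0], [5.0, 6.0, 7.0, 4.0, 5.0, 6.0, 7.0])
        with pytest.warns(UserWarning, match="empty phase"):
            r = pdt_k_row(s, 3, PDTConfig(n_permutations=200), np.random.default_rng(0))
        assert r.n_subsets_used == 2
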