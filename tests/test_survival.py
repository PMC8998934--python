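"""Kaplan-Meier, log-rank, Mann-Whitney and percent-enhancement checks.

lifelines and scipy serve as independent oracles for the authored
implementations; small cases are verified against hand tabulation and full
enumeration.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from t2flux import (
    km_curve,
    logrank,
    mann_whitney,
    percent_enhancement,
    simulate_survival_cohort,
)


class TestKmCurve:
    def test_hand_product_limit(self):
        s = km_curve([10.0, 20.0, 30.0], [True, True, True])
        assert np.allclose(s.survival, [2 / 3, 1 / 3, 0.0])
        assert s.median_days == 20.0  # first time S <= 0.5

    def test_all_censored_median_undefined(self):
        s = km_curve([5.0, 9.0], [False, False])
        assert s.survival.size == 0
        assert not s.median_defined
        assert math.isnan(s.median_days)

    def test_single_event_median_at_that_time(self):
        s = km_curve([42.0], [True])
        assert s.median_days == 42.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(17)
        times = rng.exponential(50.0, size=200)
        s = km_curve(times, np.ones(200, dtype=bool))
        for t in rng.uniform(0, 150.0, size=20):
            empirical = float(np.mean(times > t))
            assert s.survival_at(t) == pytest.approx(empirical, abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(23)
        times = rng.exponential(60.0, size=80)
        events = rng.uniform(size=80) < 0.7
        s = km_curve(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t in s.times:
            assert s.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_median_invariant_under_administrative_censoring_after_median(self):
        """Cutting follow-up at any time past the median leaves the median fixed."""
        times = np.array([10.0, 20.0, 30.0, 40.0, 55.0, 70.0])
        events = np.ones(6, dtype=bool)
        base = km_curve(times, events)
        cutoff = 35.0  # strictly after the median (20 or 30)
        assert cutoff > base.median_days
        trunc_times = np.minimum(times, cutoff)
        trunc_events = events & (times <= cutoff)
        truncated = km_curve(trunc_times, trunc_events)
        assert truncated.median_days == base.median_days


def brute_force_logrank(times_a, times_b):
    """Exhaustive risk-set tabulation for all-event two-group data."""
    all_times = sorted(set(times_a) | set(times_b))
    obs = exp = var = 0.0
    for t in all_times:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        n = na + nb
        d = sum(1 for x in times_a if x == t) + sum(1 for x in times_b if x == t)
        da = sum(1 for x in times_a if x == t)
        obs += da
        exp += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (obs - exp) ** 2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


class TestLogrank:
    def test_identical_groups_null(self):
        times = [5.0, 10.0, 15.0]
        events = [True] * 3
        r = logrank(times, events, times, events)
        assert r.defined
        assert r.chi_square == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_separated_groups_match_brute_force_tabulation(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 20.0, 30.0]
        r = logrank(a, [True] * 3, b, [True] * 3)
        chi2_ref, p_ref = brute_force_logrank(a, b)
        assert r.chi_square == pytest.approx(chi2_ref, rel=1e-12)
        assert r.p == pytest.approx(p_ref, rel=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(31)
        a = rng.exponential(40.0, size=12)
        b = rng.exponential(70.0, size=15)
        r1 = logrank(a, [True] * 12, b, [True] * 15)
        r2 = logrank(b, [True] * 15, a, [True] * 12)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-12)

    def test_matches_lifelines_with_censoring(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(37)
        ta, tb = rng.exponential(40.0, 30), rng.exponential(55.0, 30)
        ea, eb = rng.uniform(size=30) < 0.8, rng.uniform(size=30) < 0.8
        r = logrank(ta, ea, tb, eb)
        ref = lifelines_stats.logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert r.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert r.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_zero_event_group_flagged(self):
        r = logrank([5.0, 6.0], [False, False], [1.0, 2.0], [True, True])
        assert not r.defined
        assert "zero events" in r.message


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        r = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert r.u == 0.0
        assert r.p == pytest.approx(2.0 / 6.0, rel=1e-12)
        assert r.method == "exact"

    def test_identical_multisets_p_one(self):
        r = mann_whitney([3.0, 7.0, 9.0], [3.0, 7.0, 9.0])
        assert r.p == pytest.approx(1.0)

    def test_extreme_ordering_gives_smallest_attainable_p(self):
        # all of A below all of B: p = 2 / C(na+nb, na)
        r = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert r.p == pytest.approx(2.0 / math.comb(6, 3), rel=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_scipy_enumeration(self, seed):
        """For tie-free samples with n <= 8, exact p equals scipy's exact test."""
        rng = np.random.default_rng(seed)
        na = int(rng.integers(2, 5))
        nb = int(rng.integers(2, 5))
        pooled = rng.permutation(np.arange(1.0, na + nb + 1.0))
        a, b = pooled[:na], pooled[na:]
        r = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_exact_p_equals_full_enumeration_with_ties(self):
        """The exact p is the enumeration probability even under ties."""
        a, b = [1.0, 2.0, 2.0], [2.0, 5.0]
        r = mann_whitney(a, b)
        pooled = a + b
        na = len(a)
        center = na * len(b) / 2.0

        def u_of(subset):
            aa = [pooled[i] for i in subset]
            bb = [pooled[i] for i in range(len(pooled)) if i not in subset]
            return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

        dev = abs(r.u - center)
        hits = total = 0
        for subset in combinations(range(len(pooled)), na):
            total += 1
            if abs(u_of(subset) - center) >= dev - 1e-12:
                hits += 1
        assert r.p == pytest.approx(hits / total, rel=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, size=30)
        b = rng.normal(0.8, 1.0, size=30)
        r = mann_whitney(a, b)
        assert r.method == "asymptotic"
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestPercentEnhancement:
    @pytest.mark.parametrize(
        "treated,control,expected",
        [(66, 44, 50), (73, 59, 24), (66, 50, 32), (73, 63, 16), (50, 44, 14), (63, 59, 7), (44, 44, 0)],
    )
    def test_reported_median_pairs(self, treated, control, expected):
        assert percent_enhancement(treated, control) == expected

    def test_antisymmetry_of_sign(self):
        for a, b in [(66.0, 44.0), (59.0, 73.0), (50.0, 63.0)]:
            if a != b:
                assert (percent_enhancement(a, b) > 0) == (percent_enhancement(b, a) < 0)

    def test_undefined_median_propagates(self):
        assert math.isnan(percent_enhancement(math.nan, 44.0))

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            percent_enhancement(-1.0, 44.0)


class TestCohortRecovery:
    def test_km_median_enhancement_on_large_cohort(self):
        """Simulated groups with medians 44 and 66 recover ~50% enhancement."""
        cohort = simulate_survival_cohort(
            {"control": 44.0, "treated": 66.0}, n_per_group=10_000, censor_day=1e9, seed=90
        )
        medians = {}
        for group, df in cohort.groupby("group"):
            s = km_curve(df["day"], df["event"], group=group)
            assert s.median_defined
            medians[group] = s.median_days
        assert medians["control"] == pytest.approx(44.0, rel=0.02)
        assert medians["treated"] == pytest.approx(66.0, rel=0.02)
        pct = percent_enhancement(medians["treated"], medians["control"])
        assert 48 <= pct <= 52
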