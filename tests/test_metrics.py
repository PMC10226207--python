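"""Gini, concentration curve, concentration index, and its standard error."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ineqdecomp as iq
from ineqdecomp.survey import DataError


class TestGini:
    def test_constant_is_zero(self):
        assert iq.gini_index([3.0] * 7) == pytest.approx(0.0, abs=1e-14)

    def test_two_point_example(self):
        # ranks (0.25, 0.75): 2*cov/mean = 2*0.125/0.5
        assert iq.gini_index([0.0, 1.0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_single_holder_closed_form(self, n):
        y = np.zeros(n)
        y[-1] = 11.0
        assert iq.gini_index(y) == pytest.approx((n - 1) / n)

    def test_all_zero_raises(self):
        with pytest.raises(DataError):
            iq.gini_index([0.0, 0.0])

    def test_matches_one_minus_twice_lorenz_area(self, rng):
        y = rng.gamma(2.0, 1.0, size=500)
        curve = iq.concentration_curve(y, y)  # Lorenz: ranked by itself
        assert iq.gini_index(y) == pytest.approx(1 - 2 * curve.area(), abs=1e-9)

    def test_equals_ci_ranked_by_itself(self, rng):
        y = rng.gamma(2.0, 1.0, size=300)
        w = rng.uniform(0.5, 2.0, size=300)
        ci = iq.concentration_index(y, y, w)
        assert iq.gini_index(y, w) == pytest.approx(ci.value, abs=1e-12)


class TestConcentrationCurve:
    def test_constant_outcome_is_diagonal(self, rng):
        score = rng.normal(size=100)
        curve = iq.concentration_curve(score, np.ones(100))
        np.testing.assert_allclose(curve.outcome_share, curve.population_share,
                                   atol=1e-12)

    def test_endpoints(self, rng):
        score = rng.normal(size=50)
        outcome = rng.integers(0, 2, size=50).astype(float)
        outcome[0] = 1  # ensure positive total
        curve = iq.concentration_curve(score, outcome)
        assert curve.population_share[0] == 0 and curve.outcome_share[0] == 0
        assert curve.population_share[-1] == 1 and curve.outcome_share[-1] == 1
        assert np.all(np.diff(curve.outcome_share) >= 0)

    def test_outcome_confined_to_poorest_fifth(self):
        score = np.arange(100, dtype=float)
        outcome = (score < 20).astype(float)
        curve = iq.concentration_curve(score, outcome)
        idx = np.searchsorted(curve.population_share, 0.2)
        assert curve.outcome_share[idx] == pytest.approx(1.0)
        assert np.all(curve.outcome_share[idx:] == 1.0)

    def test_pro_poor_outcome_lies_above_diagonal(self):
        # interior vertices away from the extremes: the empirical step
        # curve of a binary outcome can graze the diagonal in the first
        # few units when the poorest draws happen to be zeros
        ds = iq.generate_wave(iq.default_baseline_spec(n=5000, seed=5))
        curve = iq.concentration_curve(ds.rank_score, ds.outcome, ds.weight)
        interior = (curve.population_share > 0.02) \
            & (curve.population_share < 0.98)
        assert np.all(curve.outcome_share[interior]
                      > curve.population_share[interior])


class TestConcentrationIndex:
    def test_constant_outcome_zero_with_bounds(self):
        ci = iq.concentration_index(np.ones(6), np.arange(6))
        assert ci.value == pytest.approx(0.0, abs=1e-14)
        assert ci.bounds[0] == pytest.approx(0.0, abs=1e-12)
        assert ci.bounds[1] == pytest.approx(0.0, abs=1e-12)

    def test_poorest_holds_all(self):
        # H=(1,0,0,0) with ranks (0.125,...): C = 2*0.125/0.25 - 1
        ci = iq.concentration_index([1, 0, 0, 0], [1, 2, 3, 4])
        assert ci.value == pytest.approx(-0.75)
        assert ci.bounds == (-0.75, 0.75)

    def test_covariance_equals_rank_sum_form(self, rng):
        h = rng.integers(0, 2, size=400).astype(float)
        h[0] = 1
        score = rng.normal(size=400)
        ranks = iq.fractional_rank(score)
        ci = iq.concentration_index(h, score)
        rank_sum = 2.0 / (400 * h.mean()) * float(h @ ranks) - 1.0
        assert ci.value == pytest.approx(rank_sum, abs=1e-12)

    def test_invariances(self, rng):
        h = rng.integers(0, 2, size=300).astype(float)
        h[0] = 1
        score = rng.normal(size=300)
        w = rng.uniform(0.5, 3.0, size=300)
        base = iq.concentration_index(h, score, w).value
        scaled = iq.concentration_index(h, score, 7.3 * w).value
        monotone = iq.concentration_index(h, np.exp(score), w).value
        assert scaled == pytest.approx(base, abs=1e-12)
        assert monotone == pytest.approx(base, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_binary_bounds_hold(self, seed):
        r = np.random.default_rng(seed)
        n = 150
        h = r.integers(0, 2, size=n).astype(float)
        if h.sum() == 0:
            h[0] = 1
        score = r.normal(size=n)
        w = r.uniform(0.1, 5.0, size=n)
        ci = iq.concentration_index(h, score, w)
        lo, hi = ci.bounds
        assert lo - 1e-12 <= ci.value <= hi + 1e-12
        assert abs(ci.value) <= 1

    def test_weighted_false_ignores_weights(self, rng):
        h = rng.integers(0, 2, size=200).astype(float)
        h[0] = 1
        score = rng.normal(size=200)
        w = rng.uniform(0.1, 5.0, size=200)
        unweighted = iq.concentration_index(h, score, w, weighted=False)
        plain = iq.concentration_index(h, score)
        assert unweighted.value == pytest.approx(plain.value, abs=1e-14)

    def test_normalizations(self):
        h = np.array([1, 1, 0, 0, 0, 0], dtype=float)
        score = np.arange(6, dtype=float)
        plain = iq.concentration_index(h, score).value
        wag = iq.concentration_index(h, score, normalize="wagstaff").value
        err = iq.concentration_index(h, score, normalize="erreygers").value
        mean = h.mean()
        assert wag == pytest.approx(plain / (1 - mean))
        assert err == pytest.approx(4 * mean * plain)


class TestStandardError:
    def test_constant_outcome_gives_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            se = iq.ci_standard_error(np.ones(10), np.arange(10))
        assert se == 0.0

    def test_weight_scale_invariance(self, rng):
        h = rng.integers(0, 2, size=500).astype(float)
        h[0] = 1
        score = rng.normal(size=500)
        w = rng.uniform(0.5, 2.0, size=500)
        se1 = iq.ci_standard_error(h, score, w)
        se2 = iq.ci_standard_error(h, score, 2 * w)
        assert se1 == pytest.approx(se2, rel=1e-10)

    def test_against_monte_carlo_oracle(self):
        """SE from the convenient regression should land within a factor of
        two of the Monte-Carlo sampling SD of C over repeated draws."""
        n = 4000
        master = np.random.default_rng(777)
        score = master.normal(size=n)
        ranks = iq.fractional_rank(score)
        p = 1 / (1 + np.exp(1.2 * (ranks - 0.3) * 4))  # pro-poor gradient
        values = []
        for _ in range(300):
            h = (master.random(n) < p).astype(float)
            values.append(iq.concentration_index(h, ranks=ranks).value)
        mc_sd = float(np.std(values))
        h = (master.random(n) < p).astype(float)
        se = iq.ci_standard_error(h, ranks=ranks)
        assert 0.5 * mc_sd < se < 2.0 * mc_sd

    def test_cluster_fallback_warns_with_one_cluster(self, rng):
        h = rng.integers(0, 2, size=100).astype(float)
        h[0] = 1
        score = rng.normal(size=100)
        with pytest.warns(UserWarning, match="clusters"):
            se = iq.ci_standard_error(h, score, cluster_id=np.zeros(100))
        assert se > 0
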