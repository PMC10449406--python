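import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samplingcost import (
    PriorDistribution,
    enumerate_wor_pmf,
    geometric_runtime_moments,
    kl_surprisal_identity_check,
    make_weightset,
    oracle_moments,
    precedence_probability,
    wor_expected_runtime,
    wor_runtime_variance,
)
from tests.conftest import random_weightsets


class TestGeometricMoments:
    @pytest.mark.parametrize("p, mean, var", [(1.0, 1.0, 0.0), (0.5, 2.0, 2.0)])
    def test_closed_form(self, p, mean, var):
        s = geometric_runtime_moments(p)
        assert s.mean_draws == pytest.approx(mean)
        assert s.var_draws == pytest.approx(var)
        assert s.target_surprisal == pytest.approx(-math.log(p))

    def test_variance_mean_relation(self):
        # var = mean^2 - mean holds exactly for the geometric draw count
        for p in (0.9, 0.3, 0.05):
            s = geometric_runtime_moments(p)
            assert s.var_draws == pytest.approx(s.mean_draws**2 - s.mean_draws, rel=1e-12)

    def test_monte_carlo_agreement(self, rng):
        draws = rng.geometric(0.1, size=10**6)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(geometric_runtime_moments(0.1).mean_draws - draws.mean()) < 3 * se

    def test_monotone_in_surprisal(self):
        ps = np.linspace(0.01, 1.0, 50)
        means = [geometric_runtime_moments(p).mean_draws for p in ps]
        vars_ = [geometric_runtime_moments(p).var_draws for p in ps]
        assert np.all(np.diff(means) < 0)  # decreasing in p == increasing in surprisal
        assert np.all(np.diff(vars_) < 0)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_probability(self, p):
        with pytest.raises(ValueError):
            geometric_runtime_moments(p)


class TestPrecedence:
    def test_symmetry_and_formula(self):
        assert precedence_probability(1.0, 1.0) == pytest.approx(0.5)
        assert precedence_probability(2.0, 1.0) == pytest.approx(2 / 3)

    def test_both_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            precedence_probability(0.0, 0.0)


class TestWithoutReplacementMoments:
    def test_single_item(self):
        ws = make_weightset([1.0])
        assert wor_expected_runtime(ws).mean_draws == 1.0
        assert wor_runtime_variance(ws).var_draws == 0.0

    def test_two_equal_items(self):
        ws = make_weightset([1.0, 1.0])
        assert wor_expected_runtime(ws).mean_draws == pytest.approx(1.5)
        assert wor_runtime_variance(ws).var_draws == pytest.approx(0.25)

    def test_documented_example(self, small_weightset):
        assert wor_expected_runtime(small_weightset).mean_draws == pytest.approx(
            1.96190, abs=1e-5
        )

    def test_moments_match_oracle(self):
        """Closed-form mean/variance equal enumeration on random instances."""
        for ws in random_weightsets(50, range(1, 7), seed=2024):
            analytic = wor_runtime_variance(ws)
            exact = oracle_moments(enumerate_wor_pmf(ws))
            assert analytic.mean_draws == pytest.approx(exact.mean_draws, abs=1e-10)
            assert analytic.var_draws == pytest.approx(exact.var_draws, abs=1e-10)

    def test_mean_bounds(self):
        for ws in random_weightsets(20, range(1, 7), seed=5):
            m = wor_expected_runtime(ws).mean_draws
            assert 1.0 <= m <= ws.K + 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        u0s=st.tuples(st.floats(0.1, 5.0), st.floats(0.1, 5.0)),
        rest=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
    )
    def test_mean_decreases_in_target_weight(self, u0s, rest):
        """Raising the target weight strictly lowers expected runtime."""
        lo, hi = sorted(u0s)
        if hi - lo < 1e-9:
            return
        m_lo = wor_expected_runtime(make_weightset([lo] + rest)).mean_draws
        m_hi = wor_expected_runtime(make_weightset([hi] + rest)).mean_draws
        assert m_hi < m_lo

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(rest=st.lists(st.floats(0.01, 10.0), min_size=0, max_size=8))
    def test_wor_mean_never_exceeds_wr_mean(self, rest):
        """Removing rejected hypotheses can only speed the guesser up."""
        ws = make_weightset([1.0] + rest)
        wor = wor_expected_runtime(ws).mean_draws
        wr = geometric_runtime_moments(ws.target_probability).mean_draws
        assert wor <= wr + 1e-12

    def test_size_cap_and_override(self):
        big = make_weightset(np.ones(6001))
        with pytest.raises(ValueError, match="allow_large"):
            wor_runtime_variance(big)
        res = wor_runtime_variance(make_weightset(np.ones(101)), allow_large=True)
        assert res.var_draws > 0


class TestKLIdentity:
    def test_indicator_on_uniform(self):
        prior = PriorDistribution(np.full(8, 0.125))
        lik = np.zeros(8)
        lik[3] = 1.0
        surprisal, kl, gap = kl_surprisal_identity_check(prior, lik)
        assert surprisal == pytest.approx(math.log(8), abs=1e-12)
        assert kl == pytest.approx(math.log(8), abs=1e-12)
        assert gap < 1e-12

    def test_uninformative_likelihood(self):
        prior = PriorDistribution(np.array([0.6, 0.4]))
        surprisal, kl, gap = kl_surprisal_identity_check(prior, [1.0, 1.0])
        assert surprisal == pytest.approx(0.0, abs=1e-12)
        assert kl == pytest.approx(0.0, abs=1e-12)

    def test_graded_likelihood_breaks_identity(self):
        prior = PriorDistribution(np.full(3, 1 / 3))
        lik = np.array([0.5, 0.5, 1.0])
        surprisal, kl, gap = kl_surprisal_identity_check(prior, lik)
        # direct summation oracle
        marginal = float(lik @ prior.probabilities)
        post = lik * prior.probabilities / marginal
        kl_direct = float(np.sum(post * np.log(post / prior.probabilities)))
        assert surprisal == pytest.approx(-math.log(marginal), abs=1e-12)
        assert kl == pytest.approx(kl_direct, abs=1e-12)
        assert gap > 1e-6

    def test_identity_holds_for_all_binary_likelihoods(self, rng):
        """Surprisal equals KL(posterior||prior) iff structures determine the word."""
        for _ in range(100):
            n = int(rng.integers(2, 10))
            p = rng.dirichlet(np.ones(n))
            lik = rng.integers(0, 2, size=n).astype(float)
            if lik.sum() == 0:
                lik[int(rng.integers(n))] = 1.0
            prior = PriorDistribution(p)
            _, _, gap = kl_surprisal_identity_check(prior, lik)
            assert gap < 1e-12
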