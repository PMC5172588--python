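"""Generative models: Li words, Bernoulli populations, the ring counterexample."""

import collections
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from zipflatent.models import (
    BernoulliPopulationModel,
    EnumerableJointModel,
    LiWordModel,
    PlaceFieldRingModel,
    _all_patterns,
    bernoulli_entropy_scalar,
    chain_rule_entropies,
    entropy_variance_scaling,
)


class TestLiWordModel:
    def test_length_pmf_hand_values(self):
        assert LiWordModel(M=4).length_pmf(1) == pytest.approx(0.2, rel=1e-15)
        assert LiWordModel(M=1).length_pmf(3) == pytest.approx(0.5**3, rel=1e-15)

    def test_length_pmf_normalizes(self):
        for M in (1, 2, 4, 26):
            z = np.arange(1, 3000)
            assert LiWordModel(M=M).length_pmf(z).sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_rejects_invalid_length(self):
        with pytest.raises(ValueError):
            LiWordModel(M=4).length_pmf(0)

    def test_pattern_energy_hand_value(self):
        # z=1, M=4: any single letter has probability (1/4)(1/5) = 1/20
        assert LiWordModel(M=4).pattern_energy(1) == pytest.approx(
            math.log(20), rel=1e-14
        )

    def test_pattern_energy_pure_length_term_when_M1(self):
        m = LiWordModel(M=1)
        z = np.arange(1, 20)
        assert np.allclose(m.pattern_energy(z), -np.log(m.length_pmf(z)))

    @pytest.mark.parametrize("M", [2, 4, 26])
    def test_pattern_energy_matches_direct_formula(self, M):
        m = LiWordModel(M=M)
        z = np.arange(1, 51)
        direct = -np.log(M ** (-z.astype(float)) * m.length_pmf(z))
        assert np.allclose(m.pattern_energy(z), direct, rtol=1e-12)

    @pytest.mark.parametrize("M", [1, 2, 4, 10, 26])
    def test_logpz_variance_closed_form_vs_bruteforce(self, M):
        m = LiWordModel(M=M)
        assert m.logpz_variance() == pytest.approx(
            m.logpz_variance_bruteforce(z_cap=3000), abs=1e-10
        )

    def test_logpz_variance_m4_value(self):
        assert LiWordModel(M=4).logpz_variance() == pytest.approx(0.99587, abs=1e-5)

    def test_logpz_variance_bounded(self):
        for M in range(1, 101):
            m = LiWordModel(M=M)
            assert m.logpz_variance() <= (M + 1) / M

    def test_logpz_variance_limit_one(self):
        assert LiWordModel(M=10**6).logpz_variance() == pytest.approx(1.0, abs=1e-5)

    def test_sample_reproducible_and_m1_structure(self):
        m = LiWordModel(M=1)
        w1 = m.sample(100, seed=3)
        w2 = m.sample(100, seed=3)
        assert w1 == w2
        assert all(set(w) == {"a"} for w in w1)

    def test_sampled_length_distribution(self):
        m = LiWordModel(M=4)
        words = m.sample(100_000, seed=11)
        lens = collections.Counter(len(w) for w in words)
        zmax = 12
        observed = np.array([lens.get(z, 0) for z in range(1, zmax)])
        observed = np.append(observed, len(words) - observed.sum())
        pz = np.array([m.length_pmf(z) for z in range(1, zmax)])
        expected = np.append(pz, 1 - pz.sum()) * len(words)
        stat, pval = chisquare(observed, expected)
        assert pval > 1e-4


class TestBernoulliPopulation:
    def test_entropy_hand_values(self):
        m = BernoulliPopulationModel(rates=[[0.5] * 6])
        assert m.conditional_entropy(0) == pytest.approx(6 * math.log(2), rel=1e-14)
        m2 = BernoulliPopulationModel(rates=[[0.1, 0.1]])
        assert m2.conditional_entropy(0) == pytest.approx(0.6502, abs=1e-4)

    def test_entropy_monotone_below_half(self):
        p = np.linspace(0.01, 0.49, 100)
        h = bernoulli_entropy_scalar(p)
        assert np.all(np.diff(h) > 0)

    def test_rates_validated(self):
        with pytest.raises(ValueError, match="inside"):
            BernoulliPopulationModel(rates=[[0.0, 0.5]])

    def test_marginal_logprob_single_state_reduces_to_product(self):
        m = BernoulliPopulationModel(rates=[[0.3, 0.8]])
        x = np.array([1, 0])
        assert m.marginal_logprob(x) == pytest.approx(
            math.log(0.3 * 0.2), rel=1e-14
        )

    def test_marginal_logprob_hand_mixture(self):
        m = BernoulliPopulationModel(rates=[[0.5, 0.5], [0.1, 0.1]])
        got = m.marginal_logprob(np.array([0, 0]))
        assert got == pytest.approx(math.log(0.5 * 0.25 + 0.5 * 0.81), rel=1e-14)

    def test_marginal_normalizes_by_enumeration(self, rng):
        n = 10
        m = BernoulliPopulationModel(rates=rng.uniform(0.05, 0.95, size=(4, n)))
        logps = m.marginal_logprob_many(_all_patterns(n))
        assert np.exp(logps).sum() == pytest.approx(1.0, abs=1e-10)

    def test_marginal_rejects_dimension_mismatch(self):
        m = BernoulliPopulationModel(rates=[[0.5, 0.5]])
        with pytest.raises(ValueError):
            m.marginal_logprob(np.array([0, 1, 1]))

    def test_sample_rates_converge(self, rng):
        rates = np.array([[0.1, 0.4, 0.25], [0.6, 0.2, 0.35]])
        m = BernoulliPopulationModel(rates=rates)
        x, z = m.sample(60_000, seed=21)
        for state in (0, 1):
            emp = x[z == state].mean(axis=0)
            assert np.allclose(emp, rates[state], atol=0.02)

    def test_population_rate(self):
        m = BernoulliPopulationModel(rates=[[0.1, 0.3]])
        assert m.population_rate(0) == pytest.approx(0.2, rel=1e-15)


class TestEntropyVarianceScaling:
    @staticmethod
    def shared_family(n):
        """All neurons share p(z) in {0.5, 0.1}: iid-conditional elements."""
        return BernoulliPopulationModel(
            rates=np.vstack([np.full(n, 0.5), np.full(n, 0.1)])
        )

    def test_hand_value_n2(self):
        var2 = self.shared_family(2).entropy_variance()
        h1 = np.array([math.log(2), bernoulli_entropy_scalar(0.1)])
        var1 = float(h1.var())
        assert var2 == pytest.approx(4 * var1, rel=1e-12)
        assert var2 == pytest.approx(0.1355, abs=1e-4)

    def test_exact_n_squared_relation(self):
        var1 = self.shared_family(1).entropy_variance()
        for n in (8, 64, 512):
            assert self.shared_family(n).entropy_variance() == pytest.approx(
                n**2 * var1, rel=1e-12
            )

    def test_coherent_slope_two(self):
        _, _, slope = entropy_variance_scaling(
            self.shared_family, [32, 64, 128, 256, 512, 1024]
        )
        assert slope == pytest.approx(2.0, abs=0.01)

    def test_incoherent_slope_one(self):
        def jittered(n):
            rng = np.random.default_rng(1000 + n)
            return BernoulliPopulationModel(
                rates=rng.uniform(0.05, 0.45, size=(256, n))
            )

        _, _, slope = entropy_variance_scaling(jittered, [32, 64, 128, 256, 512, 1024])
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_requires_three_sizes(self):
        with pytest.raises(ValueError, match="at least 3"):
            entropy_variance_scaling(self.shared_family, [2, 4])


class TestPlaceFieldRing:
    def test_flat_model_entropy(self):
        m = PlaceFieldRingModel(n=16, h=0.0, A=0.0)
        assert m.entropy(0.7) == pytest.approx(16 * math.log(2), rel=1e-14)
        assert m.entropy_range_over_z() == pytest.approx(0.0, abs=1e-12)

    def test_range_negligible_and_bound_o1(self):
        # translation symmetry: the entropy range is far below 1 nat at any n,
        # and the mean-value-theorem bound is O(1), not O(n)
        r64 = PlaceFieldRingModel(n=64, h=2.0, A=1.0)
        r512 = PlaceFieldRingModel(n=512, h=2.0, A=1.0)
        assert r64.entropy_range_over_z() < 1e-10
        assert r512.entropy_range_over_z() < 1e-10
        b64, b512 = r64.entropy_range_bound(), r512.entropy_range_bound()
        assert 0.5 < b512 / b64 < 2.0

    def test_z_dependent_amplitude_range_grows_with_n(self):
        def coherent(n):
            return PlaceFieldRingModel(
                n=n, h=2.0, A=1.0, amplitude_of_z=lambda z: 1.0 + 0.8 * math.cos(z)
            )

        r64 = coherent(64).entropy_range_over_z()
        r512 = coherent(512).entropy_range_over_z()
        assert r512 / r64 == pytest.approx(512 / 64, rel=0.05)

    def test_bound_refuses_broken_symmetry(self):
        m = PlaceFieldRingModel(n=8, h=1.0, A=1.0, amplitude_of_z=lambda z: z)
        with pytest.raises(ValueError, match="symmetry"):
            m.entropy_range_bound()


class TestChainRule:
    def test_conditionally_independent_h_equals_marginal(self, rng):
        m = BernoulliPopulationModel(rates=rng.uniform(0.1, 0.9, size=(3, 6)))
        dec = chain_rule_entropies(EnumerableJointModel.from_population_model(m))
        assert np.allclose(dec.h, dec.marginal_h, atol=1e-12)
        assert np.allclose(dec.mutual_information, 0.0, atol=1e-12)

    def test_chain_sums_to_total_entropy(self, rng):
        # coupled 3-element chain: x2 depends on x1, x3 on x2
        joint = np.zeros((2, 8))
        for z, (a, b) in enumerate([(0.8, 0.3), (0.4, 0.6)]):
            for idx in range(8):
                x = [(idx >> i) & 1 for i in range(3)]
                p1 = a if x[0] else 1 - a
                p2 = b if x[1] == x[0] else 1 - b
                p3 = 0.7 if x[2] == x[1] else 0.3
                joint[z, idx] = p1 * p2 * p3
        dec = chain_rule_entropies(EnumerableJointModel(joint=joint))
        assert np.allclose(dec.h.sum(axis=1), dec.total_entropy, atol=1e-12)
        # covariance decomposition sums to the direct variance
        assert dec.cov_h.sum() == pytest.approx(dec.entropy_variance(), abs=1e-12)

    def test_deterministic_copies_have_zero_h(self):
        # elements 2..n copy element 1 exactly: h_i = 0 for i >= 2 and the
        # entropy variance stays bounded no matter how many copies exist
        for n in (3, 6):
            joint = np.zeros((2, 2**n))
            for z, p in enumerate([0.9, 0.2]):
                joint[z, 0] = 1 - p  # all zeros
                joint[z, 2**n - 1] = p  # all ones
            dec = chain_rule_entropies(EnumerableJointModel(joint=joint))
            assert np.allclose(dec.h[:, 1:], 0.0, atol=1e-14)
            assert dec.entropy_variance() < 0.2  # independent of n

    def test_rejects_large_joint(self):
        with pytest.raises(ValueError, match="not enumerable"):
            EnumerableJointModel(joint=np.full((1, 2**15), 2.0**-15))
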