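"""Energy spectra, rank curves, exponential smoothing, and the exact identity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zipflatent import (
    EmpiricalDistribution,
    build_spectrum,
    rank_curve,
    smoothed_density,
    zipf_deviation,
    zipf_identity_residual,
    zipf_slope,
)
from conftest import random_distribution


class TestEmpiricalDistribution:
    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="empty"):
            EmpiricalDistribution.from_counts({})

    def test_rejects_zero_probability_naming_state(self):
        with pytest.raises(ValueError, match="bad_state"):
            EmpiricalDistribution(("ok", "bad_state"), np.array([1.0, 0.0]))

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum"):
            EmpiricalDistribution(("a", "b"), np.array([0.5, 0.4]))

    def test_normalize_flag(self):
        d = EmpiricalDistribution.from_probabilities(
            {"a": 2.0, "b": 2.0}, normalize=True
        )
        assert np.allclose(d.probabilities, 0.5)

    def test_from_counts_drops_zero_counts(self):
        d = EmpiricalDistribution.from_counts({"a": 3, "b": 1, "c": 0})
        assert set(d.states) == {"a", "b"}
        assert np.allclose(sorted(d.probabilities), [0.25, 0.75])


class TestBuildSpectrum:
    def test_hand_energies(self, quarter_halves):
        spec = build_spectrum(quarter_halves)
        expected = [math.log(2), math.log(4), math.log(8), math.log(8)]
        assert np.allclose(spec.energies, expected, atol=1e-15)

    def test_uniform_all_equal(self):
        K = 7
        d = EmpiricalDistribution(tuple(range(K)), np.full(K, 1.0 / K))
        spec = build_spectrum(d)
        assert np.allclose(spec.energies, math.log(K))

    def test_single_state_zero_energy(self):
        spec = build_spectrum(EmpiricalDistribution(("a",), np.array([1.0])))
        assert spec.energies[0] == 0.0


class TestRankCurve:
    def test_hand_ranks_with_ties(self, quarter_halves):
        curve = rank_curve(build_spectrum(quarter_halves))
        assert list(curve.ranks) == [1, 2, 4, 4]

    def test_uniform_all_max_rank(self):
        K = 5
        d = EmpiricalDistribution(tuple(range(K)), np.full(K, 1.0 / K))
        assert list(rank_curve(build_spectrum(d)).ranks) == [K] * K

    @pytest.mark.parametrize("n_states", [2, 17, 300])
    def test_matches_sort_and_count_oracle(self, rng, n_states):
        d = random_distribution(rng, n_states)
        spec = build_spectrum(d)
        curve = rank_curve(spec)
        # oracle: for each atom, count atoms with energy <= its energy
        oracle = np.array(
            [int(np.sum(spec.energies <= e)) for e in spec.energies]
        )
        assert np.array_equal(curve.ranks, oracle)
        assert curve.ranks.max() == n_states


class TestSmoothedDensity:
    def test_hand_value_at_log4(self, quarter_halves):
        spec = build_spectrum(quarter_halves)
        # 1/2 e^{log2 - log4} + 1/4 = 1/2
        val = smoothed_density(spec, [math.log(4)]).values[0]
        assert val == pytest.approx(0.5, abs=1e-15)

    def test_zero_below_support(self, quarter_halves):
        spec = build_spectrum(quarter_halves)
        assert smoothed_density(spec, [0.1]).values[0] == 0.0

    def test_max_energy_full_count(self, quarter_halves):
        spec = build_spectrum(quarter_halves)
        emax = spec.energies[-1]
        val = smoothed_density(spec, [emax]).values[0]
        assert val == pytest.approx(4 * math.exp(-emax), rel=1e-14)

    def test_matches_probability_sum_oracle(self, rng):
        d = random_distribution(rng, 200)
        spec = build_spectrum(d)
        pts = np.sort(rng.uniform(spec.energies[0], spec.energies[-1], 50))
        got = smoothed_density(spec, pts).values
        oracle = np.array(
            [
                math.fsum(
                    p * math.exp(e - x)
                    for p, e in zip(spec.probabilities, spec.energies)
                    if e <= x
                )
                for x in pts
            ]
        )
        assert np.allclose(got, oracle, rtol=1e-12)

    def test_rejects_nonfinite_eval_points(self, quarter_halves):
        spec = build_spectrum(quarter_halves)
        with pytest.raises(ValueError, match="finite"):
            smoothed_density(spec, [np.inf])


class TestZipfIdentity:
    def test_hand_example_zero(self, quarter_halves):
        res = zipf_identity_residual(build_spectrum(quarter_halves))
        assert np.max(np.abs(res)) < 1e-12

    def test_single_state(self):
        spec = build_spectrum(EmpiricalDistribution(("a",), np.array([1.0])))
        assert zipf_identity_residual(spec)[0] == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n_states=st.integers(min_value=2, max_value=2000),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_identity_holds_on_random_spectra(self, n_states, seed):
        rng = np.random.default_rng(seed)
        d = random_distribution(rng, n_states)
        res = zipf_identity_residual(build_spectrum(d))
        assert np.max(np.abs(res)) < 1e-12


class TestZipfDeviation:
    @pytest.mark.parametrize("K", [10, 1000, 10_000])
    def test_exact_zipf_gives_zero(self, K):
        k = np.arange(1, K + 1)
        h = (1.0 / k).sum()
        d = EmpiricalDistribution(tuple(k.tolist()), 1.0 / (k * h))
        assert zipf_deviation(build_spectrum(d)) < 1e-12

    def test_geometric_positive(self):
        k = np.arange(1, 21)
        p = 2.0 ** (-k.astype(float))
        p[-1] *= 2  # close the geometric tail so the mass sums to 1
        d = EmpiricalDistribution(tuple(k.tolist()), p)
        assert zipf_deviation(build_spectrum(d)) > 0.1

    def test_two_equiprobable_states_zero(self):
        d = EmpiricalDistribution(("a", "b"), np.array([0.5, 0.5]))
        assert zipf_deviation(build_spectrum(d)) == pytest.approx(0.0, abs=1e-15)

    def test_relabeling_invariance(self, rng):
        p = rng.dirichlet(np.ones(50))
        d1 = EmpiricalDistribution(tuple(range(50)), p)
        perm = rng.permutation(50)
        d2 = EmpiricalDistribution(tuple(f"s{i}" for i in range(50)), p[perm])
        assert zipf_deviation(build_spectrum(d1)) == pytest.approx(
            zipf_deviation(build_spectrum(d2)), rel=1e-12
        )

    def test_rejects_single_atom(self):
        spec = build_spectrum(EmpiricalDistribution(("a",), np.array([1.0])))
        with pytest.raises(ValueError, match="at least 2"):
            zipf_deviation(spec)


class TestZipfSlope:
    def test_exact_power_law_recovers_minus_one(self):
        K = 5000
        k = np.arange(1, K + 1)
        h = (1.0 / k).sum()
        d = EmpiricalDistribution(tuple(k.tolist()), 1.0 / (k * h))
        slope = zipf_slope(rank_curve(build_spectrum(d)))
        assert slope == pytest.approx(-1.0, abs=0.01)

    def test_steeper_law_recovers_exponent(self):
        K = 5000
        k = np.arange(1, K + 1, dtype=float)
        w = k**-1.5
        d = EmpiricalDistribution(tuple(range(K)), w / w.sum())
        slope = zipf_slope(rank_curve(build_spectrum(d)))
        assert slope == pytest.approx(-1.5, abs=0.02)


def test_curve_export_columns(quarter_halves):
    df = rank_curve(build_spectrum(quarter_halves)).to_frame()
    assert list(df.columns) == [
        "state", "probability", "energy_nats", "rank", "log10_rank",
    ]
    assert np.allclose(df["log10_rank"], np.log10(df["rank"]))
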