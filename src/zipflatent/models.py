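"""Generative latent-variable models that do (and do not) produce Zipf's law.

Three model families:

* :class:`LiWordModel` -- random "words" built by drawing symbols uniformly
  from an alphabet of M letters plus a stop symbol, so that the word length z
  is geometric, ``P(z) = (1/M) (M/(M+1))^z`` for z >= 1, and every specific
  length-z string has probability ``M^{-z} P(z)``.  Sequence length is the
  latent variable and mixing over lengths produces Zipf's law.

* :class:`BernoulliPopulationModel` -- n conditionally independent binary
  neurons whose firing probabilities ``p_i(z)`` depend on a discrete latent
  state z (e.g. time since stimulus onset).  When the latent variable
  modulates the rates coherently, the conditional entropy varies by O(n) over
  z, the energy variance scales as n^2, and Zipf's law emerges.

* :class:`PlaceFieldRingModel` -- the counterexample: cosine-tuned log odds
  around a ring.  Translating the latent angle shifts which neurons fire but,
  by symmetry, changes the population entropy only by O(1), so the energy
  distribution never broadens and Zipf's law does not emerge.

Plus :func:`chain_rule_entropies`, which decomposes the conditional entropy
of any small enumerable joint model into per-element averaged conditional
entropies, the machinery behind the n^2 variance-scaling argument for
non-independent data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "LiWordModel",
    "BernoulliPopulationModel",
    "PlaceFieldRingModel",
    "EnumerableJointModel",
    "ChainRuleDecomposition",
    "bernoulli_entropy_scalar",
    "entropy_variance_scaling",
    "chain_rule_entropies",
]


def bernoulli_entropy_scalar(p: np.ndarray | float) -> np.ndarray | float:
    """Entropy (nats) of a Bernoulli variable, elementwise: H_B(p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("Bernoulli rates must lie strictly inside (0, 1)")
    return -(p * np.log(p) + (1 - p) * np.log1p(-p))


# ---------------------------------------------------------------------------
# Li random-word model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LiWordModel:
    """Random words over an M-letter alphabet terminated by a stop symbol.

    Each symbol is one of M letters or the stop, all equiprobable; the word
    is the run of letters before the first stop.  The length z is therefore
    geometric with success probability 1/(M+1) (support z >= 1; empty words
    are excluded by the leading 1/M normalizer), and each specific length-z
    string has probability ``M^{-z} P(z)``.

    ``z_max`` truncates enumeration only; sampling is untruncated.  The
    default leaves a geometric tail mass below 1e-12.
    """

    M: int
    z_max: int | None = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("alphabet size M must be >= 1")
        if self.z_max is None:
            # tail mass after z_max is (M/(M+1))^z_max; solve for < 1e-12
            zm = int(math.ceil(-12 * math.log(10) / math.log(self.M / (self.M + 1))))
            object.__setattr__(self, "z_max", zm)

    def length_pmf(self, z: int | np.ndarray) -> float | np.ndarray:
        """P(z) = (1/M) (M/(M+1))^z for integer z >= 1."""
        z = np.asarray(z)
        if np.any(z < 1):
            raise ValueError("lengths must be integers >= 1")
        val = (1.0 / self.M) * (self.M / (self.M + 1.0)) ** z
        return float(val) if val.ndim == 0 else val

    def pattern_energy(self, z: int | np.ndarray) -> float | np.ndarray:
        """Energy (nats) of any specific length-z string: z log M - log P(z)."""
        z = np.asarray(z)
        if np.any(z < 1):
            raise ValueError("lengths must be integers >= 1")
        val = z * math.log(self.M) - np.log(self.length_pmf(z))
        return float(val) if val.ndim == 0 else val

    def logpz_variance(self) -> float:
        """Closed-form Var_z[log P(z)] = M(M+1) [log(1 + 1/M)]^2.

        Bounded by (M+1)/M because log(1+eps) <= eps; hence O(1) in M.
        """
        return self.M * (self.M + 1) * math.log(1.0 + 1.0 / self.M) ** 2

    def logpz_variance_bruteforce(self, z_cap: int = 500) -> float:
        """Direct summation of Var_z[log P(z)] over z <= z_cap (oracle)."""
        z = np.arange(1, z_cap + 1)
        pz = self.length_pmf(z)
        # log P(z) computed in closed form so that underflowed tail terms
        # (pz -> 0) contribute exactly 0 rather than 0 * (-inf)
        lp = -math.log(self.M) + z * math.log(self.M / (self.M + 1.0))
        m1 = np.sum(pz * lp)
        m2 = np.sum(pz * lp**2)
        return float(m2 - m1**2)

    def sample(self, n_samples: int, seed: int | np.random.Generator) -> list[str]:
        """Draw words: geometric lengths, then iid uniform letters.

        Letters are lowercase a, b, c, ... (wrapping into multi-character
        tokens if M > 26, though typical use keeps M <= 26).
        """
        rng = np.random.default_rng(seed)
        lengths = rng.geometric(1.0 / (self.M + 1), size=n_samples)
        alphabet = _alphabet(self.M)
        letters = rng.integers(0, self.M, size=int(lengths.sum()))
        words = []
        pos = 0
        for L in lengths:
            words.append("".join(alphabet[j] for j in letters[pos : pos + L]))
            pos += L
        return words


def _alphabet(M: int) -> list[str]:
    if M <= 26:
        return [chr(ord("a") + i) for i in range(M)]
    return [f"s{i}." for i in range(M)]


# ---------------------------------------------------------------------------
# Bernoulli population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BernoulliPopulationModel:
    """Conditionally independent binary neurons with state-dependent rates.

    ``rates`` has one row per latent state and one column per neuron
    (shape Z x n); all entries strictly inside (0, 1).  ``prior`` is P(z)
    over the Z latent states (uniform by default, matching equal-time
    sampling of time bins).
    """

    rates: np.ndarray
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        object.__setattr__(self, "rates", rates)
        if np.any((rates <= 0) | (rates >= 1)):
            raise ValueError("rates must lie strictly inside (0, 1)")
        if self.prior is None:
            object.__setattr__(
                self, "prior", np.full(rates.shape[0], 1.0 / rates.shape[0])
            )
        else:
            prior = np.asarray(self.prior, dtype=float)
            if prior.shape != (rates.shape[0],):
                raise ValueError("prior must have one entry per latent state")
            if abs(prior.sum() - 1.0) > 1e-12 or np.any(prior < 0):
                raise ValueError("prior must be a probability vector")
            object.__setattr__(self, "prior", prior)

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[1]

    def conditional_entropy(self, z: int) -> float:
        """H_{x|z}(z) in nats: sum over neurons of the Bernoulli entropy."""
        return float(np.sum(bernoulli_entropy_scalar(self.rates[z])))

    def entropies(self) -> np.ndarray:
        """H_{x|z}(z) for every latent state."""
        return bernoulli_entropy_scalar(self.rates).sum(axis=1)

    def entropy_variance(self) -> float:
        """Var_z[H_{x|z}(z)] under the prior."""
        h = self.entropies()
        m = float(np.sum(self.prior * h))
        return float(np.sum(self.prior * (h - m) ** 2))

    def population_rate(self, z: int) -> float:
        """nu(z) = mean firing probability across the population."""
        return float(self.rates[z].mean())

    def conditional_logprob(self, x: np.ndarray) -> np.ndarray:
        """log P(x|z) for every z; x is a binary vector of length n."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_neurons,):
            raise ValueError(
                f"pattern has length {x.shape}, model has {self.n_neurons} neurons"
            )
        if np.any((x != 0) & (x != 1)):
            raise ValueError("patterns must be binary")
        return (
            x * np.log(self.rates) + (1 - x) * np.log1p(-self.rates)
        ).sum(axis=1)

    def marginal_logprob(self, x: np.ndarray) -> float:
        """log P(x) = log sum_z P(z) P(x|z), via log-sum-exp (no truncation)."""
        return float(logsumexp(self.conditional_logprob(x) + np.log(self.prior)))

    def marginal_logprob_many(self, X: np.ndarray) -> np.ndarray:
        """Vectorized marginal log probability for a (samples x n) 0/1 matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_neurons:
            raise ValueError("X must be (n_samples, n_neurons)")
        logp = np.log(self.rates)  # (Z, n)
        log1mp = np.log1p(-self.rates)
        # (samples, Z): X @ (logp - log1mp)^T + sum log1mp per z
        ll = X @ (logp - log1mp).T + log1mp.sum(axis=1)
        return logsumexp(ll + np.log(self.prior), axis=1)

    def sample(
        self, n_samples: int, seed: int | np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw (patterns, latent labels): z ~ prior, then x_i ~ Bern(p_i(z))."""
        rng = np.random.default_rng(seed)
        z = rng.choice(self.n_states, size=n_samples, p=self.prior)
        x = (rng.random((n_samples, self.n_neurons)) < self.rates[z]).astype(np.int8)
        return x, z


# ---------------------------------------------------------------------------
# Place-field ring model (the non-Zipfian counterexample)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlaceFieldRingModel:
    """Cosine-tuned binary neurons on a ring: logit p_i = -h + A cos(z - theta_i).

    Preferred angles theta_i = 2*pi*i/n are evenly spaced and the latent z is
    an angle in [0, 2*pi).  Translating z permutes the tuning curves, so the
    population entropy is nearly independent of z: its range over z is O(1)
    no matter how large n grows, far short of the O(n) entropy modulation
    required for Zipf's law.

    ``amplitude_of_z`` optionally makes the modulation amplitude itself a
    function of z, breaking the translation symmetry; the entropy range then
    grows linearly with n and Zipf's law is restored.
    """

    n: int
    h: float
    A: float
    amplitude_of_z: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one neuron")

    @property
    def preferred_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n) / self.n

    def rates(self, z: float) -> np.ndarray:
        """p(z - theta_i) for all neurons; strictly inside (0, 1)."""
        amp = self.A if self.amplitude_of_z is None else self.amplitude_of_z(z)
        logits = -self.h + amp * np.cos(z - self.preferred_angles)
        return 1.0 / (1.0 + np.exp(-logits))

    def entropy(self, z: float) -> float:
        """Population entropy H(z) = sum_i H_B(p(z - theta_i)), in nats.

        Compensated summation keeps the result correctly rounded, since for
        the translation-symmetric ring the z-dependence of H is far smaller
        than naive summation error.
        """
        return math.fsum(bernoulli_entropy_scalar(self.rates(z)))

    def entropy_range_over_z(self, n_grid: int | None = None) -> float:
        """max - min of H(z) over a uniform angle grid (default 4n points).

        The 4n default resolves the 2*pi/n spacing of the preferred angles.
        For the fixed-amplitude ring, H(z) is exactly periodic with period
        2*pi/n and its true range decays exponentially in n, so for large n
        the returned value is limited by double-precision rounding of H
        itself (a noise floor of order ``n * 1e-16`` nats) -- either way,
        negligible against the O(n) modulation Zipf's law would need.  Use
        :meth:`entropy_range_bound` for the O(1) analytic bound.
        """
        if n_grid is None:
            n_grid = 4 * self.n
        grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
        hs = np.array([self.entropy(z) for z in grid])
        return float(hs.max() - hs.min())

    def entropy_range_bound(self, n_grid: int | None = None) -> float:
        """Mean-value-theorem bound on the entropy range over z, in nats.

        Any angle z sits within pi/n of some preferred angle theta_j, and
        H(theta_j) is independent of j by symmetry, so the range of H over z
        is at most ``(pi/n)`` times the largest possible slope, itself
        bounded by the sum of the n per-neuron derivative magnitudes -- each
        O(1) -- hence the bound is O(1) in n: the latent angle can never
        modulate the population entropy extensively, which is why the ring
        model does not produce Zipf's law.
        """
        if self.amplitude_of_z is not None:
            raise ValueError(
                "the O(1) range bound relies on translation symmetry; it does "
                "not apply when the amplitude depends on z"
            )
        if n_grid is None:
            n_grid = 4 * self.n
        grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)
        max_abs_deriv = 0.0
        for z in grid:
            p = self.rates(z)
            # dH_B/dz = log((1-p)/p) * p(1-p) * (-A sin(z - theta_i))
            dp_dz = p * (1.0 - p) * (-self.A * np.sin(z - self.preferred_angles))
            deriv = math.fsum(np.abs(np.log((1.0 - p) / p) * dp_dz))
            max_abs_deriv = max(max_abs_deriv, deriv)
        return (math.pi / self.n) * max_abs_deriv

    def to_population_model(self, n_states: int) -> BernoulliPopulationModel:
        """Discretize the ring into n_states latent states with uniform prior."""
        grid = np.linspace(0.0, 2.0 * np.pi, n_states, endpoint=False)
        rates = np.vstack([self.rates(z) for z in grid])
        return BernoulliPopulationModel(rates=rates)


# ---------------------------------------------------------------------------
# Entropy-variance scaling over population size
# ---------------------------------------------------------------------------


def entropy_variance_scaling(
    model_family: Callable[[int], BernoulliPopulationModel],
    n_list: Sequence[int],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Var_z[H_{x|z}] versus population size n, with the fitted log-log slope.

    For a family whose neurons share identically distributed per-element
    entropies over z (coherent latent modulation), the total conditional
    entropy is n times the per-element entropy, so its variance over z is
    exactly n^2 times the per-element variance: slope 2.  Independent
    per-neuron rate jitter with no shared modulation gives variance O(n):
    slope 1.

    Returns ``(n_array, variance_array, slope)``.
    """
    if len(n_list) < 3:
        raise ValueError("need at least 3 population sizes to fit a slope")
    n_arr = np.asarray(sorted(n_list), dtype=float)
    variances = np.array(
        [model_family(int(n)).entropy_variance() for n in n_arr]
    )
    if np.any(variances <= 0):
        raise ValueError("entropy variance must be positive for slope fitting")
    slope = float(np.polyfit(np.log(n_arr), np.log(variances), 1)[0])
    return n_arr, variances, slope


# ---------------------------------------------------------------------------
# Chain-rule entropy decomposition for small enumerable joints
# ---------------------------------------------------------------------------

_MAX_ENUM_ELEMENTS = 14


@dataclass(frozen=True)
class EnumerableJointModel:
    """A fully enumerated conditional distribution over binary vectors.

    ``joint[z]`` is a probability vector of length 2**n over all binary
    patterns of n elements, bit i of the pattern index giving x_i (bit 0 is
    element 0).  Only small n is supported; this exists so the chain-rule
    entropy decomposition can be checked exactly against enumeration.
    """

    joint: np.ndarray  # (Z, 2**n)
    prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        joint = np.atleast_2d(np.asarray(self.joint, dtype=float))
        object.__setattr__(self, "joint", joint)
        n = int(math.log2(joint.shape[1]))
        if 2**n != joint.shape[1]:
            raise ValueError("joint table length must be a power of 2")
        if n > _MAX_ENUM_ELEMENTS:
            raise ValueError(
                f"joint with {n} binary elements is not enumerable here "
                f"(limit {_MAX_ENUM_ELEMENTS})"
            )
        if not np.allclose(joint.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("each conditional joint must sum to 1")
        if self.prior is None:
            object.__setattr__(
                self, "prior", np.full(joint.shape[0], 1.0 / joint.shape[0])
            )

    @property
    def n_elements(self) -> int:
        return int(math.log2(self.joint.shape[1]))

    @property
    def n_states(self) -> int:
        return self.joint.shape[0]

    @classmethod
    def from_population_model(
        cls, model: BernoulliPopulationModel
    ) -> "EnumerableJointModel":
        """Enumerate a (small) conditionally independent Bernoulli model."""
        n = model.n_neurons
        patterns = _all_patterns(n)
        logp = patterns @ np.log(model.rates).T + (1 - patterns) @ np.log1p(
            -model.rates
        ).T  # (2**n, Z)
        return cls(joint=np.exp(logp).T, prior=model.prior)


def _all_patterns(n: int) -> np.ndarray:
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


@dataclass(frozen=True)
class ChainRuleDecomposition:
    """Chain-rule split of the conditional entropy of an enumerable joint.

    ``h[z, i]`` is the entropy of x_i given z and x_0..x_{i-1}, averaged over
    the earlier elements; these sum over i to the full conditional entropy
    H_{x|z}(z) exactly.  ``marginal_h[z, i]`` is the elementwise marginal
    entropy H_{x_i|z}(z); the gap ``marginal_h - h`` is the mutual
    information between x_i and its predecessors given z.  Covariance
    matrices over z (under the prior) decompose Var_z[H]: the entries of
    ``cov_h`` sum to the direct variance of H.
    """

    h: np.ndarray  # (Z, n) averaged conditional entropies
    marginal_h: np.ndarray  # (Z, n) elementwise marginal entropies
    total_entropy: np.ndarray  # (Z,) direct H_{x|z}(z)
    cov_h: np.ndarray  # (n, n) Cov_z[h_i, h_j]
    cov_marginal_h: np.ndarray  # (n, n) Cov_z[H_{x_i|z}, H_{x_j|z}]
    prior: np.ndarray

    @property
    def mutual_information(self) -> np.ndarray:
        """I_i(z) = H_{x_i|z}(z) - h_i(z), the predecessor information."""
        return self.marginal_h - self.h

    def entropy_variance(self) -> float:
        m = float(np.sum(self.prior * self.total_entropy))
        return float(np.sum(self.prior * (self.total_entropy - m) ** 2))


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def chain_rule_entropies(model: EnumerableJointModel) -> ChainRuleDecomposition:
    """Exact chain-rule entropy decomposition by full enumeration.

    For each latent state z and element i, computes the conditional entropy
    of x_i given z and all earlier elements, weighted by the probability of
    the earlier elements.  The per-element terms sum to the full conditional
    entropy exactly (chain rule); their covariance matrix over z sums to
    Var_z[H_{x|z}], the quantity whose n^2 scaling signals Zipf's law.
    """
    n = model.n_elements
    Z = model.n_states
    patterns = _all_patterns(n).astype(int)  # (2**n, n)
    h = np.zeros((Z, n))
    marg = np.zeros((Z, n))
    total = np.zeros(Z)
    for z in range(Z):
        p = model.joint[z]
        total[z] = float(-np.sum(_xlogx(p)))
        for i in range(n):
            # marginal entropy of element i
            p1 = float(p[patterns[:, i] == 1].sum())
            marg[z, i] = -sum(
                q * math.log(q) for q in (p1, 1.0 - p1) if q > 0.0
            )
            # averaged conditional entropy given predecessors x_0..x_{i-1}
            # group patterns by their prefix and by x_i
            if i == 0:
                prefix = np.zeros(len(patterns), dtype=int)
            else:
                prefix = patterns[:, :i] @ (1 << np.arange(i))
            # joint over (prefix, x_i)
            key = prefix * 2 + patterns[:, i]
            joint_pi = np.bincount(key, weights=p, minlength=2 ** (i + 1)).reshape(
                -1, 2
            )
            p_prefix = joint_pi.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cond = np.where(
                    p_prefix[:, None] > 0, joint_pi / p_prefix[:, None], 0.0
                )
            ent = -np.sum(_xlogx(cond), axis=1)
            h[z, i] = float(np.sum(p_prefix * ent))
    w = model.prior
    def _cov(mat: np.ndarray) -> np.ndarray:
        mean = w @ mat
        centered = mat - mean
        return (centered * w[:, None]).T @ centered
    return ChainRuleDecomposition(
        h=h,
        marginal_h=marg,
        total_entropy=total,
        cov_h=_cov(h),
        cov_marginal_h=_cov(marg),
        prior=w,
    )
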