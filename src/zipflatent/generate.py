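"""Synthetic-data generators for the three data domains, with ground truth.

Every generator returns, alongside the sampled data, the analytic population
it was built from (probabilities, rates, PEEV, length pmf), so downstream
estimators can be validated by parameter recovery rather than against
constants.

* :func:`gen_categorical` emulates word-frequency tables: a few categories
  ("parts of speech") each holding a vocabulary of a chosen size, with either
  a uniform or a power-law within-category frequency law.  Categories with
  small vocabularies yield common items and low energies; large vocabularies
  yield rare items and high energies -- the structure that makes the
  category a Zipf-producing latent variable.

* :func:`gen_spike_trains` emulates post-stimulus population spiking:
  per-neuron firing probabilities decay with the trial-aligned time bin,
  ``p_i(z) = b_i + a_i exp(-z / tau)``.  With coherent modulation the shared
  decay drives all entropies together (n^2 energy-variance scaling); the
  incoherent control permutes each neuron's time profile independently,
  destroying the shared latent structure while preserving every marginal.

* :func:`gen_varlength_sequences` emulates variable-length sequence sets:
  the random-word process (M equiprobable letters terminated by a stop
  symbol), whose geometric length distribution is the latent variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SpikeRaster
from .models import BernoulliPopulationModel, LiWordModel
from .peev import CategoricalLatentDataset, PEEVDecomposition

__all__ = [
    "CategoricalConfig",
    "SpikeConfig",
    "SequenceConfig",
    "CategoricalSample",
    "SpikeSample",
    "SequenceSample",
    "gen_categorical",
    "gen_spike_trains",
    "gen_varlength_sequences",
]


# ---------------------------------------------------------------------------
# Categorical (word-like) data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalConfig:
    """Population design for word-like categorical data.

    ``vocab_sizes[c]`` is the number of distinct items in category c;
    ``category_weights[c]`` its share of total probability mass (normalized
    internally); ``within_exponents[c]`` the exponent s of the within-category
    frequency law P(j|c) proportional to j^(-s) (0 gives a uniform law, the
    point-mass-energy case).
    """

    vocab_sizes: tuple[int, ...]
    category_weights: tuple[float, ...] | None = None
    within_exponents: tuple[float, ...] | None = None
    n_tokens: int = 1_000_000

    def __post_init__(self) -> None:
        k = len(self.vocab_sizes)
        if k == 0 or any(v < 1 for v in self.vocab_sizes):
            raise ValueError("vocab sizes must be positive integers")
        if self.category_weights is None:
            object.__setattr__(self, "category_weights", tuple([1.0 / k] * k))
        elif len(self.category_weights) != k or any(
            w <= 0 for w in self.category_weights
        ):
            raise ValueError("category weights must be positive, one per category")
        if self.within_exponents is None:
            object.__setattr__(self, "within_exponents", tuple([0.0] * k))
        elif len(self.within_exponents) != k:
            raise ValueError("one within-category exponent per category")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be positive")


@dataclass(frozen=True)
class CategoricalSample:
    """Sampled dataset plus the analytic population it was drawn from."""

    dataset: CategoricalLatentDataset
    population: pd.DataFrame  # item, category, probability
    analytic: PEEVDecomposition
    seed: int


def _population_table(config: CategoricalConfig) -> pd.DataFrame:
    rows = []
    wsum = sum(config.category_weights)
    for c, (V, w, s) in enumerate(
        zip(config.vocab_sizes, config.category_weights, config.within_exponents)
    ):
        j = np.arange(1, V + 1, dtype=float)
        within = j ** (-s)
        within /= within.sum()
        for jj, q in enumerate(within, start=1):
            rows.append((f"c{c}_w{jj}", f"cat{c}", (w / wsum) * q))
    return pd.DataFrame(rows, columns=["item", "category", "probability"])


def _analytic_peev(pop: pd.DataFrame) -> PEEVDecomposition:
    """Exact PEEV of a population with known probabilities."""
    p = pop["probability"].to_numpy()
    e = -np.log(p)
    mean_e = float(np.sum(p * e))
    total = float(np.sum(p * (e - mean_e) ** 2))
    if total <= 0:
        raise ValueError("degenerate population: zero energy variance")
    between = 0.0
    within = 0.0
    for _, grp in pop.groupby("category", sort=False):
        pg = grp["probability"].to_numpy()
        pz = pg.sum()
        w = pg / pz
        eg = -np.log(pg)
        m = float(np.sum(w * eg))
        between += pz * (m - mean_e) ** 2
        within += pz * float(np.sum(w * (eg - m) ** 2))
    return PEEVDecomposition(
        total_var=total,
        between_var=between,
        within_var=within,
        peev=between / total,
        n_categories=pop["category"].nunique(),
        n_states=len(pop),
    )


def gen_categorical(config: CategoricalConfig, seed: int) -> CategoricalSample:
    """Draw a token sample from the designed population.

    Token counts are multinomial over the population; items that receive no
    tokens are dropped (their energy would be undefined), which is exactly
    the finite-sample truncation a real frequency table exhibits.
    """
    rng = np.random.default_rng(seed)
    pop = _population_table(config)
    counts = rng.multinomial(config.n_tokens, pop["probability"].to_numpy())
    observed = pop.assign(count=counts).loc[lambda d: d["count"] > 0]
    ds = CategoricalLatentDataset(
        observed[["item", "count", "category"]].reset_index(drop=True)
    )
    return CategoricalSample(
        dataset=ds, population=pop, analytic=_analytic_peev(pop), seed=seed
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeConfig:
    """Post-stimulus decaying-rate population design.

    Rates follow ``p_i(z) = b_i + a_i exp(-z / tau)`` over trial-aligned bins
    z = 0 .. trial_length-1, with per-neuron baselines and amplitudes
    jittered around ``baseline`` and ``amplitude`` by +/- ``jitter``
    (relative).  ``coherent=False`` permutes each neuron's time profile
    independently, which preserves all per-neuron marginals but removes the
    shared latent modulation.
    """

    n_neurons: int = 30
    trial_length: int = 100
    n_trials: int = 30
    baseline: float = 0.02
    amplitude: float = 0.35
    tau: float = 15.0
    jitter: float = 0.2
    coherent: bool = True
    bin_ms: float = 20.0

    def __post_init__(self) -> None:
        if min(self.n_neurons, self.trial_length, self.n_trials) < 1:
            raise ValueError("population, trial length and trial count must be >= 1")
        if not (0 < self.baseline and self.baseline + self.amplitude * (1 + self.jitter) < 1):
            raise ValueError("rates must stay inside (0, 1)")


@dataclass(frozen=True)
class SpikeSample:
    raster: SpikeRaster
    model: BernoulliPopulationModel  # ground-truth rates
    seed: int


def spike_rate_matrix(config: SpikeConfig, seed: int) -> np.ndarray:
    """Ground-truth rate matrix (trial_length x n_neurons) for a config."""
    rng = np.random.default_rng(seed)
    z = np.arange(config.trial_length, dtype=float)
    b = config.baseline * (
        1 + config.jitter * rng.uniform(-1, 1, size=config.n_neurons)
    )
    a = config.amplitude * (
        1 + config.jitter * rng.uniform(-1, 1, size=config.n_neurons)
    )
    decay = np.exp(-z / config.tau)  # (Z,)
    rates = b[None, :] + a[None, :] * decay[:, None]
    if not config.coherent:
        # independent per-neuron time shuffles: marginals intact, shared
        # modulation destroyed
        for i in range(config.n_neurons):
            rates[:, i] = rng.permutation(rates[:, i])
    return rates


def gen_spike_trains(config: SpikeConfig, seed: int) -> SpikeSample:
    """Sample a trial-structured binary raster from the designed rates."""
    rates = spike_rate_matrix(config, seed)
    model = BernoulliPopulationModel(rates=rates)
    rng = np.random.default_rng(seed + 1)
    draws = rng.random((config.n_trials, config.trial_length, config.n_neurons))
    matrix = (draws < rates[None, :, :]).astype(np.int8)
    latent = np.tile(np.arange(config.trial_length), config.n_trials)
    raster = SpikeRaster(
        matrix=matrix.reshape(-1, config.n_neurons),
        trial_length=config.trial_length,
        bin_ms=config.bin_ms,
        latent=latent,
    )
    return SpikeSample(raster=raster, model=model, seed=seed)


# ---------------------------------------------------------------------------
# Variable-length sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceConfig:
    """Random-word process: M letters plus a stop symbol, all equiprobable."""

    M: int = 4
    n_sequences: int = 100_000

    def __post_init__(self) -> None:
        if self.M < 1 or self.n_sequences < 1:
            raise ValueError("M and n_sequences must be positive")


@dataclass(frozen=True)
class SequenceSample:
    sequences: list[str]
    model: LiWordModel
    seed: int


def gen_varlength_sequences(config: SequenceConfig, seed: int) -> SequenceSample:
    """Sample words whose geometric length distribution is the latent variable."""
    model = LiWordModel(M=config.M)
    return SequenceSample(
        sequences=model.sample(config.n_sequences, seed), model=model, seed=seed
    )
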