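"""Discrete distributions, energies, rank curves and the exact Zipf identity.

The central object is the *energy spectrum* of a discrete distribution: each
state ``x`` with probability ``P(x)`` is assigned an energy ``E(x) = -log P(x)``
in nats.  Ranking states by energy (equivalently, by decreasing probability)
gives the Zipf curve, and Zipf's law -- frequency inversely proportional to
rank -- is equivalent to ``log r(E) = E + const``.

The identity implemented here is exact for any discrete distribution::

    log r(E) = E + log P_S(E)

where ``P_S(E)`` is the energy distribution smoothed with a one-sided
exponential kernel.  For a discrete spectrum, ``e^E * P_S(E)`` equals the
number of states with energy <= E, so with the max-tie rank convention
(rank = count of states at or below this energy) the identity holds to
machine precision.  Departures from Zipf's law are therefore exactly the
variations of ``log P_S(E)`` across the support, which motivates the
``zipf_deviation`` statistic: the probability-weighted standard deviation of
``log P_S(E(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmpiricalDistribution",
    "EnergySpectrum",
    "ZipfCurve",
    "SmoothedEnergyDensity",
    "build_spectrum",
    "rank_curve",
    "smoothed_density",
    "zipf_identity_residual",
    "zipf_deviation",
    "zipf_slope",
]

_PROB_SUM_TOL = 1e-12


@dataclass(frozen=True)
class EmpiricalDistribution:
    """A finite discrete distribution over opaque, unique state identifiers.

    Probabilities must be strictly positive and sum to one (within 1e-12).
    When built from counts, probabilities are the maximum-likelihood
    frequencies ``count / total``; zero-count states are dropped because
    their energy would be undefined.
    """

    states: tuple[Hashable, ...]
    probabilities: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", probs)
        if len(self.states) == 0:
            raise ValueError("empty distribution: at least one state is required")
        if len(self.states) != len(set(self.states)):
            raise ValueError("state identifiers must be unique")
        if probs.shape != (len(self.states),):
            raise ValueError("probabilities must align one-to-one with states")
        bad = np.nonzero(~(probs > 0.0))[0]
        if bad.size:
            raise ValueError(
                f"state {self.states[bad[0]]!r} has non-positive probability "
                f"{probs[bad[0]]!r}; energies require strictly positive probabilities"
            )
        total = probs.sum()
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ValueError(
                f"probabilities sum to {total!r}, not 1 (tolerance 1e-12); "
                "pass normalize=True to from_probabilities to renormalize"
            )

    @classmethod
    def from_counts(
        cls, counts: Mapping[Hashable, int] | pd.Series
    ) -> "EmpiricalDistribution":
        """Maximum-likelihood distribution from non-negative integer counts.

        Zero-count states are dropped; no pseudocounts are applied.
        """
        if isinstance(counts, pd.Series):
            items = list(counts.items())
        else:
            items = list(counts.items())
        kept = [(s, int(c)) for s, c in items if c != 0]
        if any(c < 0 for _, c in kept):
            raise ValueError("counts must be non-negative")
        if not kept:
            raise ValueError("empty distribution: all counts are zero")
        states = tuple(s for s, _ in kept)
        carr = np.array([c for _, c in kept], dtype=float)
        probs = carr / carr.sum()
        return cls(states, probs, counts=carr)

    @classmethod
    def from_probabilities(
        cls,
        probs: Mapping[Hashable, float],
        *,
        normalize: bool = False,
    ) -> "EmpiricalDistribution":
        states = tuple(probs.keys())
        parr = np.array([probs[s] for s in states], dtype=float)
        if normalize:
            parr = parr / parr.sum()
        return cls(states, parr)

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class EnergySpectrum:
    """Atoms ``(state, probability, energy)`` sorted ascending by energy.

    Energies are in nats: ``energy = -log(probability)`` exactly, per atom.
    """

    states: tuple[Hashable, ...]
    probabilities: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("atoms must be sorted ascending by energy")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class ZipfCurve:
    """Per-atom rank/probability/energy with the max-tie rank convention.

    ``rank`` of an atom is the number of atoms with energy <= its energy, so
    tied atoms share the largest rank of their tie group and the maximum rank
    equals the number of atoms.
    """

    states: tuple[Hashable, ...]
    probabilities: np.ndarray
    energies: np.ndarray
    ranks: np.ndarray
    tie_convention: str = "max"

    def __len__(self) -> int:
        return len(self.states)

    def to_frame(self, counts: np.ndarray | None = None) -> pd.DataFrame:
        """Tabular export: state, probability, energy (nats), rank, log10 rank."""
        df = pd.DataFrame(
            {
                "state": list(self.states),
                "probability": self.probabilities,
                "energy_nats": self.energies,
                "rank": self.ranks,
                "log10_rank": np.log10(self.ranks),
            }
        )
        if counts is not None:
            df.insert(1, "count", counts)
        return df


@dataclass(frozen=True)
class SmoothedEnergyDensity:
    """Values of the exponentially smoothed energy density on a grid.

    For a discrete spectrum, ``P_S(E) = e^{-E} * #{atoms with energy <= E}``.
    """

    energies: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"energy_nats": self.energies, "P_S": self.values})


def build_spectrum(dist: EmpiricalDistribution) -> EnergySpectrum:
    """Energy spectrum of a distribution: one atom per state, sorted ascending.

    Energy is the negative natural log of the state's probability.
    """
    energies = -np.log(dist.probabilities)
    order = np.argsort(energies, kind="stable")
    return EnergySpectrum(
        states=tuple(dist.states[i] for i in order),
        probabilities=dist.probabilities[order],
        energies=energies[order],
    )


def rank_curve(spec: EnergySpectrum) -> ZipfCurve:
    """Rank each atom by cumulative count of atoms at or below its energy.

    With ties, every tied atom receives the maximal rank of the tie group;
    this is the unique convention under which the rank-energy identity
    ``log r = E + log P_S`` is exact at the atoms.
    """
    ranks = np.searchsorted(spec.energies, spec.energies, side="right")
    return ZipfCurve(
        states=spec.states,
        probabilities=spec.probabilities,
        energies=spec.energies,
        ranks=ranks.astype(np.int64),
    )


def smoothed_density(
    spec: EnergySpectrum, eval_points: Sequence[float] | np.ndarray
) -> SmoothedEnergyDensity:
    """Smoothed energy density ``P_S`` of a discrete spectrum at given energies.

    ``P_S(E)`` is the energy distribution convolved with a one-sided
    exponential kernel; for a sum of probability-weighted delta functions this
    collapses to ``e^{-E}`` times the number of atoms with energy <= E, which
    is how it is evaluated here (exactly zero below the minimum energy).
    """
    pts = np.asarray(eval_points, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("evaluation energies must be finite")
    counts = np.searchsorted(spec.energies, pts, side="right")
    values = counts * np.exp(-pts)
    return SmoothedEnergyDensity(energies=pts, values=values)


def zipf_identity_residual(spec: EnergySpectrum) -> np.ndarray:
    """Per-atom residual of the exact identity ``log r(E) - E - log P_S(E)``.

    Identically zero (to floating precision) for every discrete spectrum under
    the max-tie rank convention and the "<=" smoothing cumulative sum.
    """
    curve = rank_curve(spec)
    ps = smoothed_density(spec, spec.energies).values
    return np.log(curve.ranks) - spec.energies - np.log(ps)


def zipf_deviation(spec: EnergySpectrum) -> float:
    """Probability-weighted standard deviation of ``log P_S(E(x))`` over atoms.

    Zero iff ``log P_S`` is constant across the support, i.e. iff the
    distribution obeys Zipf's law exactly over its support; positive
    otherwise.  Invariant under relabeling of states.
    """
    if len(spec) < 2:
        raise ValueError("zipf_deviation requires at least 2 atoms")
    log_ps = np.log(smoothed_density(spec, spec.energies).values)
    w = spec.probabilities
    mean = np.sum(w * log_ps) / np.sum(w)
    var = np.sum(w * (log_ps - mean) ** 2) / np.sum(w)
    return float(np.sqrt(max(var, 0.0)))


def zipf_slope(
    curve: ZipfCurve,
    rank_range: tuple[float, float] | None = None,
) -> float:
    """Least-squares slope of ``log P`` against ``log rank`` over a rank window.

    Zipf's law corresponds to slope -1.  By default the window covers the
    geometric interior of the rank axis, ranks in ``[R^0.15, R^0.85]`` with
    ``R`` the maximum rank, which excludes the head (few atoms, heavy
    discreteness) and the sampling-noise-dominated tail.  Tied atoms collapse
    to a single (rank, probability) point so that long plateaus of equiprobable
    states are not over-weighted.
    """
    ranks = np.asarray(curve.ranks, dtype=float)
    probs = np.asarray(curve.probabilities, dtype=float)
    if rank_range is None:
        rmax = ranks.max()
        rank_range = (rmax ** 0.15, rmax ** 0.85)
    lo, hi = rank_range
    # one point per distinct rank (ties share a rank and a probability)
    uniq, idx = np.unique(ranks, return_index=True)
    r, p = uniq, probs[idx]
    sel = (r >= lo) & (r <= hi)
    if sel.sum() < 2:
        raise ValueError("rank window contains fewer than 2 distinct ranks")
    x, y = np.log(r[sel]), np.log(p[sel])
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)
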