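"""The proportion of explained energy variance (PEEV) for categorical latents.

Given observations that each fall into a single known category z, the law of
total variance splits the variance of the energy E(x) = -log P(x) into a
between-category part (variance of the conditional mean energy over z) and a
within-category part (mean conditional energy variance)::

    Var_x[E] = Var_z[ E_{x|z}[E] ] + E_z[ Var_{x|z}[E] ]

PEEV is the between-category share of that total.  A value near 1 means the
latent variable controls the mean energy -- the broadening mechanism by which
mixing narrow conditional energy distributions produces Zipf's law; a value
near 0 means the latent variable explains none of the energy spread.

Energies are always computed from the *marginal* distribution P(x); the
conditional distributions P(x|z) only reweight those same energies.  Using
-log P(x|z) as the energy would be a different (and incorrect) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .spectrum import EmpiricalDistribution, EnergySpectrum, build_spectrum

__all__ = [
    "CategoricalLatentDataset",
    "PEEVDecomposition",
    "ConditionalSpectrum",
    "conditional_energy_moments",
    "decompose_energy_variance",
    "peev",
    "conditional_spectra",
]


@dataclass(frozen=True)
class CategoricalLatentDataset:
    """Items with positive integer counts and one category label each.

    Induces P(z) (category count shares), P(x|z) (within-category
    frequencies) and P(x) (overall frequencies).  Constructed from a
    three-column table of (item, count, category).
    """

    items: pd.DataFrame  # columns: item, count, category

    def __post_init__(self) -> None:
        df = self.items
        required = {"item", "count", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"items table must have columns {sorted(required)}")
        if len(df) == 0:
            raise ValueError("empty dataset")
        if (df["count"] <= 0).any():
            bad = df.loc[df["count"] <= 0, "item"].iloc[0]
            raise ValueError(f"item {bad!r} has non-positive count")
        if df["item"].duplicated().any():
            dup = df.loc[df["item"].duplicated(), "item"].iloc[0]
            raise ValueError(
                f"item {dup!r} appears under multiple rows; each item must carry "
                "exactly one category (use split_duplicates when reading files)"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[Hashable, int, Hashable]]
    ) -> "CategoricalLatentDataset":
        df = pd.DataFrame(records, columns=["item", "count", "category"])
        return cls(df)

    @property
    def n_states(self) -> int:
        return len(self.items)

    @property
    def n_categories(self) -> int:
        return self.items["category"].nunique()

    @property
    def total_count(self) -> float:
        return float(self.items["count"].sum())

    def marginal(self) -> EmpiricalDistribution:
        """P(x): maximum-likelihood frequencies over all items."""
        return EmpiricalDistribution.from_counts(
            dict(zip(self.items["item"], self.items["count"]))
        )

    def category_probabilities(self) -> pd.Series:
        """P(z): category count shares, indexed by category."""
        by_cat = self.items.groupby("category", sort=False)["count"].sum()
        return by_cat / by_cat.sum()

    def energies(self) -> np.ndarray:
        """E(x) = -log P(x) from the marginal, aligned with the items table."""
        p = self.items["count"].to_numpy(dtype=float) / self.total_count
        return -np.log(p)


@dataclass(frozen=True)
class PEEVDecomposition:
    """Law-of-total-variance decomposition of the energy, all in nats^2."""

    total_var: float
    between_var: float
    within_var: float
    peev: float
    n_categories: int
    n_states: int

    def to_dict(self) -> dict:
        return {
            "total_var": self.total_var,
            "between_var": self.between_var,
            "within_var": self.within_var,
            "peev": self.peev,
            "n_categories": self.n_categories,
            "n_states": self.n_states,
        }


@dataclass(frozen=True)
class ConditionalSpectrum:
    """Atoms of P(E|z): the marginal energies reweighted by P(x|z)."""

    category: Hashable
    states: tuple[Hashable, ...]
    weights: np.ndarray  # P(x|z), sums to 1
    energies: np.ndarray  # from the marginal P(x)


def _per_category(ds: CategoricalLatentDataset):
    """Yield (category, P(z), P(x|z) weights, energies) per category."""
    energies = ds.energies()
    counts = ds.items["count"].to_numpy(dtype=float)
    total = counts.sum()
    for cat, idx in ds.items.groupby("category", sort=False).indices.items():
        c = counts[idx]
        yield cat, c.sum() / total, c / c.sum(), energies[idx], idx


def conditional_energy_moments(
    ds: CategoricalLatentDataset, order: int = 1
) -> tuple[pd.Series, float]:
    """Per-category conditional energy moments and the overall moment.

    Returns ``(per_category, overall)`` where ``per_category[z]`` is
    ``sum_x P(x|z) E(x)^k`` with energies from the marginal P(x), and
    ``overall = sum_x P(x) E(x)^k``.  Mixing the conditional moments with
    P(z) recovers the overall moment exactly.
    """
    if order < 0:
        raise ValueError("moment order must be non-negative")
    energies = ds.energies()
    p = ds.items["count"].to_numpy(dtype=float) / ds.total_count
    overall = float(np.sum(p * energies**order))
    cats, vals = [], []
    for cat, _, w, e, _ in _per_category(ds):
        cats.append(cat)
        vals.append(float(np.sum(w * e**order)))
    return pd.Series(vals, index=pd.Index(cats, name="category")), overall


def decompose_energy_variance(
    probabilities: np.ndarray,
    energies: np.ndarray,
    categories: np.ndarray | Sequence[Hashable],
) -> PEEVDecomposition:
    """Law-of-total-variance split of given energies under given weights.

    ``probabilities`` must be the marginal P(x) over states (summing to 1),
    ``energies`` the per-state energies (normally -log P(x), but any
    externally supplied energy -- e.g. from a model's exact marginal -- is
    accepted), and ``categories`` the per-state latent labels.  Raises on a
    degenerate (zero-variance) energy distribution, for which PEEV is
    undefined.
    """
    p = np.asarray(probabilities, dtype=float)
    e = np.asarray(energies, dtype=float)
    cats = np.asarray(categories)
    if not (p.shape == e.shape == cats.shape):
        raise ValueError("probabilities, energies and categories must align")
    mean_e = float(np.sum(p * e))
    total_var = float(np.sum(p * (e - mean_e) ** 2))
    if total_var <= 0.0 or np.ptp(e) == 0.0:
        raise ValueError(
            "degenerate energy distribution: total energy variance is zero, "
            "PEEV is undefined"
        )
    between = 0.0
    within = 0.0
    for cat in pd.unique(cats):
        idx = cats == cat
        pz = float(p[idx].sum())
        w = p[idx] / pz
        cond_mean = float(np.sum(w * e[idx]))
        cond_var = float(np.sum(w * (e[idx] - cond_mean) ** 2))
        between += pz * (cond_mean - mean_e) ** 2
        within += pz * cond_var
    value = between / total_var
    return PEEVDecomposition(
        total_var=total_var,
        between_var=between,
        within_var=within,
        peev=float(min(max(value, 0.0), 1.0)),
        n_categories=len(pd.unique(cats)),
        n_states=len(p),
    )


def peev(ds: CategoricalLatentDataset) -> PEEVDecomposition:
    """PEEV and the full energy-variance decomposition of a dataset.

    Plug-in estimate: probabilities are maximum-likelihood frequencies and no
    small-sample bias correction is applied.  Raises if the total energy
    variance is zero (every state equiprobable), in which case PEEV is
    undefined.
    """
    p = ds.items["count"].to_numpy(dtype=float) / ds.total_count
    return decompose_energy_variance(
        p, ds.energies(), ds.items["category"].to_numpy()
    )


def conditional_spectra(ds: CategoricalLatentDataset) -> list[ConditionalSpectrum]:
    """P(E|z) per category: marginal energies reweighted by P(x|z).

    Mixing the returned spectra with P(z) recovers the total energy
    distribution atom-by-atom.
    """
    out = []
    items = ds.items["item"].to_numpy()
    for cat, _, w, e, idx in _per_category(ds):
        order = np.argsort(e, kind="stable")
        out.append(
            ConditionalSpectrum(
                category=cat,
                states=tuple(items[idx][order]),
                weights=w[order],
                energies=e[order],
            )
        )
    return out


def per_category_report(ds: CategoricalLatentDataset) -> pd.DataFrame:
    """Conditional mean and variance of the energy per category, with P(z)."""
    rows = []
    for cat, pz, w, e, _ in _per_category(ds):
        m = float(np.sum(w * e))
        v = float(np.sum(w * (e - m) ** 2))
        rows.append({"category": cat, "p_z": pz, "mean_energy": m, "var_energy": v})
    return pd.DataFrame(rows)
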