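"""End-to-end spike-train analysis: samples -> conditional spectra -> PEEV.

Sampled binary population patterns carry a latent label (the trial-aligned
time bin that generated them).  For conditional energy distributions the
labels are grouped into blocks of consecutive bins (default 5, i.e. 100 ms
at 20 ms bins), so that each conditional spectrum pools enough samples to be
meaningful.

Pattern energies can come from two sources: the exact model marginal
``-log P(x)`` (default for simulated data, where the model is known), or the
empirical pattern frequencies.  Both are exposed because real data offers
only the second.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .models import BernoulliPopulationModel
from .peev import PEEVDecomposition, decompose_energy_variance
from .spectrum import (
    EmpiricalDistribution,
    EnergySpectrum,
    ZipfCurve,
    build_spectrum,
    rank_curve,
)

__all__ = [
    "group_latent_blocks",
    "pattern_table",
    "spike_energy_decomposition",
    "empirical_zipf_curve",
]


def group_latent_blocks(latent: np.ndarray, block_bins: int = 5) -> np.ndarray:
    """Map per-sample time-bin labels to block labels of ``block_bins`` bins."""
    if block_bins < 1:
        raise ValueError("block_bins must be >= 1")
    return np.asarray(latent) // block_bins


def pattern_table(
    x: np.ndarray, latent: np.ndarray, block_bins: int = 5
) -> pd.DataFrame:
    """Count unique (pattern, latent-block) pairs.

    Returns a table with columns ``pattern`` (bytes key), ``count``,
    ``category`` (block label) and the decoded binary row in ``bits``.
    A pattern observed in several blocks contributes one state per block --
    the conditional distributions P(x|z) reweight the same pattern energies.
    """
    x = np.asarray(x, dtype=np.int8)
    blocks = group_latent_blocks(latent, block_bins)
    keys = [(row.tobytes(), int(b)) for row, b in zip(x, blocks)]
    counts = Counter(keys)
    rows = []
    for (key, block), c in counts.items():
        rows.append(
            {
                "pattern": key,
                "category": block,
                "count": c,
                "bits": np.frombuffer(key, dtype=np.int8),
            }
        )
    return pd.DataFrame(rows)


def spike_energy_decomposition(
    x: np.ndarray,
    latent: np.ndarray,
    model: BernoulliPopulationModel | None = None,
    block_bins: int = 5,
    energy_source: str = "model",
) -> PEEVDecomposition:
    """PEEV of sampled population patterns with latent-block categories.

    ``energy_source='model'`` uses the exact marginal ``-log P(x)`` from the
    generating model (which must then be supplied); ``'empirical'`` uses
    ``-log`` of the observed pattern frequency.  Weights P(x, z) are always
    the empirical (pattern, block) frequencies.
    """
    table = pattern_table(x, latent, block_bins)
    p = table["count"].to_numpy(dtype=float)
    p /= p.sum()
    if energy_source == "model":
        if model is None:
            raise ValueError("energy_source='model' requires the generating model")
        patterns = np.stack(table["bits"].to_numpy())
        energies = -model.marginal_logprob_many(patterns)
    elif energy_source == "empirical":
        # frequency of the pattern across all blocks
        freq = table.groupby("pattern")["count"].transform("sum").to_numpy(float)
        energies = -np.log(freq / table["count"].sum())
    else:
        raise ValueError("energy_source must be 'model' or 'empirical'")
    return decompose_energy_variance(p, energies, table["category"].to_numpy())


def empirical_zipf_curve(samples: list | np.ndarray) -> ZipfCurve:
    """Zipf curve from raw samples (any hashable items, e.g. sampled words)."""
    if isinstance(samples, np.ndarray) and samples.ndim == 2:
        samples = [row.tobytes() for row in np.ascontiguousarray(samples)]
    counts = Counter(samples)
    dist = EmpiricalDistribution.from_counts(counts)
    return rank_curve(build_spectrum(dist))
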