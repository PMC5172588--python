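"""Readers and writers for word tables, FASTA sequence sets, and spike rasters.

Canonical formats, all plain text:

* word tables -- TSV with a header row naming columns ``word``, ``count``,
  ``pos`` (a column-mapping argument accommodates other layouts);
* variable-length sequence sets -- FASTA, with sequence length as the
  (deterministic) latent category;
* spike rasters -- TSV of 0/1 entries, one row per time bin and one column
  per neuron, with trial structure given by a fixed trial length in bins and
  an optional leading latent-label column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import BernoulliPopulationModel
from .peev import CategoricalLatentDataset, PEEVDecomposition

__all__ = [
    "SpikeRaster",
    "read_word_table",
    "write_word_table",
    "read_fasta_lengths",
    "write_fasta",
    "read_spike_raster",
    "write_spike_raster",
    "estimate_rates",
    "write_peev_report",
]


# ---------------------------------------------------------------------------
# Word tables (categorical data)
# ---------------------------------------------------------------------------


def read_word_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    split_duplicates: bool = False,
) -> CategoricalLatentDataset:
    """Read a (word, count, part-of-speech) TSV into a categorical dataset.

    ``columns`` maps canonical names {"word", "count", "pos"} to the file's
    column names.  A word listed under two different parts of speech is
    rejected unless ``split_duplicates`` is set, in which case its counts are
    kept under distinct (word, pos) states.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty word table") from None
    colmap = {"word": "word", "count": "count", "pos": "pos"}
    if columns:
        colmap.update(columns)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[
        ["word", "count", "pos"]
    ]
    bad = df.index[df["count"].isna() | (pd.to_numeric(df["count"], errors="coerce").isna())]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed count at line {bad[0] + 2}")
    df["count"] = df["count"].astype(np.int64)
    dup = df["word"].duplicated(keep=False)
    if dup.any():
        conflicting = df.loc[dup].groupby("word")["pos"].nunique()
        if (conflicting > 1).any() and not split_duplicates:
            w = conflicting.index[conflicting > 1][0]
            raise ValueError(
                f"{path}: word {w!r} appears under multiple parts of speech; "
                "pass split_duplicates=True to keep them as distinct states"
            )
        if split_duplicates:
            df["word"] = df["word"] + "/" + df["pos"].astype(str)
        df = df.groupby(["word", "pos"], sort=False, as_index=False)["count"].sum()
    df = df.rename(columns={"word": "item", "pos": "category"})
    return CategoricalLatentDataset(df[["item", "count", "category"]])


def write_word_table(ds: CategoricalLatentDataset, path: str | Path) -> None:
    """Write a categorical dataset back to the canonical 3-column TSV."""
    out = ds.items.rename(columns={"item": "word", "category": "pos"})
    out[["word", "count", "pos"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA (sequence-length latent)
# ---------------------------------------------------------------------------


def read_fasta_lengths(path: str | Path) -> CategoricalLatentDataset:
    """Aggregate a FASTA file into (sequence, count, length) states.

    Identical sequences are merged into a single state with a summed count;
    the category of each state is its integer sequence length, the
    deterministic latent variable for variable-length data.
    """
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if not s:
            raise ValueError(f"{path}: empty sequence record {rec.id!r}")
        counts[s] = counts.get(s, 0) + 1
    if not counts:
        raise ValueError(f"{path}: no FASTA records found")
    records = [(seq, c, len(seq)) for seq, c in counts.items()]
    return CategoricalLatentDataset.from_records(records)


def write_fasta(sequences: list[str], path: str | Path) -> None:
    """Write sequences to FASTA with sequential record ids."""
    records = [
        SeqRecord(Seq(s), id=f"seq{i}", description="") for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Spike rasters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeRaster:
    """Binary spike matrix: rows are time bins, columns are neurons.

    Rows are ordered trial by trial; ``trial_length`` bins per trial, so the
    row count equals ``n_trials * trial_length``.  ``bin_ms`` records the bin
    width.  ``latent`` optionally carries a per-row latent label (the
    trial-aligned bin index, by construction of the generators).
    """

    matrix: np.ndarray
    trial_length: int
    bin_ms: float = 20.0
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise ValueError("raster must be a 2-D matrix")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        if m.shape[0] % self.trial_length != 0:
            raise ValueError(
                f"{m.shape[0]} rows is not a multiple of trial length "
                f"{self.trial_length}"
            )
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0] // self.trial_length

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[1]

    def by_trial(self) -> np.ndarray:
        """Reshape to (n_trials, trial_length, n_neurons)."""
        return self.matrix.reshape(self.n_trials, self.trial_length, self.n_neurons)


def read_spike_raster(
    path: str | Path, trial_length: int, bin_ms: float = 20.0
) -> SpikeRaster:
    """Read a 0/1 TSV raster; a leading ``latent`` column is used if present."""
    df = pd.read_csv(path, sep="\t")
    latent = None
    if "latent" in df.columns:
        latent = df["latent"].to_numpy()
        df = df.drop(columns=["latent"])
    m = df.to_numpy()
    if not np.isin(m, (0, 1)).all():
        raise ValueError(f"{path}: raster contains non-binary entries")
    return SpikeRaster(matrix=m, trial_length=trial_length, bin_ms=bin_ms, latent=latent)


def write_spike_raster(raster: SpikeRaster, path: str | Path) -> None:
    df = pd.DataFrame(
        raster.matrix, columns=[f"n{i}" for i in range(raster.n_neurons)]
    )
    if raster.latent is not None:
        df.insert(0, "latent", raster.latent)
    df.to_csv(path, sep="\t", index=False)


def estimate_rates(
    raster: SpikeRaster, rate_floor: float | None = None
) -> BernoulliPopulationModel:
    """Per-bin maximum-likelihood firing rates p_i(z) across trials.

    ``p_i(z)`` is the fraction of trials in which neuron i spiked in
    trial-aligned bin z.  Rates are clipped into
    ``[floor, 1 - floor]`` with ``floor = 1/(2 * n_trials)`` by default, so
    that silent (or saturated) neurons keep finite energies.
    """
    trials = raster.by_trial().astype(float)
    if rate_floor is None:
        rate_floor = 1.0 / (2.0 * raster.n_trials)
    rates = trials.mean(axis=0)  # (trial_length, n_neurons)
    rates = np.clip(rates, rate_floor, 1.0 - rate_floor)
    return BernoulliPopulationModel(rates=rates)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_peev_report(decomp: PEEVDecomposition, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(decomp.to_dict(), fh, indent=2)
        fh.write("\n")
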