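"""Tabular IO and post-denoising preprocessing for SV count data.

Readers validate hard (duplicated ids, negative or non-integer counts,
orphan samples are errors naming the offending cell); the filters mirror a
standard amplicon workflow: SV length filter, negative-control SV removal,
taxonomy back-fill from the deepest assigned rank, conversion to relative
abundance, rank agglomeration, and per-individual averaging ("average
microbiome").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RANKS

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "individual_id", "band", "life_stage", "sex", "mother_id", "role", "day",
]
SIGHTING_COLUMNS = ["day", "individual_a", "individual_b", "category"]
SIGHTING_CATEGORIES = {"close", "medium", "far", "seen"}


@dataclass
class CountTable:
    """Samples x SVs non-negative integer counts, with optional SV lengths."""

    data: pd.DataFrame
    sv_lengths: pd.Series | None = None

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicated SV ids: {dups}")
        arr = self.data.to_numpy()
        if (arr < 0).any():
            s, v = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {self.data.index[s]!r}, SV {self.data.columns[v]!r}"
            )
        if self.sv_lengths is not None:
            self.sv_lengths = self.sv_lengths.reindex(self.data.columns)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def sv_ids(self) -> list:
        return list(self.data.columns)

    def copy_with(self, data: pd.DataFrame) -> "CountTable":
        lengths = None
        if self.sv_lengths is not None:
            lengths = self.sv_lengths.reindex(data.columns)
        return CountTable(data=data, sv_lengths=lengths)


@dataclass
class FilterReport:
    """Bookkeeping for an SV-removal step."""

    n_svs_removed: int
    n_svs_total: int
    fraction_of_sequences: float  # share of total reads carried by removed SVs
    fraction_of_svs: float

    def __str__(self) -> str:
        return (
            f"removed {self.n_svs_removed}/{self.n_svs_total} SVs; "
            f"{100 * self.fraction_of_sequences:.3f}% of total sequences; "
            f"{100 * self.fraction_of_svs:.3f}% of SVs"
        )


def _read_tsv(path, index_col):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing required column {index_col!r}")
    return df.set_index(index_col)


def read_counts(path) -> CountTable:
    df = _read_tsv(path, "sample_id")
    for col in df.columns:
        try:
            df[col] = df[col].astype(np.int64)
        except ValueError:
            bad = df.index[~df[col].str.fullmatch(r"-?\d+")][0]
            raise ValueError(
                f"non-integer count at sample {bad!r}, SV {col!r}"
            ) from None
    return CountTable(data=df)


def read_taxonomy(path) -> tuple:
    """Returns (taxonomy DataFrame over the 7 ranks, optional length Series)."""
    df = _read_tsv(path, "sv_id")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing taxonomy ranks {missing}")
    lengths = None
    if "length" in df.columns:
        lengths = df["length"].astype(int)
        lengths.name = "length"
    return df[RANKS].copy(), lengths


def read_metadata(path) -> pd.DataFrame:
    df = _read_tsv(path, "sample_id")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    df = df[METADATA_COLUMNS].copy()
    df["day"] = df["day"].astype(int)
    return df


def read_sightings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SIGHTING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sighting columns {missing}")
    df = df[SIGHTING_COLUMNS].copy()
    df["day"] = df["day"].astype(int)
    bad = set(df["category"]) - SIGHTING_CATEGORIES
    if bad:
        raise ValueError(f"{path}: unknown sighting categories {sorted(bad)}")
    return df


def read_tables(directory) -> tuple:
    """Read and cross-validate a fixture directory.

    Returns (CountTable, taxonomy, metadata, sightings).  Metadata must
    cover every count-table sample; taxonomy must cover every SV.
    """
    directory = Path(directory)
    table = read_counts(directory / "counts.tsv")
    taxonomy, lengths = read_taxonomy(directory / "taxonomy.tsv")
    if lengths is not None:
        table = CountTable(data=table.data, sv_lengths=lengths)
    metadata = read_metadata(directory / "metadata.tsv")
    sightings = read_sightings(directory / "sightings.csv")
    orphans = sorted(set(table.sample_ids) - set(metadata.index))
    if orphans:
        raise ValueError(f"samples missing from metadata: {orphans}")
    no_tax = sorted(set(table.sv_ids) - set(taxonomy.index))
    if no_tax:
        raise ValueError(f"SVs missing from taxonomy: {no_tax}")
    logger.info(
        "read %d samples x %d SVs, %d metadata rows, %d sighting rows",
        len(table.sample_ids), len(table.sv_ids), len(metadata), len(sightings),
    )
    return table, taxonomy, metadata, sightings


def filter_sv_length(table: CountTable, max_len: int = 260) -> tuple:
    """Drop SVs longer than ``max_len`` bp (strictly greater).

    Returns (filtered table, FilterReport).  The report carries the removed
    share both of total sequences (reads) and of SVs.
    """
    if table.sv_lengths is None:
        raise ValueError(
            "SV lengths unavailable; skip the length filter explicitly if lengths "
            "were not recorded"
        )
    keep = table.sv_lengths <= max_len
    removed = (~keep).sum()
    total_reads = table.data.to_numpy().sum()
    removed_reads = table.data.loc[:, ~keep].to_numpy().sum()
    report = FilterReport(
        n_svs_removed=int(removed),
        n_svs_total=table.data.shape[1],
        fraction_of_sequences=removed_reads / total_reads if total_reads else 0.0,
        fraction_of_svs=removed / table.data.shape[1],
    )
    logger.info("length filter (> %d bp): %s", max_len, report)
    return table.copy_with(table.data.loc[:, keep]), report


def remove_control_svs(table: CountTable, control_sample_ids) -> tuple:
    """Remove every SV detected in any negative control, then drop controls.

    Any nonzero control count flags an SV as a contaminant.
    """
    control_sample_ids = list(control_sample_ids)
    unknown = sorted(set(control_sample_ids) - set(table.sample_ids))
    if unknown:
        raise ValueError(f"unknown control sample ids: {unknown}")
    controls = table.data.loc[control_sample_ids]
    contaminants = controls.columns[(controls > 0).any(axis=0)]
    data = table.data.drop(index=control_sample_ids, columns=contaminants)
    report = FilterReport(
        n_svs_removed=len(contaminants),
        n_svs_total=table.data.shape[1],
        fraction_of_sequences=(
            table.data[contaminants].to_numpy().sum() / table.data.to_numpy().sum()
            if table.data.to_numpy().sum() else 0.0
        ),
        fraction_of_svs=len(contaminants) / table.data.shape[1],
    )
    logger.info("control filter: %s", report)
    return table.copy_with(data), report


def backfill_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    """Fill missing ranks from the deepest known assignment.

    A missing Genus under Family "Prevotellaceae" becomes
    "Family_Prevotellaceae" at genus and species level, so rank
    agglomeration never silently drops unassigned SVs.  SVs with no
    assignment at any rank are labelled "Unassigned" throughout (logged).
    Idempotent.
    """
    out = tax.copy()
    filled = out.mask(out == "")
    unassigned = filled[RANKS].isna().all(axis=1)
    if unassigned.any():
        logger.warning(
            "%d SVs with no assignment at any rank labelled 'Unassigned'",
            int(unassigned.sum()),
        )
        out.loc[unassigned, RANKS] = "Unassigned"
        filled = out.mask(out == "")
    for sv in out.index[~unassigned]:
        deepest_rank, deepest_label = None, None
        for rank in RANKS:
            val = filled.at[sv, rank]
            if isinstance(val, str) and val:
                deepest_rank, deepest_label = rank, val
            else:
                if deepest_rank is None:
                    raise ValueError(f"SV {sv!r} missing {rank} with no higher assignment")
                out.at[sv, rank] = f"{deepest_rank}_{deepest_label}"
    return out


def to_relative_abundance(table) -> pd.DataFrame:
    """Divide each sample's counts by its total; rows sum to 1.

    Accepts a CountTable or a (possibly real-valued) DataFrame, e.g. the
    per-individual averaged table.
    """
    data = table.data if isinstance(table, CountTable) else table
    totals = data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    return data.div(totals, axis=0)


def agglomerate(rel: pd.DataFrame, tax: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum columns sharing the taxonomy label at ``rank``; row sums preserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    missing = sorted(set(rel.columns) - set(tax.index))
    if missing:
        raise ValueError(f"SVs absent from taxonomy: {missing}")
    labels = tax.loc[rel.columns, rank]
    if labels.isna().any() or (labels == "").any():
        raise ValueError(f"taxonomy not back-filled at rank {rank!r}")
    out = rel.T.groupby(labels.values, sort=True).sum().T
    out.columns.name = rank
    return out


def merge_by_individual(table, metadata: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of raw sample counts per individual (real-valued).

    The per-individual "average microbiome"; convert with
    :func:`to_relative_abundance` before computing distances.
    """
    data = table.data if isinstance(table, CountTable) else table
    missing = sorted(set(data.index) - set(metadata.index))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    groups = metadata.loc[data.index, "individual_id"]
    merged = data.groupby(groups.values, sort=True).mean()
    merged.index.name = "individual_id"
    return merged
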