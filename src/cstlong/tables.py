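"""Count-table I/O, relative-abundance conversion, and the prevalence filter.

The central container is :class:`CountTable`: a samples x phylotypes matrix of
nonnegative integer read counts plus per-sample metadata (subject id, study
group, week of sampling and an optional Nugent score).  Downstream analyses
operate either on the raw counts (count-model regression, with the log total
reads as offset) or on the row-normalised relative abundances ("community
states").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "read_count_table", "to_relative_abundance", "prevalence_filter"]

GROUPS = ("non_pregnant", "pregnant")

METADATA_COLUMNS = ["sample_id", "subject_id", "group", "week", "nugent"]


@dataclass
class CountTable:
    """Samples x taxa integer read counts with per-sample metadata.

    ``counts`` is a DataFrame indexed by sample_id with taxon names as
    columns; ``metadata`` is indexed by sample_id with columns subject_id,
    group, week and (optionally) nugent.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.copy()
        self.metadata = self.metadata.copy()
        self.counts.index = self.counts.index.astype(str).rename("sample_id")
        self.metadata.index = self.metadata.index.astype(str).rename("sample_id")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)][0]
            raise ValueError(f"negative count in sample {bad!r}")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing sample_id {missing[0]!r}")
        self.metadata = self.metadata.loc[self.counts.index]
        for col in ("subject_id", "group", "week"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad_groups = set(self.metadata["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def totals(self) -> pd.Series:
        """Total reads per sample (the count-model offset is log of this)."""
        return self.counts.sum(axis=1)

    def drop_empty_samples(self) -> "CountTable":
        """Drop samples with zero total reads, warning about each."""
        totals = self.totals
        empty = totals.index[totals == 0]
        if len(empty):
            warnings.warn(f"dropping {len(empty)} sample(s) with zero total reads: "
                          f"{list(empty[:5])}", stacklevel=2)
            keep = totals.index[totals > 0]
            return CountTable(self.counts.loc[keep], self.metadata.loc[keep])
        return self

    def select_taxa(self, taxa) -> "CountTable":
        return CountTable(self.counts[list(taxa)], self.metadata)

    # -- I/O -------------------------------------------------------------
    def write(self, counts_path, metadata_path) -> None:
        """Write counts and metadata as TSV (taxa as columns)."""
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_count_table(path, metadata_path, drop_empty: bool = True) -> CountTable:
    """Read a TSV count matrix (samples x taxa) and its sample metadata TSV.

    Samples with zero total reads are dropped with a warning.  Raises a
    ``ValueError`` naming the offending sample on metadata/count mismatches
    or negative counts.
    """
    counts = pd.read_csv(path, sep="\t", index_col="sample_id")
    try:
        counts = counts.astype(np.int64)
    except ValueError as exc:
        raise ValueError(f"count table {path} has non-integer entries: {exc}") from exc
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    table = CountTable(counts, metadata)
    return table.drop_empty_samples() if drop_empty else table


def to_relative_abundance(table: CountTable) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (community states).

    Returns a DataFrame of proportions; every row sums to 1.  Raises on any
    zero-total sample (drop them first).
    """
    totals = table.totals
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")
    return table.counts.div(totals, axis=0)


def prevalence_filter(table: CountTable, threshold: float = 0.25) -> list[str]:
    """Taxa present (count >= 1) in at least ``threshold`` of all samples.

    The boundary is inclusive: a taxon seen in exactly 25% of samples passes
    the default filter.  Samples are pooled across groups.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if table.n_samples == 0:
        raise ValueError("empty table")
    prevalence = (table.counts >= 1).mean(axis=0)
    return [t for t in table.taxon_names if prevalence[t] >= threshold]
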