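"""Sample x taxon count tables and group-level summaries.

The count table is the pipeline's central object: one row per animal
(sample), one column per OTU (reads sharing an identical taxonomy
string), integer counts, and a group label per sample.  Everything
downstream — prevalence filtering, the two-part test, CLR-PCA, the
random forest — consumes per-sample *relative* abundances derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonCountTable",
    "relative_abundance",
    "prevalence",
    "prevalence_filter",
    "group_summary",
    "read_count_table",
    "read_metadata",
]


@dataclass
class TaxonCountTable:
    """Integer count matrix (samples x taxa) with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are taxonomy strings,
        values non-negative integers.
    groups
        Mapping or Series sample id -> group label, covering every sample.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        if isinstance(self.groups, Mapping):
            self.groups = pd.Series(self.groups)
        self.groups = self.groups.reindex(self.counts.index)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxa in count table")
        if self.groups.isna().any():
            missing = list(self.groups.index[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_samples(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise KeyError(f"unknown group: {group!r}")
        return list(self.groups.index[self.groups == group])

    def subset_groups(self, groups: Sequence[str]) -> "TaxonCountTable":
        keep = self.groups.isin(list(groups))
        return TaxonCountTable(self.counts.loc[keep], self.groups[keep])

    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        if metadata_path is not None:
            self.groups.rename("group").to_csv(
                metadata_path, sep="\t", index_label="sample_id"
            )


def read_count_table(counts_path: str | Path, metadata_path: str | Path) -> TaxonCountTable:
    """Load a count-table TSV and its sample metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    groups = read_metadata(metadata_path)
    missing = [s for s in counts.index if s not in groups.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return TaxonCountTable(counts, groups.loc[counts.index])


def read_metadata(metadata_path: str | Path) -> pd.Series:
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    if "group" not in meta.columns:
        raise ValueError("metadata TSV needs columns: sample_id, group")
    return meta["group"]


def relative_abundance(table: TaxonCountTable) -> pd.DataFrame:
    """Per-sample proportions: counts divided by the sample's row total.

    Relative abundance is computed per sample before any pooling; group
    values reported elsewhere are summaries of these per-animal values.
    """
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample row(s): {list(zero)}")
    return table.counts.div(totals, axis=0)


def prevalence(table: TaxonCountTable, group: str) -> pd.Series:
    """Fraction of the group's samples in which each taxon has count > 0."""
    rows = table.group_samples(group)
    return (table.counts.loc[rows] > 0).mean(axis=0)


def prevalence_filter(
    table: TaxonCountTable, group_a: str, group_b: str, min_prop: float = 0.5
) -> list[str]:
    """Taxa present in at least ``min_prop`` of samples in either group.

    The comparison is inclusive: a taxon seen in exactly half of one
    group's animals is retained.
    """
    if group_a == group_b:
        raise ValueError("prevalence filter needs two distinct groups")
    prev_a = prevalence(table, group_a)
    prev_b = prevalence(table, group_b)
    keep = (prev_a >= min_prop) | (prev_b >= min_prop)
    return list(keep.index[keep])


def group_summary(table: TaxonCountTable) -> pd.DataFrame:
    """Per (group, taxon) summaries of per-sample relative abundances.

    Emits median, mean, proportion of samples positive, quartiles and
    1.5 x IQR whisker bounds (box-plot parity).  Medians of even-sized
    groups are the mean of the two central order statistics.
    """
    if table.counts.empty:
        raise ValueError("empty table")
    rel = relative_abundance(table)
    records = []
    for group in table.group_names:
        sub = rel.loc[table.group_samples(group)]
        pos = prevalence(table, group)
        q1 = sub.quantile(0.25)
        q3 = sub.quantile(0.75)
        iqr = q3 - q1
        for taxon in table.taxa:
            records.append(
                {
                    "group": group,
                    "taxon": taxon,
                    "median_relabund": float(sub[taxon].median()),
                    "mean_relabund": float(sub[taxon].mean()),
                    "prop_positive": float(pos[taxon]),
                    "q1": float(q1[taxon]),
                    "q3": float(q3[taxon]),
                    "whisker_low": float(q1[taxon] - 1.5 * iqr[taxon]),
                    "whisker_high": float(q3[taxon] + 1.5 * iqr[taxon]),
                }
            )
    return pd.DataFrame.from_records(records)
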