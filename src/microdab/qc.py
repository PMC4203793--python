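"""Read quality control: windowed trimming, filters, OTU aggregation.

Rules implemented:

* both sequence ends are trimmed over a moving window of 5 nucleotides
  until the window's average quality meets or exceeds 20;
* trimmed reads with more than 1 ambiguity, or shorter than 200 nt, are
  discarded;
* reads passing QC are grouped by identical taxonomy-assignment string
  into OTUs and counted per sample.

FASTQ qualities are decoded as Phred+33.  Demultiplexing, paired-end
assembly, chimera removal and classification happen upstream; this
module consumes single-end FASTQ plus a read-id -> taxonomy table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .tables import TaxonCountTable

__all__ = [
    "Read",
    "QCParams",
    "trim_read",
    "filter_read",
    "canonicalize_taxonomy",
    "build_taxon_table",
    "read_fastq",
    "read_taxonomy_tsv",
    "run_qc",
]

_UNAMBIGUOUS = frozenset("ACGTacgt")


@dataclass(frozen=True)
class Read:
    """One sequencing read with per-base Phred qualities."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases and quals differ in length")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class QCParams:
    window: int = 5
    min_mean_quality: float = 20.0
    max_ambiguities: int = 1
    min_length: int = 200
    trim_ends: str = "both"  # "both", "left", "right"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_ambiguities < 0:
            raise ValueError("max_ambiguities must be >= 0")
        if self.trim_ends not in ("both", "left", "right"):
            raise ValueError("trim_ends must be one of both/left/right")


def _trim_left(quals: tuple[int, ...], window: int, threshold: float) -> int:
    """Number of bases to drop from the left end.

    Repeatedly inspect the terminal window; while its mean quality is
    below the threshold drop the terminal base and re-inspect.  When
    fewer than ``window`` bases remain the whole remainder is the window.
    """
    start = 0
    n = len(quals)
    while start < n:
        win = quals[start : min(start + window, n)]
        if sum(win) / len(win) >= threshold:
            break
        start += 1
    return start


def trim_read(read: Read, params: QCParams = QCParams()) -> Read:
    """Quality-trim a read at both ends (5' pass, then 3' pass).

    Degenerate inputs (nothing passes) yield an empty read, which the
    length filter discards downstream.
    """
    quals = read.quals
    start, stop = 0, len(quals)
    if params.trim_ends in ("both", "left"):
        start = _trim_left(quals, params.window, params.min_mean_quality)
    if params.trim_ends in ("both", "right"):
        trimmed = _trim_left(quals[start:][::-1], params.window, params.min_mean_quality)
        stop = len(quals) - trimmed
    if stop < start:
        start, stop = 0, 0
    return replace(read, bases=read.bases[start:stop], quals=quals[start:stop])


def filter_read(read: Read, params: QCParams = QCParams()) -> tuple[bool, str]:
    """Keep/discard decision for a post-trim read.

    Returns ``(keep, reason)`` with reason in {"ambiguity", "length",
    "pass"}.  Any character outside ACGT (N and the IUPAC partial
    ambiguity codes, case-insensitive) counts as an ambiguity.  A read of
    exactly ``min_length`` is kept: the rule discards reads *shorter*
    than the threshold.
    """
    n_ambig = sum(1 for b in read.bases if b not in _UNAMBIGUOUS)
    if n_ambig > params.max_ambiguities:
        return False, "ambiguity"
    if len(read) < params.min_length:
        return False, "length"
    return True, "pass"


_WS_RUN = re.compile(r"\s+")


def canonicalize_taxonomy(taxonomy: str) -> str:
    """Strip flanking whitespace and collapse internal runs; case kept.

    OTU identity is the exact canonical string — assignments differing at
    any rank are distinct OTUs.
    """
    return _WS_RUN.sub(" ", taxonomy.strip())


def build_taxon_table(
    assignments: Iterable[tuple[str, str]],
    metadata: Mapping[str, str] | pd.Series,
) -> TaxonCountTable:
    """Aggregate QC-passing reads into a sample x taxon count table.

    ``assignments`` yields (sample_id, taxonomy_string) per kept read.
    Taxa are the union over all samples; absent combinations are zero.
    Metadata samples with no surviving reads are dropped (a sample with
    an all-zero row carries no compositional information).
    """
    groups = pd.Series(dict(metadata)) if not isinstance(metadata, pd.Series) else metadata
    tally: dict[str, dict[str, int]] = {}
    n = 0
    for sample_id, taxonomy in assignments:
        if sample_id not in groups.index:
            raise ValueError(f"read references unknown sample id: {sample_id!r}")
        taxon = canonicalize_taxonomy(taxonomy)
        row = tally.setdefault(sample_id, {})
        row[taxon] = row.get(taxon, 0) + 1
        n += 1
    if n == 0:
        raise ValueError("no QC-passing reads to tabulate")
    counts = pd.DataFrame.from_dict(tally, orient="index").fillna(0).astype(int)
    counts = counts.reindex(columns=sorted(counts.columns))
    counts = counts.loc[[s for s in groups.index if s in counts.index]]
    return TaxonCountTable(counts, groups.loc[counts.index])


def read_fastq(path: str | Path) -> Iterable[Read]:
    """Iterate Phred+33 FASTQ records as Read objects."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))


def read_taxonomy_tsv(path: str | Path) -> pd.Series:
    """Two-column TSV (read_id, taxonomy_string) -> Series."""
    tax = pd.read_csv(path, sep="\t", index_col=0, header=0)
    return tax.iloc[:, 0]


def run_qc(
    fastq_by_sample: Mapping[str, str | Path],
    taxonomy: pd.Series,
    metadata: Mapping[str, str] | pd.Series,
    params: QCParams = QCParams(),
) -> tuple[TaxonCountTable, pd.DataFrame]:
    """Trim, filter and tabulate a demultiplexed study.

    Parameters
    ----------
    fastq_by_sample
        Mapping sample id -> FASTQ path (one file per sample).
    taxonomy
        Series read id -> taxonomy string for every read.
    metadata
        Mapping sample id -> group label.

    Returns the count table plus a per-sample QC report (input, kept and
    per-reason discard counts).
    """
    assignments: list[tuple[str, str]] = []
    report_rows = []
    for sample_id, path in fastq_by_sample.items():
        n_in = n_kept = n_ambig = n_short = 0
        for read in read_fastq(path):
            n_in += 1
            trimmed = trim_read(read, params)
            keep, reason = filter_read(trimmed, params)
            if keep:
                n_kept += 1
                if read.id not in taxonomy.index:
                    raise ValueError(f"read {read.id!r} missing from taxonomy table")
                assignments.append((sample_id, str(taxonomy.loc[read.id])))
            elif reason == "ambiguity":
                n_ambig += 1
            else:
                n_short += 1
        report_rows.append(
            {
                "sample_id": sample_id,
                "reads_in": n_in,
                "reads_kept": n_kept,
                "discarded_ambiguity": n_ambig,
                "discarded_length": n_short,
            }
        )
    report = pd.DataFrame.from_records(report_rows).set_index("sample_id")
    table = build_taxon_table(assignments, metadata)
    return table, report
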