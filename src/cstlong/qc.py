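"""Read-level quality filtering for 16S rRNA pyrosequencing FASTQ files.

A read is kept iff it passes, in order:

1. length between ``min_len`` and ``max_len`` (inclusive; defaults 200-400 bp);
2. no ambiguous base calls (no N);
3. no homopolymeric run longer than ``max_homopolymer`` (default 8 bp);
4. mean Phred quality >= ``min_window_mean_q`` (default 25) within every
   sliding window of ``window`` bp (default 50, step 1; the trailing partial
   window is included).

Each rejected read is tallied under its *first* failing criterion.  Chimera
detection and denoising are separate, downstream concerns and are recorded
in the report as not applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReadRecord",
    "FilterCriteria",
    "FilterReport",
    "longest_homopolymer",
    "min_window_mean_quality",
    "passes_filter",
    "filter_reads",
    "filter_fastq",
]

CRITERIA = ("length", "ambiguous", "homopolymer", "window_quality")


@dataclass
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self):
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.sequence)} bases"
            )


@dataclass
class FilterCriteria:
    """Thresholds for the four read filters (defaults follow 454 16S QC practice)."""

    min_len: int = 200
    max_len: int = 400
    allow_ambiguous: bool = False
    max_homopolymer: int = 8
    window: int = 50
    min_window_mean_q: float = 25.0

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class FilterReport:
    """Per-criterion rejection tallies for one filtering run."""

    n_input: int = 0
    n_kept: int = 0
    rejected: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CRITERIA})
    not_applied: tuple[str, ...] = ("chimera_removal", "denoising")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("criterion\tcount\n")
            fh.write(f"input\t{self.n_input}\n")
            fh.write(f"kept\t{self.n_kept}\n")
            for crit in CRITERIA:
                fh.write(f"rejected_{crit}\t{self.rejected[crit]}\n")
            for step in self.not_applied:
                fh.write(f"{step}\tnot_applied\n")


def longest_homopolymer(sequence: str) -> int:
    """Length of the longest run of identical characters (0 for empty input)."""
    best = run = 0
    prev = None
    for base in sequence:
        run = run + 1 if base == prev else 1
        prev = base
        if run > best:
            best = run
    return best


def min_window_mean_quality(qualities, window: int) -> float:
    """Smallest mean quality over all step-1 windows of size ``window``.

    Reads shorter than ``window`` are scored with a single whole-read window.
    The trailing partial window (the last ``len % 1`` .. ``window-1`` bases)
    is included, matching the strictest reading of a sliding-window rule.
    """
    q = np.asarray(qualities, dtype=float)
    n = q.size
    if n == 0:
        raise ValueError("empty quality vector")
    if n <= window:
        return float(q.mean())
    csum = np.concatenate([[0.0], np.cumsum(q)])
    full = (csum[window:] - csum[:-window]) / window  # all complete windows
    # trailing partial windows: starts n-window+1 .. n-1
    tails = (csum[n] - csum[n - window + 1 : n]) / np.arange(window - 1, 0, -1)
    return float(min(full.min(), tails.min()))


def first_failing_criterion(read: ReadRecord, criteria: FilterCriteria) -> str | None:
    """Name of the first criterion the read fails, or None if it passes all."""
    n = len(read.sequence)
    if not criteria.min_len <= n <= criteria.max_len:
        return "length"
    if not criteria.allow_ambiguous and "N" in read.sequence.upper():
        return "ambiguous"
    if longest_homopolymer(read.sequence) > criteria.max_homopolymer:
        return "homopolymer"
    if min_window_mean_quality(read.qualities, criteria.window) < criteria.min_window_mean_q:
        return "window_quality"
    return None


def passes_filter(read: ReadRecord, criteria: FilterCriteria | None = None) -> bool:
    return first_failing_criterion(read, criteria or FilterCriteria()) is None


def filter_reads(
    reads: Iterable[ReadRecord],
    criteria: FilterCriteria | None = None,
    report: FilterReport | None = None,
) -> Iterator[ReadRecord]:
    """Yield the reads passing all criteria, tallying rejections in ``report``.

    The report (if supplied) is updated in place as the stream is consumed,
    counting each rejected read once under its first failing criterion.
    """
    criteria = criteria or FilterCriteria()
    for read in reads:
        if report is not None:
            report.n_input += 1
        fail = first_failing_criterion(read, criteria)
        if fail is None:
            if report is not None:
                report.n_kept += 1
            yield read
        elif report is not None:
            report.rejected[fail] += 1


# -- FASTQ plumbing (Sanger/Phred+33 encoding assumed) -------------------

def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse a FASTQ file into ReadRecords; raises on malformed records."""
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            yield ReadRecord(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ {path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            yield rec

    return SeqIO.write(_records(), str(path), "fastq")


def filter_fastq(in_path, out_path, report_path=None,
                 criteria: FilterCriteria | None = None) -> FilterReport:
    """Filter a FASTQ file end to end; returns (and optionally writes) the report."""
    report = FilterReport()
    kept = filter_reads(read_fastq(in_path), criteria, report)
    write_fastq(kept, out_path)
    if report_path is not None:
        report.to_tsv(report_path)
    return report
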