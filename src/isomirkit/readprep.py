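"""Read preparation: 3' adapter trimming, length filtering, histograms.

Small-RNA library reads carry the 3' sequencing adapter whenever the
cloned insert is shorter than the read length, so adapter removal is the
step that turns 50 nt raw reads into 18-25 nt miRNA-sized inserts.  The
trimmer searches the leftmost read position where the read suffix aligns
to a *prefix* of the adapter within a mismatch budget; everything from
that position on is truncated.  Trimmed length 0 (adapter-only reads)
and untrimmed full-length reads are both legitimate outcomes and show up
as the extreme modes of the post-trimming length distribution.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; ``sequence`` reflects any trimming applied."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length != sequence length for read {self.read_id!r}"
            )

    @property
    def trimmed_length(self) -> int:
        return len(self.sequence)


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate a (possibly gzipped) FASTQ file as ReadRecords."""
    with _open_maybe_gzip(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(title.split()[0], seq.upper().replace("U", "T"), qual)


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_maybe_gzip(path, "wt") as handle:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 5,
    max_err_rate: float = 0.1,
) -> ReadRecord:
    """Remove the 3' adapter from one read.

    Finds the leftmost position ``p`` such that ``read[p:]`` aligns to a
    prefix of ``adapter`` with at most ``floor(max_err_rate * overlap)``
    mismatches when the overlap is at least ``min_overlap``; shorter
    terminal overlaps must match an adapter prefix exactly.  The read is
    truncated to ``[0:p)`` (possibly to length 0); if no position
    qualifies the read is returned unchanged.  Bases are never edited,
    only removed, and the operation is idempotent.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = adapter.upper().replace("U", "T")
    seq = read.sequence
    n = len(seq)
    for p in range(n):
        overlap = n - p
        compare = min(overlap, len(adapter))
        mismatches = sum(
            1 for a, b in zip(seq[p : p + compare], adapter[:compare]) if a != b
        )
        if overlap >= min_overlap:
            if mismatches <= int(max_err_rate * overlap):
                return _truncate(read, p)
        elif mismatches == 0:
            # terminal overlap too short for the mismatch rule: demand an
            # exact adapter-prefix match (catches inserts 1-4 nt short of
            # the read length)
            return _truncate(read, p)
    return read


def _truncate(read: ReadRecord, p: int) -> ReadRecord:
    if p >= len(read.sequence):
        return read
    return replace(
        read,
        sequence=read.sequence[:p],
        quality=read.quality[:p] if read.quality is not None else None,
    )


def filter_reads(
    reads: Iterable[ReadRecord], min_len: int = 18
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Keep reads with trimmed length >= ``min_len``.

    Shorter inserts cannot be aligned reliably against 18+ nt references.
    Returns the kept reads and counts by outcome; kept + discarded always
    equals the input count.
    """
    kept: list[ReadRecord] = []
    stats = {"input": 0, "kept": 0, "too_short": 0}
    for r in reads:
        stats["input"] += 1
        if r.trimmed_length >= min_len:
            kept.append(r)
            stats["kept"] += 1
        else:
            stats["too_short"] += 1
    return kept, stats


def length_histogram(reads: Iterable[ReadRecord]) -> dict[int, int]:
    """Exact integer histogram of trimmed read lengths."""
    hist: dict[int, int] = {}
    for r in reads:
        hist[r.trimmed_length] = hist.get(r.trimmed_length, 0) + 1
    return hist


def write_histogram(hist: dict[int, int], path) -> None:
    """Serialize a length histogram as a two-column TSV (length, count)."""
    with open(path, "w") as handle:
        handle.write("length\tcount\n")
        for length in sorted(hist):
            handle.write(f"{length}\t{hist[length]}\n")
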