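"""Zero-mismatch read-to-variant assignment.

Because the variant database enumerates every admissible isoform
explicitly, zero-mismatch full-length alignment of a short read against
it is equivalent to an exact dictionary lookup on the read sequence; a
hash index therefore replaces an external short-read aligner without
approximation.  Sequence-identical database entries (paralogous loci,
trimmed forms colliding with shorter matures, ...) are resolved by a
deterministic priority rule so every read yields exactly one reported
assignment.  A linear-scan oracle and a parser for legacy bowtie
``.map`` output are provided for cross-checking and interoperability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .readprep import ReadRecord
from .refdb import VariantDB, VariantRecord

logger = logging.getLogger(__name__)

UNALIGNED = "UNALIGNED"

#: priority of (category, templated): simplest biological explanation first
_CLASS_RANK = {
    ("canonical", True): 0,
    ("trim3", True): 1,
    ("ext3", True): 2,
    ("ext5", True): 3,
    ("ext3", False): 4,
    ("ext5", False): 5,
}


class AssignError(Exception):
    pass


@dataclass(frozen=True)
class Assignment:
    """Outcome for one read: a single variant (or UNALIGNED) plus how the
    choice was made and how many sequence-identical candidates existed."""

    read_id: str
    variant_id: str
    n_candidates: int
    resolution: str  # unique | tie_broken | unaligned

    @property
    def aligned(self) -> bool:
        return self.variant_id != UNALIGNED


def priority_key(v: VariantRecord) -> tuple:
    """Sort key for candidates sharing one sequence: canonical < trimmed <
    templated 3' < templated 5' < non-templated 3' < non-templated 5',
    then fewer modified bases, then lexicographic variant_id."""
    return (_CLASS_RANK[(v.category, v.templated)], v.n_mod, v.variant_id)


@dataclass
class SeqIndex:
    """Hash index: full variant sequence -> candidates in priority order."""

    mapping: dict[str, list[str]]

    def __len__(self) -> int:
        return len(self.mapping)


def build_index(db: VariantDB) -> SeqIndex:
    """Index every database sequence with priority-ordered candidates."""
    if len(db) == 0:
        raise AssignError("cannot index an empty database")
    buckets: dict[str, list[VariantRecord]] = {}
    for v in db.variants:
        buckets.setdefault(v.sequence, []).append(v)
    mapping = {
        seq: [v.variant_id for v in sorted(group, key=priority_key)]
        for seq, group in buckets.items()
    }
    return SeqIndex(mapping=mapping)


def assign_read(sequence: str, index: SeqIndex, read_id: str = "") -> Assignment:
    """Exact full-length lookup; ties resolved by the priority order."""
    candidates = index.mapping.get(sequence)
    if not candidates:
        return Assignment(read_id, UNALIGNED, 0, "unaligned")
    resolution = "unique" if len(candidates) == 1 else "tie_broken"
    return Assignment(read_id, candidates[0], len(candidates), resolution)


def oracle_assign(sequence: str, db: VariantDB, read_id: str = "") -> Assignment:
    """Reference implementation: linear scan over all database records
    applying the identical priority rule.  Must agree with
    :func:`assign_read` on every input; exists to cross-check the index."""
    hits = [v for v in db.variants if v.sequence == sequence]
    if not hits:
        return Assignment(read_id, UNALIGNED, 0, "unaligned")
    best = min(hits, key=priority_key)
    resolution = "unique" if len(hits) == 1 else "tie_broken"
    return Assignment(read_id, best.variant_id, len(hits), resolution)


def assign_batch(
    reads: Iterable[ReadRecord], index: SeqIndex, db: VariantDB | None = None
) -> tuple[list[Assignment], dict[str, int]]:
    """Assign a batch of filtered reads; each read is counted exactly once.

    The summary mirrors the pipeline's standard accounting: reads in,
    total aligned, canonical-aligned, per-category aligned, unaligned.
    """
    assignments: list[Assignment] = []
    summary = {
        "filtered_in": 0,
        "aligned_total": 0,
        "aligned_canonical": 0,
        "aligned_trim3": 0,
        "aligned_ext5": 0,
        "aligned_ext3": 0,
        "unaligned": 0,
    }
    categories = (
        {v.variant_id: v.category for v in db.variants} if db is not None else None
    )
    for read in reads:
        a = assign_read(read.sequence, index, read_id=read.read_id)
        assignments.append(a)
        summary["filtered_in"] += 1
        if a.aligned:
            summary["aligned_total"] += 1
            if categories is not None:
                summary[f"aligned_{categories[a.variant_id]}"] += 1
        else:
            summary["unaligned"] += 1
    return assignments, summary


def parse_alignment_map(path, db: VariantDB) -> list[Assignment]:
    """Ingest legacy bowtie default (.map) output against the variant DB.

    Columns: read name, strand, reference name, 0-based offset, read
    sequence, qualities, same-alignment ceiling, mismatch descriptors
    (empty for a perfect alignment).  Lines are rejected -- with a
    warning -- when the reference is unknown or the mismatch field is
    non-empty (only perfect alignments are trusted); malformed lines are
    skipped, and more than 1% malformed lines is fatal.
    """
    assignments: list[Assignment] = []
    malformed = 0
    rejected_unknown = 0
    rejected_mismatch = 0
    total = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            total += 1
            fields = line.split("\t")
            if len(fields) < 7:
                malformed += 1
                logger.warning("malformed map line %d", total)
                continue
            read_id, _strand, ref = fields[0], fields[1], fields[2]
            mismatch_descr = fields[7] if len(fields) > 7 else ""
            if ref not in db:
                rejected_unknown += 1
                logger.warning("unknown reference %r in map line %d", ref, total)
                continue
            if mismatch_descr.strip():
                rejected_mismatch += 1
                logger.warning("imperfect alignment rejected, line %d", total)
                continue
            assignments.append(Assignment(read_id, ref, 1, "unique"))
    if total and malformed / total > 0.01:
        raise AssignError(
            f"{malformed}/{total} malformed lines in {path!r} (>1%): aborting"
        )
    if rejected_unknown or rejected_mismatch:
        logger.warning(
            "map ingest: %d unknown-reference, %d imperfect lines rejected",
            rejected_unknown,
            rejected_mismatch,
        )
    return assignments


def write_assignments(assignments: Iterable[Assignment], path) -> None:
    """Assignments TSV: read_id, variant_id, resolution, n_candidates."""
    with open(path, "w") as handle:
        handle.write("read_id\tvariant_id\tresolution\tn_candidates\n")
        for a in assignments:
            handle.write(f"{a.read_id}\t{a.variant_id}\t{a.resolution}\t{a.n_candidates}\n")


def read_assignments(path) -> list[Assignment]:
    out: list[Assignment] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("read_id\t"):
            raise AssignError(f"unexpected assignments header in {path!r}")
        for line in handle:
            read_id, variant_id, resolution, n_candidates = line.rstrip("\n").split("\t")
            out.append(Assignment(read_id, variant_id, int(n_candidates), resolution))
    return out
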