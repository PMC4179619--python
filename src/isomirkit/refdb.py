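"""Reference database of miRNA isoforms (isomiRs).

Builds, from a set of mature miRNA sequences and their precursor hairpins,
the exhaustive database of sequence variants an exact-match assigner can
report: the canonical mature sequence, every 1-3 nt extension of either
end, and every 3'-trimmed form down to a minimum length.  Each variant is
classified by site (5'/3'), by whether the added bases are explained by
the precursor sequence (templated vs non-templated), and -- for
non-templated forms -- by the first non-templated nucleotide (the
A/C/G/U "iso-group") and by whether the added tail is a single repeated
base ("pure") or heterogeneous ("mixed").

Sequences are canonicalized to the DNA alphabet internally (U -> T);
iso-groups are reported in RNA letters (U, not T) following the field's
nomenclature for uridylation.
"""

from __future__ import annotations

import itertools
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

DNA = "ACGT"
#: category sort order used for deterministic export
CATEGORY_ORDER = {"canonical": 0, "trim3": 1, "ext5": 2, "ext3": 3}

DB_TABLE_COLUMNS = [
    "variant_id",
    "mirna_id",
    "sequence",
    "category",
    "n_mod",
    "added_seq",
    "templated",
    "iso_group",
    "pure",
    "supporting_hairpins",
]


class RefDBError(Exception):
    """Fatal reference-database error (unreadable input, empty mature set...)."""


@dataclass(frozen=True)
class MatureRecord:
    """One annotated mature miRNA sequence (e.g. hsa-miR-92a-3p)."""

    mirna_id: str
    accession: str
    sequence: str

    @property
    def species(self) -> str:
        return self.mirna_id.split("-", 1)[0]


@dataclass(frozen=True)
class HairpinRecord:
    """One precursor (pre-miRNA hairpin) sequence (e.g. hsa-mir-92a-1)."""

    hairpin_id: str
    sequence: str


@dataclass(frozen=True)
class MatureLocus:
    """Exact placement of a mature miRNA inside a hairpin.

    ``flank5``/``flank3`` hold up to 3 hairpin bases immediately outside
    the mature, both in 5'->3' orientation; they are the template against
    which end-extensions are checked.
    """

    mirna_id: str
    hairpin_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    flank5: str
    flank3: str


@dataclass(frozen=True)
class VariantRecord:
    """One isomiR or canonical entry of the variant database.

    ``n_mod`` counts added bases (1-3) for extensions, trimmed bases for
    trim3 variants, and is 0 for the canonical form.  ``iso_group`` is a
    RNA-letter nucleotide (A/C/G/U) for non-templated extensions, "none"
    otherwise.
    """

    variant_id: str
    mirna_id: str
    sequence: str
    category: str  # canonical | trim3 | ext5 | ext3
    n_mod: int
    added_seq: str
    templated: bool
    iso_group: str
    pure: bool
    supporting_hairpins: tuple[str, ...]


@dataclass
class VariantDB:
    """The full variant database plus its duplicate-sequence bookkeeping."""

    variants: list[VariantRecord]
    matures: dict[str, MatureRecord] = field(default_factory=dict)
    loci: dict[str, list[MatureLocus]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_id = {v.variant_id: v for v in self.variants}
        if len(self._by_id) != len(self.variants):
            raise RefDBError("duplicate variant_ids in database")

    def __len__(self) -> int:
        return len(self.variants)

    def get(self, variant_id: str) -> VariantRecord:
        return self._by_id[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._by_id

    @property
    def duplicate_groups(self) -> list[set[str]]:
        """Sets of variant_ids sharing one sequence (size >= 2)."""
        by_seq: dict[str, set[str]] = {}
        for v in self.variants:
            by_seq.setdefault(v.sequence, set()).add(v.variant_id)
        return [g for g in by_seq.values() if len(g) > 1]

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.variants:
            out[v.category] = out.get(v.category, 0) + 1
        return out


def canonicalize(seq: str) -> str:
    """Uppercase and convert RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def parse_mirna_fasta(
    path,
    species_prefix: str,
    record_type: str = "mature",
) -> list[MatureRecord] | list[HairpinRecord]:
    """Parse a miRBase-style mature or hairpin FASTA.

    Headers are ``>ID [ACCESSION] [description...]``; only records whose
    ID starts with ``species_prefix`` (case-insensitive) are kept.
    Records with characters outside A/C/G/T/U are skipped with a warning.
    """
    records: list = []
    skipped = 0
    prefix = species_prefix.lower()
    try:
        handle: TextIO = open(path)
    except OSError as exc:
        raise RefDBError(f"cannot read FASTA {path!r}: {exc}") from exc
    with handle:
        for header, seq in SimpleFastaParser(handle):
            tokens = header.split()
            if not tokens:
                skipped += 1
                continue
            rec_id = tokens[0]
            if not rec_id.lower().startswith(prefix):
                continue
            seq = canonicalize(seq)
            if not seq or any(b not in DNA for b in seq):
                logger.warning("skipping %s: non-ACGU(T) characters", rec_id)
                skipped += 1
                continue
            if record_type == "mature":
                accession = tokens[1] if len(tokens) > 1 else ""
                records.append(MatureRecord(rec_id, accession, seq))
            else:
                records.append(HairpinRecord(rec_id, seq))
    if skipped:
        logger.warning("%d record(s) skipped while parsing %s", skipped, path)
    return records


def locate_mature(
    mature: MatureRecord, hairpins: Iterable[HairpinRecord]
) -> list[MatureLocus]:
    """Find every exact occurrence of the mature inside any hairpin.

    Returns one locus per occurrence (a mature may sit on several
    paralogous hairpins, or twice on one).  Empty list -- with a warning
    -- when the mature matches no hairpin; extension variants are then
    all treated as non-templated downstream.
    """
    loci: list[MatureLocus] = []
    mseq = mature.sequence
    for hp in hairpins:
        start = hp.sequence.find(mseq)
        while start != -1:
            end = start + len(mseq)
            loci.append(
                MatureLocus(
                    mirna_id=mature.mirna_id,
                    hairpin_id=hp.hairpin_id,
                    start=start,
                    end=end,
                    flank5=hp.sequence[max(0, start - 3) : start],
                    flank3=hp.sequence[end : end + 3],
                )
            )
            start = hp.sequence.find(mseq, start + 1)
    if not loci:
        logger.warning("mature %s found in no hairpin", mature.mirna_id)
    return loci


def _outward(added_seq: str, side: str) -> str:
    """Reorder added bases so index 0 is the base adjacent to the mature.

    3' additions already read outward left-to-right; 5' additions are
    given 5'->3', so the base next to the mature is the LAST one.
    """
    if side == "3p_end":
        return added_seq
    if side == "5p_end":
        return added_seq[::-1]
    raise ValueError(f"side must be '5p_end' or '3p_end', got {side!r}")


def _flank_outward(flank: str, side: str, k: int) -> str:
    """Template bases for a k-nt addition, outward order (may be short)."""
    if side == "3p_end":
        return flank[:k]
    return flank[::-1][:k]


def classify_extension(
    added_seq: str, flank_seqs: Iterable[str], side: str
) -> tuple[bool, str, bool]:
    """Classify an end-extension against precursor flank sequences.

    A variant is *templated* when the added bases perfectly pair with the
    precursor on at least one flank (positions running past a flank's end
    cannot pair).  Otherwise the *iso-group* is the added base -- reported
    as an RNA letter -- at the first outward position where every flank
    has already failed: a position is considered templated if ANY flank
    matches it with all inner positions also matching on that same flank.
    *Pure* non-templated forms carry a single repeated base (-A/-AA/-AAA).

    Returns ``(templated, iso_group, pure)`` with ``iso_group`` in
    {"A","C","G","U","none"}.
    """
    if not added_seq:
        raise ValueError("added_seq must be non-empty")
    added = canonicalize(added_seq)
    out = _outward(added, side)
    k = len(out)
    # per-flank length of the outward-matching prefix
    best_match = 0
    for flank in flank_seqs:
        template = _flank_outward(canonicalize(flank), side, k)
        m = 0
        for a, t in zip(out, template):
            if a != t:
                break
            m += 1
        if m == k and len(template) == k:
            return True, "none", False
        best_match = max(best_match, m)
    first_nt = out[min(best_match, k - 1)]
    iso_group = "U" if first_nt == "T" else first_nt
    pure = len(set(added)) == 1
    return False, iso_group, pure


def enumerate_variants(
    mature: MatureRecord,
    loci: list[MatureLocus],
    max_ext: int = 3,
    min_len: int = 18,
) -> list[VariantRecord]:
    """Enumerate every variant of one mature miRNA.

    Emits 1 canonical + all 4^k 5'-extensions and 4^k 3'-extensions for
    k = 1..max_ext + one 3'-trimmed form per removed base down to
    ``min_len``.  Extensions are classified against all loci; canonical
    and trimmed forms are templated by construction.
    """
    L = len(mature.sequence)
    if L < min_len:
        logger.warning(
            "mature %s shorter than %d nt: no variants", mature.mirna_id, min_len
        )
        return []
    mid = mature.mirna_id
    all_hp = tuple(dict.fromkeys(l.hairpin_id for l in loci))
    out: list[VariantRecord] = [
        VariantRecord(
            variant_id=f"{mid}|canonical",
            mirna_id=mid,
            sequence=mature.sequence,
            category="canonical",
            n_mod=0,
            added_seq="",
            templated=True,
            iso_group="none",
            pure=False,
            supporting_hairpins=all_hp,
        )
    ]
    for t in range(1, L - min_len + 1):
        out.append(
            VariantRecord(
                variant_id=f"{mid}|trim3|-{t}",
                mirna_id=mid,
                sequence=mature.sequence[:-t],
                category="trim3",
                n_mod=t,
                added_seq="",
                templated=True,
                iso_group="none",
                pure=False,
                supporting_hairpins=all_hp,
            )
        )
    for side, category in (("5p_end", "ext5"), ("3p_end", "ext3")):
        flanks = [l.flank5 if side == "5p_end" else l.flank3 for l in loci]
        for k in range(1, max_ext + 1):
            for combo in itertools.product(DNA, repeat=k):
                added = "".join(combo)
                templated, iso_group, pure = classify_extension(added, flanks, side)
                if templated:
                    support = tuple(
                        l.hairpin_id
                        for l in loci
                        if classify_extension(
                            added,
                            [l.flank5 if side == "5p_end" else l.flank3],
                            side,
                        )[0]
                    )
                else:
                    support = ()
                seq = added + mature.sequence if side == "5p_end" else mature.sequence + added
                out.append(
                    VariantRecord(
                        variant_id=f"{mid}|{category}|+{added}",
                        mirna_id=mid,
                        sequence=seq,
                        category=category,
                        n_mod=k,
                        added_seq=added,
                        templated=templated,
                        iso_group=iso_group,
                        pure=pure,
                        supporting_hairpins=tuple(dict.fromkeys(support)),
                    )
                )
    return out


def build_database(
    matures: Iterable[MatureRecord],
    hairpins: Iterable[HairpinRecord],
    max_ext: int = 3,
    min_len: int = 18,
) -> VariantDB:
    """Build the full variant database over all matures.

    Duplicate sequences across variants (e.g. from paralogous loci) are
    kept; deduplication happens at read assignment, not here.
    """
    matures = list(matures)
    hairpins = list(hairpins)
    if not matures:
        raise RefDBError("no mature miRNA records: cannot build database")
    seen_ids = set()
    for m in matures:
        if m.mirna_id in seen_ids:
            raise RefDBError(f"duplicate mirna_id {m.mirna_id!r}")
        seen_ids.add(m.mirna_id)
    variants: list[VariantRecord] = []
    loci_map: dict[str, list[MatureLocus]] = {}
    for m in matures:
        loci = locate_mature(m, hairpins)
        loci_map[m.mirna_id] = loci
        variants.extend(enumerate_variants(m, loci, max_ext=max_ext, min_len=min_len))
    db = VariantDB(
        variants=variants,
        matures={m.mirna_id: m for m in matures},
        loci=loci_map,
    )
    logger.info(
        "database: %d variants from %d matures (%s); %d duplicate-sequence groups",
        len(db),
        len(matures),
        db.category_counts(),
        len(db.duplicate_groups),
    )
    return db


def _sort_key(v: VariantRecord):
    return (v.mirna_id, CATEGORY_ORDER[v.category], v.n_mod, v.added_seq)


def sorted_variants(db: VariantDB) -> list[VariantRecord]:
    """Deterministic export order: mirna_id, category, n_mod, added_seq."""
    return sorted(db.variants, key=_sort_key)


def export_database(db: VariantDB, fasta_path, table_path) -> None:
    """Write the variant FASTA (index source for an exact aligner) and the
    annotation TSV.  Byte-stable: same database -> identical files."""
    variants = sorted_variants(db)
    try:
        with open(fasta_path, "w") as fa:
            for v in variants:
                fa.write(f">{v.variant_id}\n{v.sequence}\n")
        with open(table_path, "w") as tsv:
            tsv.write("\t".join(DB_TABLE_COLUMNS) + "\n")
            for v in variants:
                tsv.write(
                    "\t".join(
                        [
                            v.variant_id,
                            v.mirna_id,
                            v.sequence,
                            v.category,
                            str(v.n_mod),
                            v.added_seq,
                            str(v.templated),
                            v.iso_group,
                            str(v.pure),
                            ",".join(v.supporting_hairpins),
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise RefDBError(f"cannot write database: {exc}") from exc


def load_database(table_path) -> VariantDB:
    """Reload a database from its annotation TSV (inverse of export)."""
    variants: list[VariantRecord] = []
    try:
        handle = open(table_path)
    except OSError as exc:
        raise RefDBError(f"cannot read database table {table_path!r}: {exc}") from exc
    with handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != DB_TABLE_COLUMNS:
            raise RefDBError(f"unexpected database table header in {table_path!r}")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            variants.append(
                VariantRecord(
                    variant_id=f[0],
                    mirna_id=f[1],
                    sequence=f[2],
                    category=f[3],
                    n_mod=int(f[4]),
                    added_seq=f[5],
                    templated=f[6] == "True",
                    iso_group=f[7],
                    pure=f[8] == "True",
                    supporting_hairpins=tuple(x for x in f[9].split(",") if x),
                )
            )
    if not variants:
        raise RefDBError(f"empty database table {table_path!r}")
    # mature set reconstructed from canonical rows
    matures = {
        v.mirna_id: MatureRecord(v.mirna_id, "", v.sequence)
        for v in variants
        if v.category == "canonical"
    }
    return VariantDB(variants=variants, matures=matures)
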