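"""Quantification, normalization, class summaries and comparisons.

Aggregates per-read assignments into a variant x sample count table,
applies reads-per-million (RPM) normalization, and produces the
class-resolved views an isomiR study reports: per-class species/read
shares, per-miRNA isoform composition, the A/C/G/U iso-group
distribution of 3' additions, a Fisher exact enrichment test, and
two-sample fold-change comparison.

Variant classes used throughout: canonical, trim3, and the four
site x origin extension classes ext5-T / ext5-NT / ext3-T / ext3-NT
(T = templated, NT = non-templated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assign import Assignment
from .refdb import VariantDB, sorted_variants

CLASSES = ["canonical", "trim3", "ext5-T", "ext5-NT", "ext3-T", "ext3-NT"]


class QuantError(Exception):
    pass


def variant_class(category: str, templated: bool) -> str:
    """Collapse (category, templated) to the six reporting classes."""
    if category in ("canonical", "trim3"):
        return category
    return f"{category}-{'T' if templated else 'NT'}"


@dataclass
class CountTable:
    """Raw and RPM-normalized counts, variants as rows, samples as columns.

    ``library_size`` records the per-sample denominator actually used for
    normalization; ``rpm`` is None until :func:`rpm_normalize` is called.
    """

    counts: pd.DataFrame
    rpm: pd.DataFrame | None = None
    library_size: pd.Series | None = None
    denominator: str = "mapped"

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def count_assignments(
    assignments_by_sample: Mapping[str, Iterable[Assignment]],
    db: VariantDB,
    keep_zero_rows: bool = True,
) -> CountTable:
    """Tally aligned assignments into raw counts per variant per sample.

    Unaligned assignments are ignored (they carry no variant).  An
    assignment naming a variant absent from the database is fatal: it
    means the assignments and database are out of sync.
    """
    order = [v.variant_id for v in sorted_variants(db)]
    samples = list(assignments_by_sample)
    counts = pd.DataFrame(0, index=pd.Index(order, name="variant_id"), columns=samples)
    for sample, assignments in assignments_by_sample.items():
        for a in assignments:
            if not a.aligned:
                continue
            if a.variant_id not in db:
                raise QuantError(
                    f"assignment references unknown variant {a.variant_id!r}"
                )
            counts.loc[a.variant_id, sample] += 1
    if not keep_zero_rows:
        counts = counts.loc[counts.sum(axis=1) > 0]
    return CountTable(counts=counts)


def rpm_normalize(
    table: CountTable,
    denominator: str = "mapped",
    filtered_sizes: Mapping[str, int] | None = None,
) -> CountTable:
    """Reads-per-million: rpm = count * 1e6 / library_size.

    ``denominator="mapped"`` (default) divides by the sample's total
    assigned reads, so per-sample RPM sums to exactly 1e6;
    ``"filtered"`` divides by externally supplied post-trimming read
    counts instead.
    """
    if denominator == "mapped":
        sizes = table.counts.sum(axis=0)
    elif denominator == "filtered":
        if filtered_sizes is None:
            raise QuantError("denominator='filtered' requires filtered_sizes")
        sizes = pd.Series({s: filtered_sizes[s] for s in table.samples})
    else:
        raise QuantError(f"unknown denominator {denominator!r}")
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise QuantError(f"zero library size for sample(s) {bad}")
    rpm = table.counts * 1e6 / sizes
    return CountTable(
        counts=table.counts,
        rpm=rpm,
        library_size=sizes.astype(int),
        denominator=denominator,
    )


def _class_series(db: VariantDB) -> pd.Series:
    return pd.Series(
        {v.variant_id: variant_class(v.category, v.templated) for v in db.variants}
    )


def summarize_classes(
    table: CountTable, db: VariantDB, detected_min: int = 1
) -> pd.DataFrame:
    """Per-sample, per-class species and read totals with percentages.

    A variant is "detected" when its raw count is >= ``detected_min``
    (set 2 for a strict more-than-one-read definition).  Read totals per
    sample sum to the sample's mapped total.
    """
    klass = _class_series(db).reindex(table.counts.index)
    rows = []
    for sample in table.samples:
        col = table.counts[sample]
        detected = (col >= detected_min).groupby(klass).sum()
        reads = col.groupby(klass).sum()
        n_detected = int((col >= detected_min).sum())
        n_reads = int(col.sum())
        for c in CLASSES:
            d = int(detected.get(c, 0))
            r = int(reads.get(c, 0))
            rows.append(
                {
                    "sample": sample,
                    "class": c,
                    "detected_species": d,
                    "reads": r,
                    "pct_species": 100.0 * d / n_detected if n_detected else 0.0,
                    "pct_reads": 100.0 * r / n_reads if n_reads else 0.0,
                }
            )
    return pd.DataFrame(rows)


def mirna_composition(
    table: CountTable,
    db: VariantDB,
    total_min: int = 100,
    thresholds: Sequence[float] = (0.1, 0.2, 0.5),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-miRNA isoform composition, pooled over samples.

    Only miRNAs whose pooled total (canonical plus all isoforms) is
    strictly greater than ``total_min`` are reported.  Returns
    ``(composition, threshold_counts)``: the first has one row per miRNA
    with the fraction of its reads in each class and a flag when the
    most-expressed form is a 3' non-templated variant; the second counts,
    per class and threshold, the miRNAs whose class fraction reaches the
    threshold.
    """
    for t in thresholds:
        if not 0 < t <= 1:
            raise QuantError(f"threshold {t} outside (0, 1]")
    klass = _class_series(db)
    parent = pd.Series({v.variant_id: v.mirna_id for v in db.variants})
    total = table.counts.sum(axis=1)
    frame = pd.DataFrame(
        {
            "reads": total,
            "mirna_id": parent.reindex(total.index),
            "class": klass.reindex(total.index),
        }
    )
    by_mirna = frame.pivot_table(
        index="mirna_id", columns="class", values="reads", aggfunc="sum", fill_value=0
    ).reindex(columns=CLASSES, fill_value=0)
    totals = by_mirna.sum(axis=1)
    by_mirna = by_mirna.loc[totals > total_min]
    totals = totals.loc[by_mirna.index]
    fractions = by_mirna.div(totals, axis=0)
    composition = fractions.add_prefix("frac_")
    composition.insert(0, "total_reads", totals.astype(int))
    composition["prevalent_class"] = fractions.idxmax(axis=1)
    composition["prevalent_is_3p_nt"] = composition["prevalent_class"] == "ext3-NT"
    composition = composition.sort_index()
    thr_rows = []
    for c in CLASSES:
        for t in thresholds:
            thr_rows.append(
                {
                    "class": c,
                    "threshold": t,
                    "n_mirnas": int((fractions[c] >= t).sum()),
                }
            )
    return composition, pd.DataFrame(thr_rows)


def isogroup_summary(
    table: CountTable, db: VariantDB, pure_only: bool = False
) -> pd.DataFrame:
    """A/C/G/U nucleotide distribution of 3'-end additions, pooled.

    The non-templated side groups variants by their iso-group (first
    non-templated nucleotide); with ``pure_only`` the mixed forms are
    dropped, restricting to -X/-XX/-XXX tails attributable to a single
    nucleotidyl-transferase activity.  The templated side groups by the
    first added (precursor-encoded) base for contrast.  Shares are
    percentages within each side.
    """
    total = table.counts.sum(axis=1)
    rows = []
    for side in ("templated", "non_templated"):
        per_group: dict[str, dict[str, int]] = {
            g: {"species": 0, "reads": 0} for g in "ACGU"
        }
        for v in db.variants:
            if v.category != "ext3":
                continue
            if side == "templated":
                if not v.templated:
                    continue
                first = v.added_seq[0]
                group = "U" if first == "T" else first
            else:
                if v.templated:
                    continue
                if pure_only and not v.pure:
                    continue
                group = v.iso_group
            reads = int(total.get(v.variant_id, 0))
            if reads > 0:
                per_group[group]["species"] += 1
                per_group[group]["reads"] += reads
        side_species = sum(d["species"] for d in per_group.values())
        side_reads = sum(d["reads"] for d in per_group.values())
        for g in "ACGU":
            d = per_group[g]
            rows.append(
                {
                    "side": side,
                    "iso_group": g,
                    "species": d["species"],
                    "reads": d["reads"],
                    "pct_species": 100.0 * d["species"] / side_species
                    if side_species
                    else 0.0,
                    "pct_reads": 100.0 * d["reads"] / side_reads if side_reads else 0.0,
                }
            )
    return pd.DataFrame(rows)


def enrichment_test(table_2x2: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 contingency table.

    Exact conditional test: with margins fixed, cell (0,0) follows a
    hypergeometric law; the two-sided p-value sums the probabilities of
    every table at most as probable as the observed one.  Probabilities
    are compared as exact integers (common denominator C(N, c1)), so no
    floating-point tie ambiguity arises.  The odds ratio is a*d / (b*c),
    infinite when b*c = 0.

    Returns ``(odds_ratio, p_two_sided)``.
    """
    (a, b), (c, d) = table_2x2
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table cells must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("both row sums and both column sums must be positive")
    odds_ratio = math.inf if b * c == 0 else (a * d) / (b * c)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    p = sum(w for w in weights if w <= observed) / math.comb(n, c1)
    return odds_ratio, min(1.0, p)


@dataclass(frozen=True)
class ComparisonRow:
    """One feature of the two-sample fold-change comparison."""

    feature_id: str
    raw_a: int
    raw_b: int
    rpm_a: float
    rpm_b: float
    log2fc: float
    expressed_flag: bool
    regulated_flag: bool
    infinite: bool = False


def differential_expression(
    table: CountTable,
    db: VariantDB,
    level: str = "mirna",
    expr_min: int = 100,
    fc_cutoff_log2: float = 1.0,
) -> list[ComparisonRow]:
    """Two-sample fold-change comparison on RPM-normalized counts.

    ``level="mirna"`` compares canonical-form counts per miRNA,
    ``"mirna_total"`` aggregates canonical plus all isoforms per parent
    miRNA, ``"variant"`` compares individual variants.  Only features
    with raw count strictly above ``expr_min`` in at least one sample are
    reported; a feature zero on one side at variant level gets a signed
    infinite log2 fold change and is flagged, not dropped.
    """
    if len(table.samples) != 2:
        raise QuantError("differential expression requires exactly two samples")
    if table.rpm is None:
        raise QuantError("run rpm_normalize before differential_expression")
    sa, sb = table.samples
    if level == "mirna":
        keep = [v.variant_id for v in db.variants if v.category == "canonical"]
        ids = {vid: db.get(vid).mirna_id for vid in keep}
        raw = table.counts.loc[keep].rename(index=ids)
        rpm = table.rpm.loc[keep].rename(index=ids)
    elif level == "mirna_total":
        parent = pd.Series({v.variant_id: v.mirna_id for v in db.variants})
        raw = table.counts.groupby(parent.reindex(table.counts.index)).sum()
        rpm = table.rpm.groupby(parent.reindex(table.rpm.index)).sum()
    elif level == "variant":
        raw, rpm = table.counts, table.rpm
    else:
        raise QuantError(f"unknown level {level!r}")
    rows: list[ComparisonRow] = []
    for fid in raw.index:
        ra, rb = int(raw.loc[fid, sa]), int(raw.loc[fid, sb])
        expressed = max(ra, rb) > expr_min
        if not expressed:
            continue
        pa, pb = float(rpm.loc[fid, sa]), float(rpm.loc[fid, sb])
        if pa > 0 and pb > 0:
            log2fc = math.log2(pb / pa)
            infinite = False
        else:
            log2fc = math.inf if pb > pa else -math.inf
            infinite = True
        regulated = abs(log2fc) > fc_cutoff_log2
        rows.append(
            ComparisonRow(
                feature_id=str(fid),
                raw_a=ra,
                raw_b=rb,
                rpm_a=pa,
                rpm_b=pb,
                log2fc=log2fc,
                expressed_flag=expressed,
                regulated_flag=regulated,
                infinite=infinite,
            )
        )
    rows.sort(key=lambda r: r.feature_id)
    return rows


def write_count_table(table: CountTable, counts_path, rpm_path=None) -> None:
    """Counts TSV (variant_id x samples); optional RPM TSV alongside."""
    table.counts.to_csv(counts_path, sep="\t")
    if rpm_path is not None:
        if table.rpm is None:
            raise QuantError("no RPM table computed")
        table.rpm.to_csv(rpm_path, sep="\t", float_format="%.6f")


def write_comparison(rows: Iterable[ComparisonRow], path) -> None:
    with open(path, "w") as handle:
        handle.write(
            "feature_id\traw_a\traw_b\trpm_a\trpm_b\tlog2fc\t"
            "expressed\tregulated\tinfinite\n"
        )
        for r in rows:
            handle.write(
                f"{r.feature_id}\t{r.raw_a}\t{r.raw_b}\t{r.rpm_a:.6f}\t"
                f"{r.rpm_b:.6f}\t{r.log2fc:.6f}\t{r.expressed_flag}\t"
                f"{r.regulated_flag}\t{r.infinite}\n"
            )
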