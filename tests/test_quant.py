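"""Counting, RPM normalization, class summaries, Fisher test, fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirkit import quant
from isomirkit.assign import Assignment
from isomirkit.quant import (
    CountTable,
    count_assignments,
    differential_expression,
    enrichment_test,
    isogroup_summary,
    mirna_composition,
    rpm_normalize,
    summarize_classes,
    variant_class,
)


def _aligned(read_id, vid):
    return Assignment(read_id, vid, 1, "unique")


def _table_from_counts(db, counts_by_sample):
    """CountTable with explicit per-variant counts, zero elsewhere."""
    assignments = {
        sample: [
            _aligned(f"{sample}_{vid}_{i}", vid)
            for vid, n in spec.items()
            for i in range(n)
        ]
        for sample, spec in counts_by_sample.items()
    }
    return count_assignments(assignments, db)


# ------------------------------------------------------------- counting


def test_count_assignments(toy_db, toy_mature):
    vid = f"{toy_mature.mirna_id}|canonical"
    table = _table_from_counts(toy_db, {"s1": {vid: 100}})
    assert table.counts.loc[vid, "s1"] == 100
    assert table.counts["s1"].sum() == 100
    assert (table.counts.drop(index=vid)["s1"] == 0).all()


def test_count_unknown_variant_fatal(toy_db):
    with pytest.raises(quant.QuantError):
        count_assignments({"s1": [_aligned("r", "nope|canonical")]}, toy_db)


def test_count_unaligned_ignored_and_zero_table(toy_db):
    table = count_assignments(
        {"s1": [Assignment("r", "UNALIGNED", 0, "unaligned")]}, toy_db
    )
    assert (table.counts["s1"] == 0).all()


def test_count_two_samples_disjoint(toy_db, toy_mature):
    v1 = f"{toy_mature.mirna_id}|canonical"
    v2 = f"{toy_mature.mirna_id}|trim3|-1"
    table = _table_from_counts(toy_db, {"a": {v1: 5}, "b": {v2: 7}})
    assert table.counts.loc[v1, "a"] == 5 and table.counts.loc[v1, "b"] == 0
    assert table.counts.loc[v2, "b"] == 7 and table.counts.loc[v2, "a"] == 0


# ---------------------------------------------------------------- RPM


def test_rpm_arithmetic(toy_db, toy_mature):
    vid = f"{toy_mature.mirna_id}|canonical"
    other = f"{toy_mature.mirna_id}|trim3|-1"
    table = _table_from_counts(toy_db, {"s1": {vid: 250, other: 750}})
    table = rpm_normalize(table)
    assert table.library_size["s1"] == 1000
    assert table.rpm.loc[vid, "s1"] == pytest.approx(250_000)


def test_rpm_filtered_denominator(toy_db, toy_mature):
    vid = f"{toy_mature.mirna_id}|canonical"
    table = _table_from_counts(toy_db, {"s1": {vid: 200}})
    table = rpm_normalize(table, denominator="filtered", filtered_sizes={"s1": 1_000_000})
    assert table.rpm.loc[vid, "s1"] == pytest.approx(200.0)


def test_rpm_zero_library_fatal(toy_db):
    table = _table_from_counts(toy_db, {"s1": {}})
    with pytest.raises(quant.QuantError):
        rpm_normalize(table)


@given(
    counts=st.lists(
        st.lists(st.integers(min_value=0, max_value=10_000), min_size=3, max_size=3),
        min_size=2,
        max_size=6,
    )
)
@settings(max_examples=100, deadline=None)
def test_rpm_conservation_on_random_tables(counts):
    frame = pd.DataFrame(counts, columns=["s1", "s2", "s3"])
    frame.index = [f"v{i}" for i in range(len(frame))]
    table = CountTable(counts=frame)
    totals = frame.sum(axis=0)
    if (totals == 0).any():
        with pytest.raises(quant.QuantError):
            rpm_normalize(table)
        return
    table = rpm_normalize(table)
    for s in table.samples:
        assert table.rpm[s].sum() == pytest.approx(1e6, rel=1e-6)


# ------------------------------------------------------------ summaries


def test_variant_class_collapse():
    assert variant_class("canonical", True) == "canonical"
    assert variant_class("ext3", False) == "ext3-NT"
    assert variant_class("ext5", True) == "ext5-T"


def test_summarize_classes_read_shares(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db,
        {"s1": {f"{mid}|canonical": 60, f"{mid}|ext3|+T": 30, f"{mid}|trim3|-1": 10}},
    )
    summary = summarize_classes(table, toy_db).set_index("class")
    assert summary.loc["canonical", "pct_reads"] == pytest.approx(60.0)
    assert summary.loc["ext3-T", "pct_reads"] == pytest.approx(30.0)
    assert summary.loc["trim3", "pct_reads"] == pytest.approx(10.0)
    assert summary["reads"].sum() == table.counts["s1"].sum()
    assert summary.loc["canonical", "detected_species"] == 1


def test_summarize_all_canonical_and_empty(toy_db, toy_mature):
    vid = f"{toy_mature.mirna_id}|canonical"
    table = _table_from_counts(toy_db, {"s1": {vid: 10}, "s2": {}})
    summary = summarize_classes(table, toy_db)
    s1 = summary[summary["sample"] == "s1"].set_index("class")
    assert s1.loc["canonical", "pct_reads"] == pytest.approx(100.0)
    s2 = summary[summary["sample"] == "s2"]
    assert (s2[["detected_species", "reads", "pct_reads"]] == 0).all().all()


def test_summarize_strict_detection_threshold(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db, {"s1": {f"{mid}|canonical": 1, f"{mid}|trim3|-1": 5}}
    )
    loose = summarize_classes(table, toy_db, detected_min=1).set_index("class")
    strict = summarize_classes(table, toy_db, detected_min=2).set_index("class")
    assert loose.loc["canonical", "detected_species"] == 1
    assert strict.loc["canonical", "detected_species"] == 0
    assert strict.loc["trim3", "detected_species"] == 1


def test_mirna_composition_strict_total_filter(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db,
        {"s1": {f"{mid}|canonical": 80, f"{mid}|trim3|-1": 15, f"{mid}|ext3|+A": 5}},
    )
    composition, _ = mirna_composition(table, toy_db, total_min=100)
    assert mid not in composition.index  # total 100 fails the strict > 100 rule


def test_mirna_composition_fractions_and_thresholds(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db, {"s1": {f"{mid}|canonical": 800, f"{mid}|ext3|+A": 200}}
    )
    composition, thresholds = mirna_composition(
        table, toy_db, total_min=100, thresholds=(0.1, 0.2, 0.5)
    )
    row = composition.loc[mid]
    assert row["frac_ext3-NT"] == pytest.approx(0.2)
    frac_cols = [c for c in composition.columns if c.startswith("frac_")]
    assert composition[frac_cols].sum(axis=1).iloc[0] == pytest.approx(1.0)
    thr = thresholds.set_index(["class", "threshold"])["n_mirnas"]
    assert thr[("ext3-NT", 0.1)] == 1
    assert thr[("ext3-NT", 0.2)] == 1
    assert thr[("ext3-NT", 0.5)] == 0
    assert not row["prevalent_is_3p_nt"]


def test_mirna_composition_prevalent_nt_flag(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db, {"s1": {f"{mid}|canonical": 10, f"{mid}|ext3|+A": 990}}
    )
    composition, _ = mirna_composition(table, toy_db)
    assert composition.loc[mid, "prevalent_is_3p_nt"]


def test_mirna_composition_rejects_bad_threshold(toy_db):
    table = _table_from_counts(toy_db, {"s1": {}})
    with pytest.raises(quant.QuantError):
        mirna_composition(table, toy_db, thresholds=(0.0,))


def test_isogroup_summary_shares(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    # flank3 is TCA: +A/+AA are pure A-forms, +TT is a pure U-form, +GA mixed
    table = _table_from_counts(
        toy_db,
        {
            "s1": {
                f"{mid}|ext3|+A": 500,
                f"{mid}|ext3|+TT": 200,
                f"{mid}|ext3|+CC": 20,
                f"{mid}|ext3|+GG": 30,
                f"{mid}|ext3|+GA": 40,
                f"{mid}|ext3|+T": 1000,  # templated (+T matches flank TCA)
            }
        },
    )
    pure = isogroup_summary(table, toy_db, pure_only=True)
    nt = pure[pure["side"] == "non_templated"].set_index("iso_group")
    assert nt["reads"].sum() == 750  # mixed +GA dropped
    assert nt.loc["A", "pct_reads"] == pytest.approx(100 * 500 / 750)
    assert nt["pct_reads"].sum() == pytest.approx(100.0)
    mixed_in = isogroup_summary(table, toy_db, pure_only=False)
    nt_all = mixed_in[mixed_in["side"] == "non_templated"].set_index("iso_group")
    assert nt_all["reads"].sum() == 790
    # +GA groups under G (first non-templated nucleotide)
    assert nt_all.loc["G", "reads"] == 30 + 40
    templ = mixed_in[mixed_in["side"] == "templated"].set_index("iso_group")
    assert templ.loc["U", "reads"] == 1000  # +T grouped by first added base
    assert templ["pct_reads"].sum() == pytest.approx(100.0)


# --------------------------------------------------------- Fisher test


def test_enrichment_test_worked_examples():
    odds, p = enrichment_test([[90, 10], [50, 50]])
    assert odds == pytest.approx(9.0)
    sp = scipy.stats.fisher_exact([[90, 10], [50, 50]])
    assert p == pytest.approx(sp.pvalue, rel=1e-9)

    odds, p = enrichment_test([[10, 10], [10, 10]])
    assert odds == 1.0 and p == 1.0

    odds, p = enrichment_test([[5, 0], [0, 5]])
    assert math.isinf(odds)
    assert p == pytest.approx(2 / math.comb(10, 5))


def test_enrichment_test_contract_violations():
    with pytest.raises(ValueError):
        enrichment_test([[-1, 2], [3, 4]])
    with pytest.raises(ValueError):
        enrichment_test([[0, 0], [3, 4]])


@given(
    a=st.integers(0, 40),
    b=st.integers(0, 40),
    c=st.integers(0, 40),
    d=st.integers(0, 40),
)
@settings(max_examples=200, deadline=None)
def test_enrichment_matches_scipy(a, b, c, d):
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    _, p = enrichment_test([[a, b], [c, d]])
    sp = scipy.stats.fisher_exact([[a, b], [c, d]])
    assert p == pytest.approx(sp.pvalue, rel=1e-7, abs=1e-12)


# ------------------------------------------------- differential expression


def _two_sample_table(db, mid, n_a, n_b, lib=1_000_000):
    canonical = f"{mid}|canonical"
    table = _table_from_counts(db, {"N": {canonical: n_a}, "T": {canonical: n_b}})
    return rpm_normalize(table, denominator="filtered", filtered_sizes={"N": lib, "T": lib})


def test_de_worked_examples(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    rows = differential_expression(_two_sample_table(toy_db, mid, 200, 800), toy_db)
    (row,) = rows
    assert row.log2fc == pytest.approx(2.0)
    assert row.regulated_flag and row.expressed_flag

    (row,) = differential_expression(_two_sample_table(toy_db, mid, 150, 150), toy_db)
    assert row.log2fc == pytest.approx(0.0)
    assert not row.regulated_flag

    rows = differential_expression(_two_sample_table(toy_db, mid, 50, 90), toy_db)
    assert rows == []  # below the >100 expression filter


def test_de_requires_two_samples(toy_db, toy_mature):
    vid = f"{toy_mature.mirna_id}|canonical"
    table = rpm_normalize(_table_from_counts(toy_db, {"only": {vid: 500}}))
    with pytest.raises(quant.QuantError):
        differential_expression(table, toy_db)


def test_de_antisymmetry(sim_db):
    rng = np.random.default_rng(42)
    canonicals = [v.variant_id for v in sim_db.variants if v.category == "canonical"]
    spec_a = {vid: int(rng.integers(0, 2000)) for vid in canonicals}
    spec_b = {vid: int(rng.integers(0, 2000)) for vid in canonicals}
    fwd = count_assignments({"A": spec_to(spec_a), "B": spec_to(spec_b)}, sim_db)
    rev = count_assignments({"B": spec_to(spec_b), "A": spec_to(spec_a)}, sim_db)
    fwd = rpm_normalize(fwd)
    rev = rpm_normalize(rev)
    rows_f = {r.feature_id: r for r in differential_expression(fwd, sim_db)}
    rows_r = {r.feature_id: r for r in differential_expression(rev, sim_db)}
    assert rows_f and set(rows_f) == set(rows_r)
    for fid, rf in rows_f.items():
        assert rows_r[fid].log2fc == pytest.approx(-rf.log2fc)


def spec_to(spec):
    return [
        _aligned(f"{vid}_{i}", vid) for vid, n in spec.items() for i in range(n)
    ]


def test_de_variant_level_infinite_flagged(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    vid = f"{mid}|ext3|+A"
    table = _table_from_counts(toy_db, {"N": {vid: 500}, "T": {f"{mid}|canonical": 500}})
    table = rpm_normalize(table)
    rows = {r.feature_id: r for r in differential_expression(table, toy_db, level="variant")}
    assert rows[vid].infinite and rows[vid].log2fc == -math.inf
    assert rows[vid].regulated_flag and rows[vid].expressed_flag


def test_de_mirna_total_aggregates_isoforms(toy_db, toy_mature):
    mid = toy_mature.mirna_id
    table = _table_from_counts(
        toy_db,
        {
            "N": {f"{mid}|canonical": 100, f"{mid}|ext3|+A": 100},
            "T": {f"{mid}|canonical": 400, f"{mid}|ext3|+A": 400},
        },
    )
    table = rpm_normalize(table, denominator="filtered",
                          filtered_sizes={"N": 10**6, "T": 10**6})
    (row,) = differential_expression(table, toy_db, level="mirna_total")
    assert row.raw_a == 200 and row.raw_b == 800
    assert row.log2fc == pytest.approx(2.0)
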