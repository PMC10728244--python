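"""QC cascade: per-stage rules, idempotence, ordering semantics, audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sharedzotu as sz
from sharedzotu.qc import (CascadeConfig, collapse_taxa, control_filter,
                           rare_filter, replicate_filter, run_cascade,
                           tag_jump_filter, target_filter)


BACT = ("Bacteria", "", "", "", "", "")


def test_control_filter_keeps_ties(table_builder, metadata_builder):
    """Sample cells with fewer reads than the control maximum are zeroed;
    a cell equal to the control level survives."""
    table = table_builder(
        {"z1": {"s1": 9, "s2": 10, "s3": 11, "ctl1": 10, "ctl2": 4},
         "z2": {"s1": 5, "s2": 0, "s3": 2, "ctl1": 0, "ctl2": 0}})
    meta = metadata_builder([
        ("s1", "a", "sp1", "none"), ("s2", "b", "sp1", "none"),
        ("s3", "c", "sp1", "none"),
        ("ctl1", "", "", "extraction"), ("ctl2", "", "", "pcr")])
    out = control_filter(table, meta)
    assert out.counts.loc["z1"].tolist() == [0, 10, 11]
    assert out.counts.loc["z2"].tolist() == [5, 0, 2]  # absent from controls
    assert "ctl1" not in out.counts.columns


def test_control_filter_without_controls_is_identity(table_builder, metadata_builder):
    table = table_builder({"z1": {"s1": 3}})
    meta = metadata_builder([("s1", "a", "sp1", "none")])
    out = control_filter(table, meta)
    pd.testing.assert_frame_equal(out.counts, table.counts)


def test_collapse_taxa_sums_same_lineage(table_builder):
    tax = {"z1": ("Bacteria", "", "", "", "", "Acinetobacter"),
           "z2": ("Bacteria", "", "", "", "", "Acinetobacter"),
           "z3": ("Bacteria", "", "", "", "", "Pseudomonas"),
           "z4": ("", "", "", "", "", ""),
           "z5": ("", "", "", "", "", "")}
    table = table_builder(
        {"z1": {"a": 5, "b": 3}, "z2": {"a": 2, "b": 0},
         "z3": {"a": 1, "b": 1}, "z4": {"a": 4, "b": 0},
         "z5": {"a": 0, "b": 6}}, tax)
    out = collapse_taxa(table)
    merged = out.counts[out.taxonomy["genus"] == "Acinetobacter"]
    assert merged.shape[0] == 1
    assert merged.iloc[0].tolist() == [7, 3]
    # fully unassigned rows stay distinct
    assert out.counts.shape[0] == 4
    assert out.total_reads == table.total_reads


def test_replicate_filter_requires_both_replicates(table_builder, metadata_builder):
    table = table_builder({"z1": {"a_r1": 30, "a_r2": 0},
                           "z2": {"a_r1": 30, "a_r2": 1},
                           "z3": {"a_r1": 0, "a_r2": 0}})
    meta = metadata_builder([("a_r1", "a", "sp1", "none"),
                             ("a_r2", "a", "sp1", "none")])
    out = replicate_filter(table, meta)
    assert list(out.counts.columns) == ["a"]
    assert out.counts["a"].tolist() == [0, 31, 0]


def test_tag_jump_threshold_is_strict(table_builder):
    """At a 10,000-read sample, 4 reads (0.04%) vanish and 5 (0.05%) stay."""
    table = table_builder({"z1": {"a": 4}, "z2": {"a": 5}, "z3": {"a": 9991}})
    out = tag_jump_filter(table, 0.0005)
    assert out.counts["a"].tolist() == [0, 5, 9991]
    ident = tag_jump_filter(table, 0.0)
    pd.testing.assert_frame_equal(ident.counts, table.counts)


def test_target_filter_domains_and_chloroplast(table_builder):
    tax = {"z1": ("Viridiplantae", "", "", "", "", ""),
           "z2": ("Bacteria", "Cyanobacteria", "Chloroplast", "", "", ""),
           "z3": ("Bacteria", "Firmicutes", "Bacilli", "", "", ""),
           "z4": ("Archaea", "", "", "", "", ""),
           "z5": ("", "", "", "", "", "")}
    table = table_builder({z: {"a": 10} for z in tax}, tax)
    out = target_filter(table)
    assert sorted(out.counts.index) == ["z3", "z4", "z5"]
    strict = target_filter(table, drop_unassigned_domain=True)
    assert sorted(strict.counts.index) == ["z3", "z4"]


def test_rare_filter_boundary(table_builder):
    table = table_builder({"z1": {"a": 19}, "z2": {"a": 20}, "z3": {"a": 0}})
    out = rare_filter(table, 20)
    assert out.counts["a"].tolist() == [0, 20, 0]
    ident = rare_filter(table, 1)
    pd.testing.assert_frame_equal(ident.counts, table.counts)


@pytest.mark.parametrize("stage", [
    lambda t: tag_jump_filter(t, 0.0005),
    lambda t: rare_filter(t, 20),
    lambda t: target_filter(t),
    lambda t: collapse_taxa(t),
])
def test_stages_are_idempotent(stage, table_builder):
    tax = {"z1": BACT, "z2": ("Bacteria", "", "", "", "", "G1"),
           "z3": ("Viridiplantae", "", "", "", "", "")}
    table = table_builder({"z1": {"a": 4, "b": 100}, "z2": {"a": 5000, "b": 25},
                           "z3": {"a": 12, "b": 3}}, tax)
    once = stage(table)
    twice = stage(once)
    pd.testing.assert_frame_equal(once.counts, twice.counts)


def test_tag_jump_and_rare_do_not_commute(table_builder):
    """Denominators freeze at stage entry, so removing sub-threshold rare
    counts first lowers the total and rescues a borderline cell."""
    counts = {"big": {"a": 95202}, "mid": {"a": 48}}
    for i in range(250):
        counts[f"tiny{i}"] = {"a": 19}
    table = table_builder(counts)
    # total = 100000; 48/100000 < 5e-4 -> tag-jump first removes "mid"
    tag_then_rare = rare_filter(tag_jump_filter(table, 0.0005), 20)
    assert tag_then_rare.counts.loc["mid", "a"] == 0
    # rare first leaves total 95250; 48/95250 >= 5e-4 -> "mid" survives
    rare_then_tag = tag_jump_filter(rare_filter(table, 20), 0.0005)
    assert rare_then_tag.counts.loc["mid", "a"] == 48


def test_cascade_order_report_and_monotone_reads(table_builder, metadata_builder):
    """Each stage removes what the fixture plants for it; reads retained are
    non-increasing and the report tracks every stage."""
    def bact(genus):
        return ("Bacteria", "", "", "", "", genus)

    tax = {"ctl_hit": bact("Ctl"),
           "dup_a": bact("Dup"),
           "dup_b": bact("Dup"),
           "single_rep": bact("Single"),
           "tagjump": bact("Tag"),
           "plant": ("Viridiplantae", "", "", "", "", ""),
           "rare": bact("Rare"),
           "solid": bact("Solid")}
    table = table_builder(
        {"ctl_hit":    {"a_r1": 3, "a_r2": 40, "b_r1": 40, "b_r2": 40, "ctl": 5},
         "dup_a":      {"a_r1": 30, "a_r2": 30, "b_r1": 25, "b_r2": 25, "ctl": 0},
         "dup_b":      {"a_r1": 30, "a_r2": 30, "b_r1": 0,  "b_r2": 0,  "ctl": 0},
         "single_rep": {"a_r1": 500, "a_r2": 0, "b_r1": 0,  "b_r2": 0,  "ctl": 0},
         "tagjump":    {"a_r1": 6,  "a_r2": 5, "b_r1": 0,  "b_r2": 0,  "ctl": 0},
         "plant":      {"a_r1": 600, "a_r2": 700, "b_r1": 0, "b_r2": 0, "ctl": 0},
         "rare":       {"a_r1": 9, "a_r2": 10, "b_r1": 0,  "b_r2": 0,  "ctl": 0},
         "solid":      {"a_r1": 15000, "a_r2": 15000, "b_r1": 9000, "b_r2": 9500,
                        "ctl": 0}},
        tax)
    meta = metadata_builder([
        ("a_r1", "a", "sp1", "none"), ("a_r2", "a", "sp1", "none"),
        ("b_r1", "b", "sp2", "none"), ("b_r2", "b", "sp2", "none"),
        ("ctl", "", "", "extraction")])
    out, report = run_cascade(table, meta)
    reads = [report.initial_reads] + [s["reads_retained"] for s in report.stages]
    assert all(x >= y for x, y in zip(reads, reads[1:]))
    assert [s["stage"] for s in report.stages] == [
        "control_filter", "collapse_taxa", "replicate_filter",
        "tag_jump_filter", "target_filter", "rare_filter"]
    assert report.final_reads == out.total_reads
    assert "plant" not in out.counts.index
    assert "single_rep" not in out.counts.index
    assert "rare" not in out.counts.index
    assert out.counts.loc["ctl_hit", "a"] == 0  # 3 < control level 5, pair broken
    merged = out.counts[out.taxonomy["genus"] == "Dup"]
    assert merged.shape[0] == 1 and merged.iloc[0].tolist() == [120, 50]


def test_cascade_empty_result_is_valid(table_builder, metadata_builder):
    table = table_builder({"z1": {"a_r1": 5, "a_r2": 0}})
    meta = metadata_builder([("a_r1", "a", "sp1", "none"),
                             ("a_r2", "a", "sp1", "none")])
    out, report = run_cascade(table, meta)
    assert out.counts.size == 0
    assert report.final_reads == 0
    assert len(report.stages) == 6


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.lists(st.integers(0, 200), min_size=4, max_size=4),
                min_size=1, max_size=8))
def test_cascade_reads_monotone_property(rows):
    """On arbitrary small tables the retained-read sequence never increases
    and row order does not affect the final table."""
    counts = {f"z{i}": {"a_r1": r[0], "a_r2": r[1], "b_r1": r[2], "b_r2": r[3]}
              for i, r in enumerate(rows)}
    from conftest import make_metadata, make_table
    table = make_table(counts, {z: BACT for z in counts})
    meta = make_metadata([
        ("a_r1", "a", "sp1", "none"), ("a_r2", "a", "sp1", "none"),
        ("b_r1", "b", "sp2", "none"), ("b_r2", "b", "sp2", "none")])
    out, report = run_cascade(table, meta)
    reads = [report.initial_reads] + [s["reads_retained"] for s in report.stages]
    assert all(x >= y for x, y in zip(reads, reads[1:]))
    # permuting rows changes nothing up to row order
    perm = list(reversed(list(counts)))
    table2 = make_table({z: counts[z] for z in perm}, {z: BACT for z in perm})
    out2, _ = run_cascade(table2, meta)
    pd.testing.assert_frame_equal(out.counts.sort_index(), out2.counts.sort_index())
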