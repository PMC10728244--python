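"""Post-denoising QC cascade for replicated ZOTU count tables.

Stages, in cascade order:

1. ``control_filter`` — zero any sample cell with fewer reads of a ZOTU than
   the extraction/PCR controls carry for that ZOTU, then drop control columns.
2. ``collapse_taxa`` — merge rows assigned to an identical full lineage.
3. ``replicate_filter`` — within each individual's replicate pair, zero taxa
   detected in only one replicate, then sum the pair into one column.
4. ``tag_jump_filter`` — zero cells below a per-sample proportional threshold
   (default 0.05% of the sample's total), mitigating cross-sample tag jumps.
5. ``target_filter`` — keep only Bacteria/Archaea, excluding class Chloroplast.
6. ``rare_filter`` — zero very rare occurrences (count below 20 by default).

Stages zero cells in place conceptually; rows/columns that end up all-zero are
dropped only at cascade end so that the audit report can attribute removed
occurrences to stages. Boundary semantics are strict ``<`` throughout: ties
survive every filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CountTable, RANKS, SampleMetadata, ValidationError

logger = logging.getLogger("sharedzotu")

TARGET_DOMAINS = frozenset({"Bacteria", "Archaea"})
EXCLUDED_CLASSES = frozenset({"Chloroplast"})


@dataclass
class FilterReport:
    """Per-stage audit of the cascade: reads retained and occurrences removed."""

    initial_reads: int
    stages: list = field(default_factory=list)  # (stage, reads_retained, occ_removed)
    final_reads: int = 0

    def record(self, stage: str, before: CountTable, after: CountTable) -> None:
        removed = before.n_occurrences - after.n_occurrences
        self.stages.append(
            {"stage": stage, "reads_retained": after.total_reads,
             "occurrences_removed": int(removed)}
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CascadeConfig:
    """Tunable thresholds of the cascade (defaults follow the study design)."""

    min_count: int = 20
    tag_jump_threshold: float = 0.0005
    control_agg: str = "max"           # how control counts aggregate: max | sum
    drop_unassigned_domain: bool = False
    taxonomy_delimiter: str = ","
    tag_jump_before_replicate: bool = False


def control_filter(table: CountTable, metadata: SampleMetadata,
                   agg: str = "max") -> CountTable:
    """Zero sample cells with fewer reads than the controls show for that ZOTU.

    For each ZOTU, the control level ``c`` is the ``agg`` (default maximum,
    the conservative choice) of its counts across all control replicates;
    sample cells with count < c are zeroed (ties survive). Control columns
    are dropped afterwards. With no controls present the stage is skipped
    with a warning.
    """
    controls = [c for c in metadata.control_replicates if c in table.counts.columns]
    sample_cols = [c for c in table.counts.columns if c not in set(controls)]
    if not controls:
        logger.warning("control_filter: no control replicates present; stage skipped")
        return CountTable(table.counts[sample_cols].copy(), table.taxonomy.copy())
    if agg == "max":
        level = table.counts[controls].max(axis=1)
    elif agg == "sum":
        level = table.counts[controls].sum(axis=1)
    else:
        raise ValueError(f"unknown control aggregation {agg!r}")
    counts = table.counts[sample_cols].copy()
    counts = counts.where(counts.ge(level, axis=0), 0)
    return CountTable(counts, table.taxonomy.copy())


def collapse_taxa(table: CountTable, delimiter: str = ",") -> CountTable:
    """Merge rows whose full lineage is identical, summing their counts.

    Rows unassigned at every rank carry no taxonomic identity and are kept
    distinct under their original ids; merged rows adopt the lineage string
    as their id. Total reads are conserved by this stage.
    """
    lineages = table.lineages(delimiter)
    assigned = lineages.str.replace(delimiter, "", regex=False).str.len() > 0
    key = lineages.where(assigned, other=pd.Series(table.counts.index.map(str),
                                                   index=table.counts.index))
    counts = table.counts.groupby(key, sort=False).sum()
    tax = table.taxonomy.groupby(key, sort=False).first()
    # groups of one keep their original id; only genuinely merged rows adopt
    # the lineage string as their id
    sizes = key.value_counts()
    first_member = {}
    for orig, k in key.items():
        first_member.setdefault(k, orig)
    rename = {k: first_member[k] for k in counts.index if sizes[k] == 1}
    counts = counts.rename(index=rename)
    tax = tax.rename(index=rename)
    return CountTable(counts, tax)


def replicate_filter(table: CountTable, metadata: SampleMetadata) -> CountTable:
    """Keep taxa detected in both replicates of an individual; sum the pair.

    The output has one column per individual. An individual with a number of
    replicates other than two is an error.
    """
    pairs = metadata.replicate_pairs()
    merged = {}
    for ind, (r1, r2) in pairs.items():
        for rep in (r1, r2):
            if rep not in table.counts.columns:
                raise ValidationError(
                    f"replicate {rep!r} of individual {ind!r} missing from table"
                )
        c1 = table.counts[r1]
        c2 = table.counts[r2]
        both = (c1 > 0) & (c2 > 0)
        merged[ind] = (c1 + c2).where(both, 0)
    counts = pd.DataFrame(merged)
    return CountTable(counts, table.taxonomy.copy())


def tag_jump_filter(table: CountTable, threshold: float = 0.0005) -> CountTable:
    """Zero cells below ``threshold`` of their sample's total reads.

    Denominators are the column totals at stage entry — they are not
    recomputed as cells are removed, reading "proportion of the total reads
    in one sample" as a fixed per-sample total. Strictly less-than: a cell
    exactly at the threshold is retained.
    """
    totals = table.counts.sum(axis=0)
    safe = totals.replace(0, 1)  # all-zero columns have nothing to remove
    frac = table.counts.div(safe, axis=1)
    counts = table.counts.where(frac.ge(threshold) | (table.counts == 0), 0)
    return CountTable(counts, table.taxonomy.copy())


def target_filter(table: CountTable, drop_unassigned_domain: bool = False) -> CountTable:
    """Keep Bacteria/Archaea rows; remove class Chloroplast.

    Rows with an unassigned domain are retained unless
    ``drop_unassigned_domain`` is set.
    """
    domain = table.taxonomy["domain"]
    klass = table.taxonomy["class"]
    keep = domain.isin(TARGET_DOMAINS)
    if not drop_unassigned_domain:
        keep |= domain == ""
    keep &= ~klass.isin(EXCLUDED_CLASSES)
    return CountTable(table.counts[keep].copy(), table.taxonomy[keep].copy())


def rare_filter(table: CountTable, min_count: int = 20) -> CountTable:
    """Zero very rare occurrences: cells with 0 < count < ``min_count``."""
    counts = table.counts.where(
        (table.counts == 0) | (table.counts >= min_count), 0
    )
    return CountTable(counts, table.taxonomy.copy())


def drop_empty(table: CountTable) -> CountTable:
    """Drop all-zero rows and columns (cascade end)."""
    row_keep = table.counts.sum(axis=1) > 0
    col_keep = table.counts.sum(axis=0) > 0
    n_rows = int((~row_keep).sum())
    n_cols = int((~col_keep).sum())
    if n_rows or n_cols:
        logger.info("dropping %d empty row(s) and %d empty column(s)", n_rows, n_cols)
    return CountTable(table.counts.loc[row_keep, col_keep].copy(),
                      table.taxonomy[row_keep].copy())


def run_cascade(table: CountTable, metadata: SampleMetadata,
                config: CascadeConfig | None = None):
    """Apply the full cascade in order; return the final table and its report.

    Order: controls -> taxonomy collapse -> replicate consistency ->
    tag-jump proportion -> domain/class targets -> rare occurrences. The
    tag-jump stage can optionally be moved before replicate merging
    (``tag_jump_before_replicate``); the default order applies it to the
    summed per-individual totals.
    """
    config = config or CascadeConfig()
    report = FilterReport(initial_reads=table.total_reads)

    def stage(name, func, tab):
        out = func(tab)
        report.record(name, tab, out)
        return out

    out = stage("control_filter",
                lambda t: control_filter(t, metadata, config.control_agg), table)
    out = stage("collapse_taxa",
                lambda t: collapse_taxa(t, config.taxonomy_delimiter), out)
    if config.tag_jump_before_replicate:
        out = stage("tag_jump_filter",
                    lambda t: tag_jump_filter(t, config.tag_jump_threshold), out)
        out = stage("replicate_filter", lambda t: replicate_filter(t, metadata), out)
    else:
        out = stage("replicate_filter", lambda t: replicate_filter(t, metadata), out)
        out = stage("tag_jump_filter",
                    lambda t: tag_jump_filter(t, config.tag_jump_threshold), out)
    out = stage("target_filter",
                lambda t: target_filter(t, config.drop_unassigned_domain), out)
    out = stage("rare_filter", lambda t: rare_filter(t, config.min_count), out)
    out = drop_empty(out)
    report.final_reads = out.total_reads
    return out, report
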