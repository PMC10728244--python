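"""Domain containers and plain-text IO for ZOTU occurrence analysis.

The analysis operates on three containers:

* :class:`CountTable` — a ZOTU x replicate (or, after replicate merging,
  ZOTU x individual) matrix of non-negative read counts, with a ranked
  taxonomy lineage per ZOTU (domain down to genus; ranks may be unassigned).
* :class:`OccurrenceMatrix` — the binary ZOTU x individual incidence matrix
  with the host-species partition of individuals. All occurrence statistics
  (richness, sharedness, null models, dissimilarities) are computed on it.
* :class:`RRAMatrix` — per-individual relative read abundances, used only for
  core-ZOTU ranking and class-level composition.

Matrix orientation is ZOTU-rows x sample-columns everywhere; "row sums" always
means per-ZOTU incidence counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sharedzotu")

#: Taxonomic ranks carried for every ZOTU, most to least inclusive. The
#: reference database underlying typical 16S assignments stops at genus.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

CONTROL_KINDS = ("none", "extraction", "pcr")


class ValidationError(ValueError):
    """Raised when an input table or metadata sheet violates an invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountTable:
    """ZOTU x sample read counts plus per-ZOTU taxonomy.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer matrix, index = unique ZOTU ids, columns =
        unique replicate (or individual) ids.
    taxonomy : DataFrame
        One row per ZOTU (same index as ``counts``), columns :data:`RANKS`;
        empty string marks an unassigned rank.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate ZOTU id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at ZOTU {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}: {arr[i, j]}"
            )
        if not self.counts.index.equals(self.taxonomy.index):
            self.taxonomy = self.taxonomy.reindex(self.counts.index)
            if self.taxonomy.isna().any().any():
                missing = self.taxonomy.index[self.taxonomy.isna().any(axis=1)][0]
                raise ValidationError(f"taxonomy missing for ZOTU {missing!r}")
        self.counts = self.counts.astype(np.int64)
        self.taxonomy = self.taxonomy.astype(str)

    @property
    def zotu_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_occurrences(self) -> int:
        """Number of non-zero ZOTU x sample cells."""
        return int((self.counts.to_numpy() > 0).sum())

    def lineages(self, delimiter: str = ",") -> pd.Series:
        """Full lineage string per ZOTU (ranks joined by ``delimiter``)."""
        return self.taxonomy[list(RANKS)].agg(delimiter.join, axis=1)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.taxonomy.copy())


@dataclass
class SampleMetadata:
    """Replicate-level sample sheet.

    One row per replicate: ``individual_id`` (empty for controls),
    ``host_species`` (empty for controls) and ``control_kind`` in
    ``{"none", "extraction", "pcr"}``. Each non-control individual must have
    exactly two replicates and one host species.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual_id", "host_species", "control_kind"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing column(s): {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate replicate id in metadata: {dup!r}")
        bad = set(self.table["control_kind"]) - set(CONTROL_KINDS)
        if bad:
            raise ValidationError(f"unknown control_kind value(s): {sorted(bad)}")
        samples = self.table[self.table["control_kind"] == "none"]
        for ind, grp in samples.groupby("individual_id"):
            if grp["host_species"].nunique() != 1:
                raise ValidationError(f"individual {ind!r} has multiple host species")

    @property
    def is_control(self) -> pd.Series:
        return self.table["control_kind"] != "none"

    @property
    def control_replicates(self) -> list:
        return list(self.table.index[self.is_control])

    @property
    def sample_replicates(self) -> list:
        return list(self.table.index[~self.is_control])

    @property
    def individuals(self) -> list:
        return list(dict.fromkeys(self.table.loc[~self.is_control, "individual_id"]))

    def species_of(self) -> pd.Series:
        """individual_id -> host_species for non-control individuals."""
        samples = self.table[~self.is_control]
        return samples.groupby("individual_id", sort=False)["host_species"].first()

    def replicate_pairs(self) -> dict:
        """individual_id -> tuple of its replicate ids; validates exactly 2."""
        samples = self.table[~self.is_control]
        pairs = {}
        for ind, grp in samples.groupby("individual_id", sort=False):
            if len(grp) != 2:
                raise ValidationError(
                    f"individual {ind!r} has {len(grp)} replicates; expected 2"
                )
            pairs[ind] = tuple(grp.index)
        return pairs


@dataclass
class OccurrenceMatrix:
    """Binary ZOTU x individual incidence matrix with a species partition."""

    presence: pd.DataFrame
    partition: pd.Series  # individual_id -> host_species

    def __post_init__(self) -> None:
        arr = self.presence.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("presence matrix entries must be 0 or 1")
        self.presence = self.presence.astype(np.int8)
        self.partition = self.partition.reindex(self.presence.columns)
        if self.partition.isna().any():
            missing = self.partition.index[self.partition.isna()][0]
            raise ValidationError(f"individual {missing!r} missing from partition")

    @property
    def zotu_ids(self) -> list:
        return list(self.presence.index)

    @property
    def individual_ids(self) -> list:
        return list(self.presence.columns)

    @property
    def species(self) -> list:
        """Species labels in first-appearance order."""
        return list(dict.fromkeys(self.partition))

    def species_columns(self, species: str) -> list:
        cols = [c for c in self.presence.columns if self.partition[c] == species]
        if not cols:
            raise KeyError(f"unknown host species {species!r}")
        return cols

    def species_incidence(self) -> pd.DataFrame:
        """ZOTU x species matrix of incidence counts (individuals occupied)."""
        return self.presence.T.groupby(self.partition, sort=False).sum().T

    def copy(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.presence.copy(), self.partition.copy())


@dataclass
class RRAMatrix:
    """Relative read abundances per ZOTU per individual; columns sum to 1."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size:
            colsums = arr.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-9):
                j = int(np.argmax(np.abs(colsums - 1.0)))
                raise ValidationError(
                    f"RRA column {self.values.columns[j]!r} sums to {colsums[j]}"
                )


# ---------------------------------------------------------------------------
# conversions


def to_occurrence(table: CountTable, metadata: SampleMetadata) -> OccurrenceMatrix:
    """Binarize a per-individual count table (presence iff count > 0).

    All count thresholds belong to the QC cascade; here strictly positive
    counts mark presence. All-zero rows and columns are dropped with a logged
    warning (they carry no occurrence information).
    """
    presence = (table.counts > 0).astype(np.int8)
    row_keep = presence.sum(axis=1) > 0
    col_keep = presence.sum(axis=0) > 0
    n_rows_dropped = int((~row_keep).sum())
    n_cols_dropped = int((~col_keep).sum())
    if n_rows_dropped:
        logger.warning("dropping %d all-zero ZOTU row(s)", n_rows_dropped)
    if n_cols_dropped:
        dropped = list(presence.columns[~col_keep])
        logger.warning("dropping %d all-zero individual column(s): %s",
                       n_cols_dropped, dropped)
    presence = presence.loc[row_keep, col_keep]
    species = metadata.species_of()
    unknown = [c for c in presence.columns if c not in species.index]
    if unknown:
        raise ValidationError(f"individual {unknown[0]!r} absent from metadata")
    return OccurrenceMatrix(presence, species.loc[list(presence.columns)])


def to_rra(table: CountTable) -> RRAMatrix:
    """Divide each column by its total. Zero-total columns are an error."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero[0]!r} has zero total reads")
    return RRAMatrix(table.counts / totals)


# ---------------------------------------------------------------------------
# IO

DEFAULT_COLUMN_MAP = {"zotu_id": "zotu_id", "taxonomy": "taxonomy"}


def read_metadata(path) -> SampleMetadata:
    """Read the replicate sample sheet (CSV)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "replicate_id" not in df.columns:
        raise ValidationError("metadata must have a 'replicate_id' column")
    df = df.set_index("replicate_id")
    if "control_kind" in df.columns:
        df["control_kind"] = df["control_kind"].replace("", "none")
    return SampleMetadata(df)


def read_count_table(path, metadata_path=None, *, column_map=None,
                     taxonomy_delimiter: str = ","):
    """Read a ZOTU table (TSV) and, optionally, its sample metadata (CSV).

    The TSV layout is one header row of sample ids plus an id column and a
    taxonomy column; deposited tables with different header names are
    accommodated through ``column_map`` (mapping the logical names
    ``zotu_id`` and ``taxonomy`` to the file's column names) rather than by
    editing the file.

    Returns ``CountTable`` or ``(CountTable, SampleMetadata)`` when
    ``metadata_path`` is given; replicate ids in counts and metadata are
    reconciled (every count column must appear in the metadata and vice
    versa).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in ("zotu_id", "taxonomy"):
        if cmap[logical] not in df.columns:
            raise ValidationError(
                f"count table missing {logical!r} column {cmap[logical]!r}"
            )
    df = df.set_index(cmap["zotu_id"])
    df.index.name = None
    tax = parse_lineages(df.pop(cmap["taxonomy"]), delimiter=taxonomy_delimiter)
    try:
        counts = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count in table: {exc}") from exc
    table = CountTable(counts, tax)
    if metadata_path is None:
        return table
    metadata = read_metadata(metadata_path)
    only_meta = set(metadata.table.index) - set(table.sample_ids)
    only_table = set(table.sample_ids) - set(metadata.table.index)
    if only_meta:
        raise ValidationError(
            f"replicate {sorted(only_meta)[0]!r} in metadata but not in count table"
        )
    if only_table:
        raise ValidationError(
            f"replicate {sorted(only_table)[0]!r} in count table but not in metadata"
        )
    return table, metadata


def parse_lineages(lineages: pd.Series, delimiter: str = ",") -> pd.DataFrame:
    """Split delimiter-joined domain..genus strings into a rank table."""
    parts = lineages.str.split(delimiter, expand=True)
    parts = parts.reindex(columns=range(len(RANKS))).fillna("")
    parts.columns = list(RANKS)
    return parts.apply(lambda s: s.str.strip())


def write_count_table(table: CountTable, path, *, taxonomy_delimiter: str = ",") -> None:
    out = table.counts.copy()
    out.insert(0, "taxonomy", table.lineages(taxonomy_delimiter))
    out.index.name = "zotu_id"
    out.to_csv(path, sep="\t")


def write_occurrence(matrix: OccurrenceMatrix, path) -> None:
    out = matrix.presence.copy()
    out.index.name = "zotu_id"
    out.to_csv(path, sep="\t")


def read_occurrence(path, metadata_path) -> OccurrenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="zotu_id")
    df.index.name = None
    metadata = read_metadata(metadata_path)
    species = metadata.species_of()
    return OccurrenceMatrix(df, species.loc[list(df.columns)])


def write_rra(rra: RRAMatrix, path) -> None:
    out = rra.values.copy()
    out.index.name = "zotu_id"
    out.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
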