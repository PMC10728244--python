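"""Shared fixtures: toy tables, a vegan-verified reference matrix, and a
brute-force enumerator of fixed-margin binary matrices."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sharedzotu.core import CountTable, OccurrenceMatrix, RANKS, SampleMetadata


def make_table(counts: dict, taxonomy: dict | None = None) -> CountTable:
    """CountTable from {zotu_id: {sample: count}} and {zotu_id: lineage-tuple}."""
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    taxonomy = taxonomy or {}
    tax = pd.DataFrame(
        [list(taxonomy.get(z, ("",) * len(RANKS))) for z in df.index],
        index=df.index, columns=list(RANKS))
    return CountTable(df, tax)


def make_metadata(rows) -> SampleMetadata:
    """SampleMetadata from (replicate, individual, species, control_kind) rows."""
    df = pd.DataFrame(rows, columns=["replicate_id", "individual_id",
                                     "host_species", "control_kind"])
    return SampleMetadata(df.set_index("replicate_id"))


def make_occurrence(arr, species_of_column) -> OccurrenceMatrix:
    arr = np.asarray(arr)
    cols = [f"i{j}" for j in range(arr.shape[1])]
    presence = pd.DataFrame(arr, index=[f"z{i}" for i in range(arr.shape[0])],
                            columns=cols)
    return OccurrenceMatrix(presence,
                            pd.Series(list(species_of_column), index=cols))


def enumerate_fixed_margin(row_sums, col_sums):
    """All binary matrices with the given margins (brute force)."""
    nr, nc = len(row_sums), len(col_sums)
    out = []

    def rec(i, cols_left, rows):
        if i == nr:
            if all(x == 0 for x in cols_left):
                out.append(np.array(rows))
            return
        for combo in itertools.combinations(range(nc), row_sums[i]):
            if all(cols_left[j] > 0 for j in combo):
                nl = list(cols_left)
                row = [0] * nc
                for j in combo:
                    row[j] = 1
                    nl[j] -= 1
                rec(i + 1, nl, rows + [row])

    rec(0, list(col_sums), [])
    return out


@pytest.fixture
def table_builder():
    return make_table


@pytest.fixture
def metadata_builder():
    return make_metadata


@pytest.fixture
def occurrence_builder():
    return make_occurrence


@pytest.fixture
def margin_enumerator():
    return enumerate_fixed_margin


#: 8 ZOTUs x 6 individuals; reference values below were computed with the
#: standard R ecology toolkit (vegan 2.7-1: specpool, vegdist on binary data,
#: betadisper type="centroid" + anova, adonis2) and frozen here.
VEGAN_MATRIX = np.array([
    [1, 0, 1, 1, 1, 0],
    [1, 0, 1, 1, 1, 0],
    [1, 0, 0, 0, 0, 0],
    [1, 0, 0, 1, 1, 0],
    [1, 0, 0, 0, 0, 1],
    [1, 1, 0, 0, 0, 0],
    [1, 1, 0, 1, 0, 1],
    [0, 1, 1, 1, 1, 1],
])

VEGAN_REFERENCE = {
    "groups": ["a", "a", "a", "b", "b", "b"],
    "specpool": {"s_obs": 8, "chao": 8.208333, "chao_se": 0.6353313,
                 "jack1": 8.833333, "jack1_se": 0.8333333, "n": 6},
    "betadisper_distances": [0.33259177, 0.37251232, 0.37251232,
                             0.04012103, 0.29722784, 0.40934399],
    "betadisper_anova": {"f": 1.0038, "p": 0.3731, "df1": 1, "df2": 4},
    "adonis2": {"f": 0.1439, "r2": 0.03473, "ss_model": 0.02323,
                "ss_total": 0.66890},
    # vegdist(..., "bray") on presence/absence == Sørensen
    "distances": np.array([
        [0.0000000, 0.6000000, 0.6000000, 0.3333333, 0.4545455, 0.6000000],
        [0.6000000, 0.0000000, 0.6666667, 0.5000000, 0.7142857, 0.3333333],
        [0.6000000, 0.6666667, 0.0000000, 0.2500000, 0.1428571, 0.6666667],
        [0.3333333, 0.5000000, 0.2500000, 0.0000000, 0.1111111, 0.5000000],
        [0.4545455, 0.7142857, 0.1428571, 0.1111111, 0.0000000, 0.7142857],
        [0.6000000, 0.3333333, 0.6666667, 0.5000000, 0.7142857, 0.0000000],
    ]),
}


@pytest.fixture
def vegan_case():
    return VEGAN_MATRIX.copy(), dict(VEGAN_REFERENCE)
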