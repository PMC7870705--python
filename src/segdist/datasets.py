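"""Published genotype-count tables from the rice S22A/S22B complementation study.

These are the printed T1 segregation counts from the map-based cloning
of the two gametophytic pollen-sterility loci on rice chromosome 2, in
hybrids between the japonica cultivar Taichung 65 and the wild species
*Oryza glumaepatula*.  Each row is one selfed T1 family genotyped at an
SSR marker tightly linked to the sterility locus: ``n_TT`` homozygous
cultivated, ``n_TG`` heterozygous, ``n_GG`` homozygous wild.

``s22b_complementation_counts`` covers the S22B candidate-fragment
transformants (plus the non-transgenic control family), scored at
RM7033; ``s22a_complementation_counts`` covers the three S22A candidate
genes (plus an empty-vector control), scored at SSR23.
"""

from __future__ import annotations

import pandas as pd

from .core import SegregationCounts

__all__ = [
    "s22b_complementation_counts",
    "s22a_complementation_counts",
    "S22B_CONTROL_ID",
    "counts_from_row",
]

#: population_id of the non-transgenic control family in the S22B table.
S22B_CONTROL_ID = "non_transgenic"

_S22B_ROWS = [
    # (population_id, construct, n_TT, n_TG, n_GG)
    ("Eco72I", "Eco72I fragment", 13, 20, 0),
    ("XmnI_a", "XmnI_a fragment", 26, 21, 5),
    ("SalI", "SalI fragment", 18, 41, 19),
    ("XmnI_b", "XmnI_b fragment", 15, 12, 2),
    (S22B_CONTROL_ID, "non-transgenic control", 42, 43, 5),
]

_S22A_ROWS = [
    ("S22A_j1", "S22A_j1 fragment", 54, 57, 17),
    ("S22A_j2", "S22A_j2 fragment", 19, 20, 0),
    ("S22A_j3", "S22A_j3 fragment", 46, 55, 2),
    ("empty_vector", "empty-vector control", 35, 41, 0),
]


def _table(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["population_id", "group", "n_TT", "n_TG", "n_GG"]
    )[["population_id", "n_TT", "n_TG", "n_GG", "group"]]


def s22b_complementation_counts() -> pd.DataFrame:
    """T1 genotype counts at RM7033 for the S22B complementation test."""
    return _table(_S22B_ROWS)


def s22a_complementation_counts() -> pd.DataFrame:
    """T1 genotype counts at SSR23 for the S22A complementation test."""
    return _table(_S22A_ROWS)


def counts_from_row(row) -> SegregationCounts:
    """Build SegregationCounts from one row of a counts table."""
    return SegregationCounts(
        n_TT=int(row["n_TT"]), n_TG=int(row["n_TG"]), n_GG=int(row["n_GG"])
    )
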