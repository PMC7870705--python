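"""Readers and writers for the tabular genetics formats.

TSV is the tabular dialect throughout (the usual genetics-lab
convention): a counts table has columns ``population_id, n_TT, n_TG,
n_GG`` (plus an optional ``group`` label), and a marker-genotype table
has one row per plant with a ``plant_id`` column, one column per marker
in map order, and a trailing ``phenotype`` column.  ``-`` (or an empty
cell, ``.``, ``NA``) is the missing-genotype token.  JSON is the
canonical machine-readable result format; writers are deterministic
byte streams (sorted keys, fixed float formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .mapping import MarkerMap, RecombinantRecord

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_marker_tsv",
    "write_marker_tsv",
    "write_json",
    "dumps_json",
]

COUNT_COLUMNS = ("n_TT", "n_TG", "n_GG")
MISSING_TOKENS = ("-", "", ".", "NA")


class TableFormatError(ValueError):
    """Malformed tabular input; the message carries the line number."""


def read_counts_tsv(path) -> pd.DataFrame:
    """Read and validate a genotype-counts TSV.

    Requires a header with ``population_id`` and the three count
    columns; counts must parse as nonnegative integers and population
    ids must be unique.  Errors name the offending line and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(
            f"{path}: empty file; expected header with columns "
            f"population_id, {', '.join(COUNT_COLUMNS)}"
        ) from None
    missing = [c for c in ("population_id", *COUNT_COLUMNS) if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in COUNT_COLUMNS:
        for i, raw in enumerate(df[col]):
            line = i + 2  # header is line 1
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}:{line}: column {col}: {raw!r} is not an integer"
                ) from None
            if value < 0:
                raise TableFormatError(
                    f"{path}:{line}: column {col}: count must be nonnegative, got {value}"
                )
        df[col] = df[col].astype(int)
    dup = df["population_id"][df["population_id"].duplicated()]
    if not dup.empty:
        raise TableFormatError(
            f"{path}: duplicate population_id(s): {', '.join(sorted(set(dup)))}"
        )
    keep = ["population_id", *COUNT_COLUMNS] + (
        ["group"] if "group" in df.columns else []
    )
    return df[keep]


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_marker_tsv(path, marker_map: MarkerMap) -> list[RecombinantRecord]:
    """Read a per-plant marker-genotype TSV against a marker map.

    The marker columns must appear in exactly the map's order between
    ``plant_id`` and ``phenotype``; genotype codes are T/H/G with ``-``
    for missing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: empty file") from None
    expected = ["plant_id", *marker_map.names, "phenotype"]
    if list(df.columns) != expected:
        raise TableFormatError(
            f"{path}: columns {list(df.columns)} do not match the marker map order "
            f"{expected}"
        )
    records = []
    for i, row in df.iterrows():
        line = i + 2
        calls = [
            None if str(row[m]).strip() in MISSING_TOKENS else str(row[m])
            for m in marker_map.names
        ]
        try:
            records.append(
                RecombinantRecord(
                    plant_id=str(row["plant_id"]), calls=tuple(calls),
                    phenotype=str(row["phenotype"]),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path}:{line}: {exc}") from None
    return records


def write_marker_tsv(records: list[RecombinantRecord], marker_map: MarkerMap, path) -> None:
    rows = []
    for r in records:
        row = {"plant_id": r.plant_id}
        row.update(
            {m: (c if c is not None else "-") for m, c in zip(marker_map.names, r.calls)}
        )
        row["phenotype"] = r.phenotype
        rows.append(row)
    pd.DataFrame(rows, columns=["plant_id", *marker_map.names, "phenotype"]).to_csv(
        path, sep="\t", index=False
    )


def _round_floats(obj, sigfigs: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sigfigs}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sigfigs) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sigfigs) for v in obj]
    return obj


def dumps_json(obj, full_precision: bool = False) -> str:
    """Deterministic JSON: sorted keys, floats at 6 significant digits by default."""
    if not full_precision:
        obj = _round_floats(obj)
    return json.dumps(obj, sort_keys=True, indent=2) + "\n"


def write_json(obj, path, full_precision: bool = False) -> None:
    Path(path).write_text(dumps_json(obj, full_precision=full_precision))
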