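"""Tab-separated I/O for observation records.

All tables are UTF-8, tab-separated, "." decimal, with a fixed header
row. Floats are written with ``repr`` so write→read round-trips records
bit-exactly. Validation failures report 1-based data-row numbers (the
header is row 0).
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    BivalentRecord,
    ChiasmaRecord,
    FociRecord,
    SampleMeta,
    SchemaError,
    ValidationError,
    check_one_marker_per_slide,
)

CHIASMA_COLUMNS = ("sample_id", "cell_id", "bivalent_id", "arm_id", "rel_pos")
BIVALENT_COLUMNS = (
    "sample_id",
    "cell_id",
    "bivalent_id",
    "chiasma_count",
    "configuration",
    "subtype",
)
FOCI_COLUMNS = ("sample_id", "slide_id", "cell_id", "marker", "count")
SAMPLE_COLUMNS = (
    "sample_id",
    "display_label",
    "genome_composition",
    "expected_bivalents_per_cell",
)

_COLUMNS_BY_TYPE = {
    ChiasmaRecord: CHIASMA_COLUMNS,
    BivalentRecord: BIVALENT_COLUMNS,
    FociRecord: FOCI_COLUMNS,
    SampleMeta: SAMPLE_COLUMNS,
}


def _read_tsv(path: str | os.PathLike, columns: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{os.fspath(path)}: missing required column(s) {', '.join(missing)}"
        )
    return frame


def _parse_float(text: str, column: str, row: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{column} must be numeric, got {text!r}", row=row)


def _parse_int(text: str, column: str, row: int) -> int:
    try:
        value = float(text)
    except ValueError:
        raise ValidationError(f"{column} must be an integer, got {text!r}", row=row)
    if value != int(value):
        raise ValidationError(f"{column} must be an integer, got {text!r}", row=row)
    return int(value)


def _wrap_row(exc: ValidationError, row: int) -> ValidationError:
    if exc.row is None:
        return ValidationError(str(exc), row=row)
    return exc


def read_chiasma_table(path: str | os.PathLike) -> list[ChiasmaRecord]:
    """Read a ``chiasmata.tsv`` table into validated records (row order kept)."""
    frame = _read_tsv(path, CHIASMA_COLUMNS)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                ChiasmaRecord(
                    sample_id=row.sample_id,
                    cell_id=row.cell_id,
                    bivalent_id=row.bivalent_id,
                    arm_id=_parse_int(row.arm_id, "arm_id", i),
                    rel_pos=_parse_float(row.rel_pos, "rel_pos", i),
                )
            )
        except ValidationError as exc:
            raise _wrap_row(exc, i) from None
    return records


def read_bivalent_table(path: str | os.PathLike) -> list[BivalentRecord]:
    frame = _read_tsv(path, BIVALENT_COLUMNS)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                BivalentRecord(
                    sample_id=row.sample_id,
                    cell_id=row.cell_id,
                    bivalent_id=row.bivalent_id,
                    chiasma_count=_parse_int(row.chiasma_count, "chiasma_count", i),
                    configuration=row.configuration,
                    subtype=row.subtype,
                )
            )
        except ValidationError as exc:
            raise _wrap_row(exc, i) from None
    return records


def read_foci_table(path: str | os.PathLike) -> list[FociRecord]:
    """Read a ``foci.tsv`` table; also checks the one-marker-per-slide rule."""
    frame = _read_tsv(path, FOCI_COLUMNS)
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            records.append(
                FociRecord(
                    sample_id=row.sample_id,
                    slide_id=row.slide_id,
                    cell_id=row.cell_id,
                    marker=row.marker,
                    count=_parse_int(row.count, "count", i),
                )
            )
        except ValidationError as exc:
            raise _wrap_row(exc, i) from None
    check_one_marker_per_slide(records)
    return records


def read_sample_table(path: str | os.PathLike) -> list[SampleMeta]:
    frame = _read_tsv(path, SAMPLE_COLUMNS)
    records = []
    seen: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {row.sample_id!r}", row=i)
        seen.add(row.sample_id)
        try:
            records.append(
                SampleMeta(
                    sample_id=row.sample_id,
                    display_label=row.display_label,
                    genome_composition=row.genome_composition,
                    expected_bivalents_per_cell=_parse_int(
                        row.expected_bivalents_per_cell,
                        "expected_bivalents_per_cell",
                        i,
                    ),
                )
            )
        except ValidationError as exc:
            raise _wrap_row(exc, i) from None
    return records


def _cell_text(value) -> str:
    if isinstance(value, float):
        return repr(value)  # full precision; float(repr(x)) == x
    return str(value)


def write_table(records: Iterable, path: str | os.PathLike) -> None:
    """Write records of one type to TSV; inverse of the matching reader.

    An empty iterable is only writable when the record type cannot be
    inferred from an element, so empty collections should be written via
    the typed frames in practice — here we default to the chiasma schema
    when given a plain empty list of unknown type.
    """
    records = list(records)
    if records:
        rec_type = type(records[0])
        if rec_type not in _COLUMNS_BY_TYPE:
            raise TypeError(f"unsupported record type {rec_type.__name__}")
        if any(type(r) is not rec_type for r in records):
            raise TypeError("mixed record types in one table")
        columns = _COLUMNS_BY_TYPE[rec_type]
    else:
        columns = CHIASMA_COLUMNS
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write(
                "\t".join(_cell_text(getattr(rec, c)) for c in columns) + "\n"
            )


def write_empty_table(path: str | os.PathLike, columns: Sequence[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
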