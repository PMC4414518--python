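"""Readers and writers for count matrices, frequencies, and coordinates.

The on-disk dialect mirrors the traditional tabular layout of seriation
data: a header row of type names, a first column of assemblage ids, and
non-negative integer counts in the body. TSV is the default; the delimiter
is auto-detected between tab and comma and can be forced explicitly.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .types import AssemblageCounts, CoordinateTable, FrequencyMatrix, ValidationError


class ParseError(ValueError):
    """Raised when a cell of the input file cannot be interpreted."""


def _detect_delimiter(header_line: str) -> str:
    # Prefer tab if present; Table-2-style type names may contain commas
    # only when quoted, which the csv module handles either way.
    return "\t" if "\t" in header_line else ","


def read_counts(path: str | Path, delimiter: str | None = None) -> AssemblageCounts:
    """Read a delimited count matrix into a validated :class:`AssemblageCounts`.

    Row and column order are preserved from the file. Malformed cells,
    duplicate ids, fewer than three type columns, and zero row totals are
    all hard errors — a silently dropped or coerced row would invisibly
    change the solution space.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        delim = delimiter or _detect_delimiter(first)
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=delim))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    header = rows[0]
    type_names = tuple(name.strip() for name in header[1:])
    ids: list[str] = []
    counts: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        ids.append(row[0].strip())
        parsed = []
        for colno, cell in enumerate(row[1:]):
            text = cell.strip()
            try:
                value = int(text)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: column {type_names[colno]!r}: "
                    f"cannot parse {text!r} as a non-negative integer"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}:{lineno}: column {type_names[colno]!r}: "
                    f"negative count {value}"
                )
            parsed.append(value)
        counts.append(parsed)
    if not counts:
        raise ParseError(f"{path}: no data rows")
    return AssemblageCounts(
        assemblage_ids=tuple(ids), type_names=type_names, counts=counts
    )


def write_counts(
    counts: AssemblageCounts, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a count matrix in the same dialect ``read_counts`` consumes.

    Round-trips bit-identically for integer matrices.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["Assemblage", *counts.type_names])
        for aid, row in zip(counts.assemblage_ids, counts.counts):
            writer.writerow([aid, *(int(v) for v in row)])


def write_frequencies(
    freqs: FrequencyMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write proportions at 6 decimal places, with a trailing N column."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["Assemblage", *freqs.type_names, "N"])
        for aid, row, total in zip(freqs.assemblage_ids, freqs.freqs, freqs.row_totals):
            writer.writerow([aid, *(f"{v:.6f}" for v in row), int(total)])


def read_coordinates(path: str | Path) -> CoordinateTable:
    """Read a CSV of ``id,x,y`` planar coordinates (header optional)."""
    path = Path(path)
    coords: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 3:
                raise ParseError(f"{path}:{lineno}: expected id,x,y")
            aid = row[0].strip()
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ParseError(
                    f"{path}:{lineno}: cannot parse coordinates {row[1:3]!r}"
                ) from None
            if aid in coords:
                raise ValidationError(f"{path}:{lineno}: duplicate id {aid!r}")
            coords[aid] = (x, y)
    return CoordinateTable(coords=coords)


def write_coordinates(table: CoordinateTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "x", "y"])
        for aid, (x, y) in table.coords.items():
            writer.writerow([aid, repr(x), repr(y)])


def min_sample_check(counts: AssemblageCounts, min_n: int) -> list[str]:
    """Return the assemblage ids whose sample size falls below ``min_n``.

    Sample-size screening is traditionally a prior analytic step (a fixed
    floor such as 50 sherds), so this check is advisory: callers decide
    whether a failing id is dropped, reported, or escalated (``--strict-n``).
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    totals = counts.row_totals
    return [
        counts.assemblage_ids[i] for i in range(counts.n_assemblages)
        if totals[i] < min_n
    ]
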