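"""Reading and writing the BIDS TSV dialect.

Tab-separated values with a mandatory header line.  Missing values are
coded as the exact lowercase string ``n/a`` and surface in memory as the
:data:`~bidslite.core_model.MISSING` marker; cells containing tabs (or
double quotes) are escaped CSV-style with double quotes.  Matching of
``n/a`` is exact and case-sensitive — ``NA``, ``N/A`` and the empty string
are ordinary cells, which a validator heuristic flags later; the reader
itself never coerces them.

The quoting dialect is implemented here rather than delegated to a generic
CSV library because its contract is stricter: a cell is quoted if and only
if it contains a tab or a quote, and a newline inside a quoted cell is a
structured error rather than a row continuation.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass

from .core_model import MISSING, BidsError, MissingValue, Table

__all__ = ["TsvError", "read_tsv", "write_tsv"]

NA_TOKEN = "n/a"


class TsvError(BidsError):
    """Structured TSV parse error carrying the 1-based row number."""

    def __init__(self, message: str, row: int = 0):
        super().__init__(message)
        self.row = row


def _split_line(line: str, row: int) -> list[str]:
    """Split one physical line into cells, honouring double-quote escaping."""
    cells: list[str] = []
    buf: list[str] = []
    i, n = 0, len(line)
    in_quotes = False
    quoted_cell = False
    while i < n:
        ch = line[i]
        if in_quotes:
            if ch == '"':
                if i + 1 < n and line[i + 1] == '"':
                    buf.append('"')
                    i += 2
                    continue
                in_quotes = False
                i += 1
                continue
            buf.append(ch)
            i += 1
        else:
            if ch == '"' and not buf:
                in_quotes = True
                quoted_cell = True
                i += 1
            elif ch == "\t":
                cells.append("".join(buf))
                buf = []
                quoted_cell = False
                i += 1
            else:
                if quoted_cell:
                    raise TsvError(
                        f"unexpected character after closing quote in row {row}", row=row
                    )
                buf.append(ch)
                i += 1
    if in_quotes:
        raise TsvError(
            f"unterminated quote in row {row} (newlines inside quoted cells "
            "are not supported)",
            row=row,
        )
    cells.append("".join(buf))
    return cells


def read_tsv(payload: bytes | str, gz: bool = False) -> Table:
    """Parse a TSV payload into a :class:`Table`.

    The first line is the header.  Cells equal to ``n/a`` become the
    missing marker; everything else is kept verbatim.  A trailing newline
    is tolerated; ragged rows and empty files are structured errors.
    """
    if isinstance(payload, bytes):
        if gz or payload[:2] == b"\x1f\x8b":
            payload = gzip.decompress(payload)
        text = payload.decode("utf-8")
    else:
        text = payload
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    if text.endswith("\n"):
        text = text[:-1]
    if not text:
        raise TsvError("empty TSV: a header line is required", row=0)
    lines = text.split("\n")
    columns = _split_line(lines[0], 1)
    table_rows: list[list[object]] = []
    for idx, line in enumerate(lines[1:], start=2):
        cells = _split_line(line, idx)
        if len(cells) != len(columns):
            raise TsvError(
                f"row {idx} has {len(cells)} cells, expected {len(columns)}", row=idx
            )
        table_rows.append([MISSING if c == NA_TOKEN else c for c in cells])
    return Table(columns=columns, rows=table_rows)


def _format_cell(cell: object) -> str:
    if isinstance(cell, MissingValue):
        return NA_TOKEN
    s = str(cell)
    if "\n" in s:
        raise TsvError("newlines inside cells cannot be represented in TSV")
    if "\t" in s or '"' in s:
        return '"' + s.replace('"', '""') + '"'
    return s


def write_tsv(t: Table, gz: bool = False) -> bytes:
    """Serialize a :class:`Table`; inverse of :func:`read_tsv`.

    Missing markers become ``n/a``; cells containing tabs or quotes are
    double-quoted with internal quotes doubled.
    """
    lines = ["\t".join(_format_cell(c) for c in t.columns)]
    for row in t.rows:
        lines.append("\t".join(_format_cell(c) for c in row))
    data = ("\n".join(lines) + "\n").encode("utf-8")
    if gz:
        return gzip.compress(data, mtime=0)
    return data
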