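"""Output-analysis tools: raw hit records -> tab-delimited table -> SQL dump.

The kernel record dialect is one tab-separated line per record with the
fixed 8-column schema ``query_id, subject_id, score, q_start, q_end,
s_start, s_end, status`` (spans 0-based half-open; status one of hit /
no-hit / failed). Malformed lines never abort a parse; they are collected
in a reject list with their line numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .errors import ValidationError
from .outstore import RunManifest, reassemble

COLUMNS = (
    "query_id",
    "subject_id",
    "score",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "status",
)
_STATUSES = {"hit", "no-hit", "failed"}
_SQL_TYPES = {
    "query_id": "TEXT",
    "subject_id": "TEXT",
    "score": "REAL",
    "q_start": "INTEGER",
    "q_end": "INTEGER",
    "s_start": "INTEGER",
    "s_end": "INTEGER",
    "status": "TEXT",
}
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class RejectedLine:
    lineno: int
    line: str
    reason: str


@dataclass
class ParsedHits:
    """A hit table plus the lines that failed to parse."""

    table: pd.DataFrame
    rejects: list[RejectedLine]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query_id": pd.Series(dtype=str),
            "subject_id": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "q_start": pd.Series(dtype=int),
            "q_end": pd.Series(dtype=int),
            "s_start": pd.Series(dtype=int),
            "s_end": pd.Series(dtype=int),
            "status": pd.Series(dtype=str),
        }
    )


def _sort(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(
        ["query_id", "score"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)


def hits_to_table(records: Iterable) -> ParsedHits:
    """Parse a record stream into the fixed 8-column hit table.

    ``records`` may be payload lines (str/bytes) or ``(query_id, payload)``
    pairs as produced by :func:`seqfarm.outstore.reassemble`. Rows are
    ordered by (query_id asc, score desc); ordering is deterministic.
    """
    rows: list[tuple] = []
    rejects: list[RejectedLine] = []
    for lineno, item in enumerate(records, start=1):
        payload = item[1] if isinstance(item, tuple) else item
        line = payload.decode("utf-8") if isinstance(payload, bytes) else str(payload)
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(COLUMNS):
            rejects.append(
                RejectedLine(lineno, line, f"expected 8 fields, got {len(fields)}")
            )
            continue
        qid, sid, score, qs, qe, ss, se, status = fields
        try:
            parsed = (qid, sid, float(score), int(qs), int(qe), int(ss), int(se), status)
        except ValueError as exc:
            rejects.append(RejectedLine(lineno, line, f"bad numeric field: {exc}"))
            continue
        if status not in _STATUSES:
            rejects.append(RejectedLine(lineno, line, f"unknown status {status!r}"))
            continue
        rows.append(parsed)
    if not rows:
        return ParsedHits(_empty_table(), rejects)
    table = pd.DataFrame(rows, columns=list(COLUMNS))
    return ParsedHits(_sort(table), rejects)


def manifest_to_table(manifest: RunManifest) -> ParsedHits:
    """Parse a whole run: reassembled results plus failure rows."""
    parsed = hits_to_table(reassemble(manifest))
    if manifest.failures:
        failure_rows = pd.DataFrame(
            [(qid, "-", 0.0, 0, 0, 0, 0, "failed") for qid, _ in manifest.failures],
            columns=list(COLUMNS),
        )
        parsed.table = _sort(pd.concat([parsed.table, failure_rows], ignore_index=True))
    return parsed


def write_tsv(table: pd.DataFrame, sink: IO[str] | str | Path) -> None:
    table.to_csv(sink, sep="\t", index=False)


def read_tsv(source: IO[str] | str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        source,
        sep="\t",
        dtype={c: (str if _SQL_TYPES[c] == "TEXT" else None) for c in COLUMNS},
    )
    if tuple(table.columns) != COLUMNS:
        raise ValidationError(f"expected columns {COLUMNS}, got {tuple(table.columns)}")
    return table


def _sql_quote(value: str) -> str:
    return "'" + value.replace("'", "''") + "'"


def table_to_sql(table: pd.DataFrame, table_name: str) -> str:
    """Render a hit table as a portable ANSI SQL dump.

    One CREATE TABLE with the 8 typed columns and one INSERT per row; string
    values are escaped so a load-then-select round trip reproduces them.
    """
    if not _IDENT_RE.match(table_name):
        raise ValidationError(f"illegal SQL identifier {table_name!r}")
    if tuple(table.columns) != COLUMNS:
        raise ValidationError(f"expected columns {COLUMNS}, got {tuple(table.columns)}")
    cols = ",\n  ".join(f"{c} {_SQL_TYPES[c]}" for c in COLUMNS)
    out = [f"CREATE TABLE {table_name} (\n  {cols}\n);"]
    col_list = ", ".join(COLUMNS)
    for row in table.itertuples(index=False):
        values = []
        for col, val in zip(COLUMNS, row):
            if _SQL_TYPES[col] == "TEXT":
                values.append(_sql_quote(str(val)))
            elif _SQL_TYPES[col] == "REAL":
                values.append(repr(float(val)))
            else:
                values.append(str(int(val)))
        out.append(
            f"INSERT INTO {table_name} ({col_list}) VALUES ({', '.join(values)});"
        )
    return "\n".join(out) + "\n"
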