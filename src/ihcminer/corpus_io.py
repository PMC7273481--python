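"""Reading and writing pathology-report corpora and extraction results.

Three concerns live here:

* parsing/serialising the plain-text report export dialect (records
  delimited by ``====`` lines, fields introduced by ``CASE:``,
  ``DIAGNOSIS:`` and ``DESCRIPTION:`` headers),
* a single-file SQLite store that round-trips reports losslessly in
  insertion order, and
* the results CSV, one row per case in the fixed column order
  ``case_id, metastatic_site, ER, PR, HER2`` where a failed extraction
  serialises as the literal token ``None``.
"""

from __future__ import annotations

import csv
import io
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from .ihc_extractor import ReceptorResult, format_receptor, parse_receptor_cell

__all__ = [
    "Report",
    "ExtractionRecord",
    "ExportParseError",
    "StoreError",
    "parse_export",
    "serialize_export",
    "build_store",
    "iter_store",
    "write_results_csv",
    "read_results_csv",
]

RESULTS_HEADER = ["case_id", "metastatic_site", "ER", "PR", "HER2"]

_DELIM_RE = re.compile(r"^={4,}\s*$")


class ExportParseError(ValueError):
    """A record in a report export could not be parsed."""


class StoreError(RuntimeError):
    """The report store is unreadable, unwritable or corrupt."""


@dataclass(frozen=True)
class Report:
    """One pathology report.

    ``diagnosis_lines`` is the line-wise diagnosis column;
    ``description_paragraphs`` holds blank-line-separated blocks of the
    description column (a block may contain internal single newlines).
    """

    case_id: str
    diagnosis_lines: tuple[str, ...] = ()
    description_paragraphs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        object.__setattr__(self, "diagnosis_lines", tuple(self.diagnosis_lines))
        object.__setattr__(
            self, "description_paragraphs", tuple(self.description_paragraphs)
        )
        for line in self.diagnosis_lines:
            if "\n" in line:
                raise ValueError(
                    f"diagnosis line of {self.case_id!r} contains a line break"
                )
        for para in self.description_paragraphs:
            if re.search(r"\n\s*\n", para):
                raise ValueError(
                    f"description paragraph of {self.case_id!r} contains a blank line"
                )


@dataclass
class ExtractionRecord:
    """One row of the results CSV."""

    case_id: str
    site_text: Optional[str] = None
    site_class: Optional[str] = None  # "regional" | "distant" | None
    er: Optional[ReceptorResult] = None
    pr: Optional[ReceptorResult] = None
    her2: Optional[ReceptorResult] = None


def _normalize(text: str) -> str:
    # Hospital exports arrive with mixed line endings; downstream matching
    # must see a single deterministic form.
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _split_paragraphs(block: str) -> list[str]:
    paras = re.split(r"\n\s*\n+", block.strip())
    return [p.strip() for p in paras if p.strip()]


def parse_export(stream: Union[str, IO[str]]) -> list[Report]:
    """Parse a plain-text report export into a list of :class:`Report`.

    Raises :class:`ExportParseError` naming the record index for a record
    missing its case id or both columns, and for duplicate case ids.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    if isinstance(text, bytes):
        text = text.decode("utf-8", errors="replace")
    text = _normalize(text)

    chunks: list[str] = []
    current: list[str] = []
    for line in text.split("\n"):
        if _DELIM_RE.match(line):
            if any(s.strip() for s in current):
                chunks.append("\n".join(current))
            current = []
        else:
            current.append(line.rstrip())
    if any(s.strip() for s in current):
        chunks.append("\n".join(current))

    reports: list[Report] = []
    seen: set[str] = set()
    for idx, chunk in enumerate(chunks):
        report = _parse_record(chunk, idx)
        if report.case_id in seen:
            raise ExportParseError(
                f"duplicate case_id {report.case_id!r} (record {idx})"
            )
        seen.add(report.case_id)
        reports.append(report)
    return reports


def _parse_record(chunk: str, idx: int) -> Report:
    case_id: Optional[str] = None
    sections: dict[str, list[str]] = {"DIAGNOSIS": [], "DESCRIPTION": []}
    current: Optional[str] = None
    for line in chunk.split("\n"):
        header = re.match(r"^(CASE|DIAGNOSIS|DESCRIPTION):\s*(.*)$", line)
        if header:
            key, rest = header.group(1), header.group(2)
            if key == "CASE":
                case_id = rest.strip()
                current = None
            else:
                current = key
                if rest.strip():
                    sections[key].append(rest)
            continue
        if current is not None:
            sections[current].append(line)
    if not case_id:
        raise ExportParseError(f"record {idx} is missing a CASE: header")
    if not sections["DIAGNOSIS"] and not sections["DESCRIPTION"]:
        raise ExportParseError(
            f"record {idx} ({case_id!r}) has neither diagnosis nor description"
        )
    diag = [ln.strip() for ln in sections["DIAGNOSIS"] if ln.strip()]
    desc = _split_paragraphs("\n".join(sections["DESCRIPTION"]))
    return Report(case_id=case_id, diagnosis_lines=diag, description_paragraphs=desc)


def serialize_export(reports: Iterable[Report]) -> str:
    """Inverse of :func:`parse_export` on well-formed corpora."""
    out: list[str] = []
    for report in reports:
        out.append("=" * 8)
        out.append(f"CASE: {report.case_id}")
        out.append("DIAGNOSIS:")
        out.extend(report.diagnosis_lines)
        out.append("DESCRIPTION:")
        out.append("\n\n".join(report.description_paragraphs))
    out.append("=" * 8)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# SQLite store
# ---------------------------------------------------------------------------

_SCHEMA = """
CREATE TABLE IF NOT EXISTS reports (
    seq INTEGER PRIMARY KEY AUTOINCREMENT,
    case_id TEXT UNIQUE NOT NULL,
    diagnosis TEXT NOT NULL,
    description TEXT NOT NULL
)
"""


def build_store(reports: Iterable[Report], store_path: Union[str, Path]) -> Path:
    """Persist reports to a single-file SQLite store; returns the path."""
    store_path = Path(store_path)
    try:
        conn = sqlite3.connect(store_path)
    except sqlite3.Error as exc:  # pragma: no cover - path errors are env specific
        raise StoreError(f"cannot open store at {store_path}: {exc}") from exc
    try:
        with conn:
            conn.execute(_SCHEMA)
            conn.execute("DELETE FROM reports")
            for report in reports:
                conn.execute(
                    "INSERT INTO reports (case_id, diagnosis, description) VALUES (?,?,?)",
                    (
                        report.case_id,
                        "\n".join(report.diagnosis_lines),
                        "\n\n".join(report.description_paragraphs),
                    ),
                )
    except sqlite3.IntegrityError as exc:
        raise StoreError(f"duplicate case_id while building store: {exc}") from exc
    except sqlite3.Error as exc:
        raise StoreError(f"cannot write store at {store_path}: {exc}") from exc
    finally:
        conn.close()
    return store_path


def iter_store(store_path: Union[str, Path]) -> Iterator[Report]:
    """Iterate stored reports in insertion order."""
    store_path = Path(store_path)
    if not store_path.exists():
        raise StoreError(f"store file does not exist: {store_path}")
    conn = sqlite3.connect(store_path)
    try:
        try:
            rows = conn.execute(
                "SELECT case_id, diagnosis, description FROM reports ORDER BY seq"
            ).fetchall()
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"corrupt store file {store_path}: {exc}") from exc
    finally:
        conn.close()
    for case_id, diagnosis, description in rows:
        yield Report(
            case_id=case_id,
            diagnosis_lines=[ln for ln in diagnosis.split("\n") if ln] if diagnosis else [],
            description_paragraphs=_split_paragraphs(description),
        )


# ---------------------------------------------------------------------------
# Results CSV
# ---------------------------------------------------------------------------


def _cell(result: Optional[ReceptorResult]) -> str:
    if result is None or result.status == "not_found":
        return "None"
    return format_receptor(result)


def write_results_csv(
    records: Iterable[ExtractionRecord], path: Union[str, Path]
) -> int:
    """Write the results CSV; returns the number of data rows written."""
    path = Path(path)
    count = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for rec in records:
            try:
                row = [
                    rec.case_id,
                    rec.site_text if rec.site_text else "None",
                    _cell(rec.er),
                    _cell(rec.pr),
                    _cell(rec.her2),
                ]
            except Exception as exc:
                raise ValueError(
                    f"unserializable field in record {rec.case_id!r}: {exc}"
                ) from exc
            writer.writerow(row)
            count += 1
    return count


def read_results_csv(path: Union[str, Path]) -> list[ExtractionRecord]:
    """Read back a results CSV written by :func:`write_results_csv`."""
    path = Path(path)
    records: list[ExtractionRecord] = []
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != RESULTS_HEADER:
            raise ValueError(f"unexpected results header: {header}")
        for row in reader:
            if not row:
                continue
            case_id, site, er, pr, her2 = row
            records.append(
                ExtractionRecord(
                    case_id=case_id,
                    site_text=None if site == "None" else site,
                    site_class=None,
                    er=parse_receptor_cell("ER", er),
                    pr=parse_receptor_cell("PR", pr),
                    her2=parse_receptor_cell("HER2", her2),
                )
            )
    return records
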