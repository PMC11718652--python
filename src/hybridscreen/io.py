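"""Readers, writers and configuration for the screening pipeline.

Formats
-------
.smi          one ``SMILES[whitespace]ID`` record per line, UTF-8; blank
              lines and ``#`` comments skipped; IDs auto-assigned
              (``row_<n>``) when absent.
CSV library   any table with a named SMILES column and optional ID column.
summary CSV   the cluster-statistics schema ``cluster,count,min,max``; the
              reader tolerates spaced thousands ("84 622") as printed in
              typeset tables.
config JSON   flat object of :class:`~hybridscreen.screening.ScreenConfig`
              fields; ``seed`` is mandatory and unknown keys are rejected.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .clustering import ClusterSummary
from .screening import ScreenConfig

__all__ = [
    "LibraryError",
    "ConfigError",
    "LibraryRecord",
    "read_library",
    "write_library",
    "read_summaries",
    "write_summaries",
    "load_config",
]

logger = logging.getLogger(__name__)


class LibraryError(ValueError):
    """Unreadable or inconsistent library file."""


class ConfigError(ValueError):
    """Invalid screen configuration document."""


@dataclass(frozen=True)
class LibraryRecord:
    """One library compound as read from disk."""

    id: str
    smiles: str
    row_number: int


def _check_unique_ids(records: list[LibraryRecord]) -> None:
    seen: dict[str, int] = {}
    for rec in records:
        if rec.id in seen:
            raise LibraryError(
                f"duplicate id {rec.id!r} at rows {seen[rec.id]} and "
                f"{rec.row_number}")
        seen[rec.id] = rec.row_number


def read_library(path, format: str | None = None, *,
                 smiles_column: str = "smiles",
                 id_column: str | None = None) -> list[LibraryRecord]:
    """Read a compound library from a .smi or CSV file.

    ``format`` defaults from the file suffix.  SMILES strings are not
    validated here — parse failures are the similarity stage's business,
    where they are logged per compound instead of aborting the read.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "smi"
    if format not in ("smi", "csv"):
        raise LibraryError(f"unknown library format {format!r}")
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")

    records: list[LibraryRecord] = []
    if format == "smi":
        with open(path, encoding="utf-8") as fh:
            for row_number, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                cid = parts[1] if len(parts) > 1 else f"row_{row_number}"
                records.append(LibraryRecord(cid, parts[0], row_number))
    else:
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise LibraryError(f"empty library file: {path}") from exc
        if smiles_column not in frame.columns:
            raise LibraryError(
                f"missing SMILES column {smiles_column!r} in {path} "
                f"(columns: {', '.join(frame.columns)})")
        if id_column is not None and id_column not in frame.columns:
            raise LibraryError(f"missing id column {id_column!r} in {path}")
        for row_number, row in frame.iterrows():
            cid = (str(row[id_column]) if id_column is not None
                   else f"row_{row_number}")
            records.append(LibraryRecord(cid, str(row[smiles_column]),
                                         int(row_number)))
    if not records:
        raise LibraryError(f"no records in library file: {path}")
    _check_unique_ids(records)
    logger.info("read %d library records from %s", len(records), path)
    return records


def write_library(records, path) -> None:
    """Write (id, smiles) records as a .smi file."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if hasattr(rec, "smiles"):
                cid, smi = rec.id, rec.smiles
            else:
                cid, smi = rec[0], rec[1]
            fh.write(f"{smi}\t{cid}\n")


def _numeric(text: str) -> float:
    # typeset tables space-group thousands: "84 622" -> 84622
    return float(text.replace(" ", "").replace(" ", ""))


def read_summaries(path) -> list[ClusterSummary]:
    """Read a cluster-summary CSV in the ``cluster,count,min,max`` schema."""
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"summary file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = [c.strip().lower() for c in reader.fieldnames or []]
        required = ["cluster", "count", "min", "max"]
        if [c for c in required if c not in cols]:
            raise LibraryError(
                f"summary file {path} must have columns cluster,count,min,"
                f"max (found: {', '.join(cols) or 'none'})")
        out = []
        for row in reader:
            row = {k.strip().lower(): v for k, v in row.items()}
            out.append(ClusterSummary(
                cluster_id=int(_numeric(row["cluster"])),
                count=int(_numeric(row["count"])),
                min_value=_numeric(row["min"]),
                max_value=_numeric(row["max"])))
    if not out:
        raise LibraryError(f"no data rows in summary file: {path}")
    return out


def write_summaries(summaries, path) -> None:
    """Write cluster summaries as ``cluster,count,min,max`` CSV."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("refusing to write an empty summary table")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cluster", "count", "min", "max"])
        for s in summaries:
            writer.writerow([s.cluster_id, s.count,
                             repr(s.min_value) if s.min_value != int(s.min_value)
                             else f"{s.min_value:g}",
                             repr(s.max_value) if s.max_value != int(s.max_value)
                             else f"{s.max_value:g}"])


def load_config(path) -> ScreenConfig:
    """Load a :class:`ScreenConfig` from JSON, rejecting unknown keys.

    ``seed`` has no default: a run without an explicit seed would be
    silently irreproducible.
    """
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a JSON object")
    known = set(ScreenConfig.__dataclass_fields__)
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {', '.join(map(repr, unknown))} "
            f"(known: {', '.join(sorted(known))})")
    if "seed" not in doc:
        raise ConfigError("config must set an explicit integer 'seed'")
    try:
        return ScreenConfig.from_dict(doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
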