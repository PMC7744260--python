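"""Site extract I/O: canonical CSV dialect plus site-mapping configuration.

A site-mapping config associates the canonical field names required by the
detection algorithms with the column names of a site's EHR extract, and
carries value-translation tables (site MAR action strings -> canonical
actions, site medication names -> canonical medications, including
many-to-one grouping such as individual fluid/TPN orders mapping to one
category).

Canonical dialect: UTF-8 CSV with RFC 4180 quoting, mandatory header row,
ISO-8601 timestamps with offset, dose ranges as paired low/high columns
(high empty for discrete doses).  Rejected rows never abort a batch; every
rejection and every unmapped value is collected in the ingest report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import pandas as pd
import yaml

from .datamodel import (
    AuditEvent,
    CommOrderText,
    MAREvent,
    OrderEvent,
    validate_event,
)

__all__ = [
    "STREAMS",
    "CANONICAL_COLUMNS",
    "SiteMapping",
    "MappingError",
    "EventBundle",
    "IngestReport",
    "StreamReport",
    "canonical_mapping",
    "load_mapping",
    "read_extract",
    "write_extract",
    "write_jsonl",
    "read_jsonl",
]

STREAMS = ("orders", "audits", "mars", "comm_orders")

#: canonical field -> required? (optional fields may be absent from extracts)
_FIELDS: dict[str, dict[str, bool]] = {
    "orders": {
        "order_id": True, "patient_id": True, "department": True,
        "medication": True, "dose_low": True, "dose_high": False,
        "unit": True, "order_time": True, "entry_time": True,
        "status": False, "discontinue_time": False,
    },
    "audits": {
        "order_id": True, "audit_time": True,
        "old_dose_low": False, "old_dose_high": False,
        "new_dose_low": True, "new_dose_high": False, "unit": True,
    },
    "mars": {
        "mar_id": True, "patient_id": True, "department": True,
        "medication": True, "action": True, "observed_dose": True,
        "unit": True, "mar_time": True,
    },
    "comm_orders": {
        "comm_id": False, "patient_id": True, "medication": False,
        "text": True, "comm_time": True,
    },
}

CANONICAL_COLUMNS = {s: list(f) for s, f in _FIELDS.items()}

_EVENT_TYPES = {
    "orders": OrderEvent,
    "audits": AuditEvent,
    "mars": MAREvent,
    "comm_orders": CommOrderText,
}

#: which translation table applies to which canonical field
_TRANSLATED_FIELDS = {
    "action": "mar_action",
    "medication": "medication",
    "department": "department",
}


class MappingError(ValueError):
    """A site-mapping config is malformed or incomplete."""


@dataclass
class SiteMapping:
    """Per-stream column maps plus value-translation tables."""

    columns: dict[str, dict[str, str]]  # stream -> {canonical field -> site column}
    translations: dict[str, dict[str, str]] = field(default_factory=dict)
    schema_version: int = 1

    def site_column(self, stream: str, canonical: str) -> Optional[str]:
        return self.columns.get(stream, {}).get(canonical)

    def translate(self, table: str, value: str) -> Optional[str]:
        """Translate a site value; identity when no table is configured.

        Returns None when a table exists but does not cover ``value`` —
        the caller records it as unmapped instead of passing it through.
        """
        tab = self.translations.get(table)
        if tab is None:
            return value
        return tab.get(value)


def canonical_mapping() -> SiteMapping:
    """Identity mapping for extracts already in the canonical dialect."""
    return SiteMapping(columns={s: {f: f for f in cols} for s, cols in CANONICAL_COLUMNS.items()})


def load_mapping(path: str | Path) -> SiteMapping:
    """Load and validate a site-mapping config file (YAML).

    Fails loudly, naming every missing required field, rather than
    deferring schema problems to ingest time.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise MappingError(f"cannot parse mapping file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise MappingError(f"mapping file {path} must contain a mapping at top level")
    streams_cfg = raw.get("streams")
    if not isinstance(streams_cfg, Mapping):
        raise MappingError("mapping file missing 'streams' section")
    columns: dict[str, dict[str, str]] = {}
    problems: list[str] = []
    for stream, fields in _FIELDS.items():
        cfg = streams_cfg.get(stream)
        if cfg is None:
            problems.append(f"stream {stream!r} not mapped")
            continue
        colmap = cfg.get("columns", cfg) if isinstance(cfg, Mapping) else None
        if not isinstance(colmap, Mapping):
            problems.append(f"stream {stream!r} has no 'columns' mapping")
            continue
        columns[stream] = {str(k): str(v) for k, v in colmap.items()}
        for canonical, required in fields.items():
            if required and canonical not in columns[stream]:
                problems.append(f"stream {stream!r} missing required field {canonical!r}")
    if problems:
        raise MappingError("invalid site mapping: " + "; ".join(problems))
    translations = {str(k): {str(a): str(b) for a, b in v.items()}
                    for k, v in (raw.get("translations") or {}).items()}
    return SiteMapping(columns=columns, translations=translations,
                       schema_version=int(raw.get("schema_version", 1)))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

@dataclass
class StreamReport:
    rows_read: int = 0
    accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason)
    unmapped_values: dict[str, list[str]] = field(default_factory=dict)  # table -> values

    def note_unmapped(self, table: str, value: str) -> None:
        vals = self.unmapped_values.setdefault(table, [])
        if value not in vals:
            vals.append(value)


@dataclass
class IngestReport:
    streams: dict[str, StreamReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            s: {
                "rows_read": r.rows_read,
                "accepted": r.accepted,
                "rejected": [{"row": i, "reason": why} for i, why in r.rejected],
                "unmapped_values": r.unmapped_values,
            }
            for s, r in self.streams.items()
        }


@dataclass
class EventBundle:
    """The four event collections of one site extract."""

    orders: list[OrderEvent] = field(default_factory=list)
    audits: list[AuditEvent] = field(default_factory=list)
    mars: list[MAREvent] = field(default_factory=list)
    comm_orders: list[CommOrderText] = field(default_factory=list)

    def stream(self, name: str) -> list:
        return getattr(self, name)


def _row_to_canonical(stream: str, row: Mapping[str, str], mapping: SiteMapping,
                      report: StreamReport) -> Optional[dict]:
    """Translate one extract row to canonical field names and values."""
    rec: dict[str, Any] = {}
    for canonical, required in _FIELDS[stream].items():
        col = mapping.site_column(stream, canonical)
        raw = row.get(col, "") if col else ""
        if raw == "" or raw is None:
            if required:
                raise ValueError(f"missing value for {canonical!r}")
            rec[canonical] = None
            continue
        table = _TRANSLATED_FIELDS.get(canonical)
        if table is not None:
            translated = mapping.translate(table, raw)
            if translated is None:
                report.note_unmapped(table, raw)
                raise ValueError(f"value {raw!r} not in {table!r} translation table")
            raw = translated
        rec[canonical] = raw
    return rec


def read_extract(paths: Mapping[str, str | Path], mapping: SiteMapping) -> tuple[EventBundle, IngestReport]:
    """Read per-stream delimited extracts into validated event collections.

    Rows that fail translation or validation are rejected and logged in the
    ingest report; a dirty row never aborts the batch.  ``paths`` may omit
    streams a site does not provide.
    """
    bundle = EventBundle()
    report = IngestReport()
    for stream, path in paths.items():
        if stream not in STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        sr = StreamReport()
        report.streams[stream] = sr
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        wanted = {mapping.site_column(stream, f) for f, req in _FIELDS[stream].items()
                  if req and mapping.site_column(stream, f)}
        missing_cols = wanted - set(df.columns)
        if missing_cols:
            raise MappingError(
                f"extract {path} lacks mapped column(s): {sorted(missing_cols)}")
        event_cls = _EVENT_TYPES[stream]
        for idx, row in enumerate(df.to_dict(orient="records")):
            sr.rows_read += 1
            try:
                rec = _row_to_canonical(stream, row, mapping, sr)
                event = event_cls.from_dict(rec)
            except (ValueError, KeyError, TypeError) as exc:
                sr.rejected.append((idx, str(exc)))
                continue
            vr = validate_event(event)
            if not vr.ok:
                sr.rejected.append((idx, "; ".join(vr.errors)))
                continue
            bundle.stream(stream).append(event)
            sr.accepted += 1
    return bundle, report


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_extract(bundle: EventBundle, paths: Mapping[str, str | Path]) -> None:
    """Write event collections as canonical-dialect CSV, one file per stream.

    ``read_extract(write_extract(x)) == x`` under the identity mapping.
    """
    for stream, path in paths.items():
        if stream not in STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        cols = CANONICAL_COLUMNS[stream]
        rows = [ev.to_dict() for ev in bundle.stream(stream)]
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, index=False, lineterminator="\n")


def write_jsonl(records: list, path: str | Path) -> None:
    """Serialize a list of events (or plain dicts) as JSON Lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            d = rec.to_dict() if hasattr(rec, "to_dict") else rec
            fh.write(json.dumps(d, sort_keys=True) + "\n")


def read_jsonl(path: str | Path, event_cls=None) -> list:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(event_cls.from_dict(d) if event_cls is not None else d)
    return out
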