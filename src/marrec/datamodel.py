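"""Canonical domain types for medication-use event reconciliation.

Every downstream stage (ingest, timeline assembly, discrepancy detection,
reporting) operates on the types defined here: continuous-infusion orders,
structured order modifications (audits), medication administration record
(MAR) documentation rows, free-text communication orders and the discrete
dose directives parsed from them, detector output calls, and the detector
configuration.

Conventions
-----------
* All timestamps are timezone-aware :class:`datetime.datetime` instants.
  Comparisons use instant ordering, never local-clock strings, so
  grace-window arithmetic survives DST transitions.
* Doses are expressed as a :class:`DoseSpec`: a discrete value (``high``
  absent) or an inclusive range ``[low, high]`` in a per-medication rate
  unit such as ``"Units/hr"`` or ``"mcg/kg/min"``.
* Dose equality is tolerance-based: ``|a - b| <= tol * max(1, |b|)`` after
  rounding both sides to a configurable number of decimals.  Clinical
  sources imply exact match; the tolerance only guards float ingestion
  noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from typing import Any, Iterable, Mapping, Optional, Sequence

__all__ = [
    "MAR_ACTIONS",
    "MAR_ACTION_VOCAB",
    "DEPARTMENTS",
    "DIRECTIVE_KINDS",
    "REASON_CODES",
    "Medication",
    "MedicationRegistry",
    "default_registry",
    "DoseSpec",
    "OrderEvent",
    "AuditEvent",
    "MAREvent",
    "CommOrderText",
    "DoseDirective",
    "DiscrepancyCall",
    "DetectorConfig",
    "ValidationReport",
    "validate_event",
    "values_equal",
    "doses_equal",
    "parse_timestamp",
    "format_timestamp",
]

#: MAR actions analyzed for potential administration errors.  Other actions
#: (e.g. pump checks unrelated to dosing) are carried as "other" and filtered
#: out before detection.
MAR_ACTIONS = frozenset({"new bag", "start", "restart", "rate verify", "rate change"})
MAR_ACTION_VOCAB = MAR_ACTIONS | {"other"}

DEPARTMENTS = ("NICU", "PICU", "adult medical ICU", "other")

DIRECTIVE_KINDS = ("set-to", "increase-by", "decrease-by")

REASON_CODES = ("dose-mismatch", "no-active-order", "unit-mismatch")


# ---------------------------------------------------------------------------
# Timestamps
# ---------------------------------------------------------------------------

def parse_timestamp(value: str) -> datetime:
    """Parse an ISO-8601 timestamp with offset into an aware datetime."""
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        raise ValueError(f"timestamp {value!r} has no UTC offset; aware instants required")
    return ts


def format_timestamp(ts: datetime) -> str:
    return ts.isoformat()


def _is_aware(ts: Any) -> bool:
    return isinstance(ts, datetime) and ts.tzinfo is not None


# ---------------------------------------------------------------------------
# Dose arithmetic
# ---------------------------------------------------------------------------

def values_equal(a: float, b: float, tolerance: float = 1e-6, decimals: int = 4) -> bool:
    """Tolerance equality of two dose/rate values.

    Both values are rounded to ``decimals`` places first; equality then means
    ``|a - b| <= tolerance * max(1, |b|)``.
    """
    ra, rb = round(float(a), decimals), round(float(b), decimals)
    return abs(ra - rb) <= tolerance * max(1.0, abs(rb))


@dataclass(frozen=True)
class DoseSpec:
    """A prescribed dose or rate: discrete (``high is None``) or a range.

    Range orders (e.g. insulin 1-10 Units/hr with a titration protocol)
    permit bedside adjustment anywhere inside the inclusive interval.
    """

    low: float
    high: Optional[float] = None
    unit: str = ""

    @property
    def is_range(self) -> bool:
        return self.high is not None

    def violations(self) -> list[str]:
        out = []
        if self.low < 0:
            out.append("dose low must be non-negative")
        if self.high is not None and self.high < self.low:
            out.append("high < low")
        if not self.unit:
            out.append("unit must be non-empty")
        return out

    def equals(self, other: "DoseSpec", tolerance: float = 1e-6, decimals: int = 4) -> bool:
        """Value equality of two dose specs (unit compared exactly)."""
        if self.unit.strip().lower() != other.unit.strip().lower():
            return False
        if self.is_range != other.is_range:
            return False
        if not values_equal(self.low, other.low, tolerance, decimals):
            return False
        if self.is_range and not values_equal(self.high, other.high, tolerance, decimals):
            return False
        return True

    def to_dict(self) -> dict:
        return {"low": self.low, "high": self.high, "unit": self.unit}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DoseSpec":
        high = d.get("high")
        return cls(low=float(d["low"]), high=None if high in (None, "") else float(high), unit=d["unit"])


def doses_equal(a: Optional[DoseSpec], b: Optional[DoseSpec], tolerance: float = 1e-6, decimals: int = 4) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return a.equals(b, tolerance, decimals)


# ---------------------------------------------------------------------------
# Medications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Medication:
    """A studied continuous-infusion medication and its canonical rate unit."""

    name: str
    canonical_unit: str
    allows_range: bool = False


class MedicationRegistry:
    """Name-unique registry of medications; extensible per site."""

    def __init__(self, medications: Iterable[Medication] = ()):
        self._by_name: dict[str, Medication] = {}
        for m in medications:
            self.add(m)

    def add(self, med: Medication) -> None:
        if med.name in self._by_name:
            raise ValueError(f"duplicate medication name {med.name!r}")
        if not med.canonical_unit:
            raise ValueError(f"medication {med.name!r} has empty canonical_unit")
        self._by_name[med.name] = med

    def get(self, name: str) -> Optional[Medication]:
        return self._by_name.get(name)

    def names(self) -> list[str]:
        return sorted(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)


#: The eleven continuously infused medications the detector was built around,
#: with the rate units in which their orders and MARs are documented.
_DEFAULT_MEDS = [
    Medication("dobutamine", "mcg/kg/min"),
    Medication("dopamine", "mcg/kg/min"),
    Medication("epinephrine", "mcg/kg/min"),
    Medication("fentanyl", "mcg/kg/hr"),
    Medication("insulin", "Units/hr", allows_range=True),
    Medication("intravenous fluids", "mL/hr"),
    Medication("lipids", "mL/hr"),
    Medication("milrinone", "mcg/kg/min"),
    Medication("morphine", "mg/hr"),
    Medication("total parenteral nutrition", "mL/hr"),
    Medication("vasopressin", "milliunits/kg/min"),
]


def default_registry() -> MedicationRegistry:
    return MedicationRegistry(_DEFAULT_MEDS)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderEvent:
    """One prescription for a continuous infusion.

    ``order_time`` is the clinical-intent time; ``entry_time`` the EHR
    documentation time.  ``discontinue_time``, when present, ends the
    prescription: MARs after it with no other active order are flagged
    ``no-active-order``.
    """

    order_id: str
    patient_id: str
    department: str
    medication: str
    dose: DoseSpec
    order_time: datetime
    entry_time: datetime
    status: str = "active"
    discontinue_time: Optional[datetime] = None

    def violations(self) -> list[str]:
        out = self.dose.violations()
        for name in ("order_time", "entry_time"):
            if not _is_aware(getattr(self, name)):
                out.append(f"{name} must be a timezone-aware datetime")
        if self.discontinue_time is not None and not _is_aware(self.discontinue_time):
            out.append("discontinue_time must be a timezone-aware datetime")
        if _is_aware(self.order_time) and _is_aware(self.entry_time) and self.entry_time < self.order_time:
            out.append("entry_time < order_time")
        if self.status not in ("active", "discontinued"):
            out.append(f"unknown status {self.status!r}")
        if self.department not in DEPARTMENTS:
            out.append(f"unknown department {self.department!r}")
        if not self.order_id:
            out.append("order_id must be non-empty")
        return out

    def to_dict(self) -> dict:
        return {
            "order_id": self.order_id,
            "patient_id": self.patient_id,
            "department": self.department,
            "medication": self.medication,
            "dose_low": self.dose.low,
            "dose_high": self.dose.high,
            "unit": self.dose.unit,
            "order_time": format_timestamp(self.order_time),
            "entry_time": format_timestamp(self.entry_time),
            "status": self.status,
            "discontinue_time": format_timestamp(self.discontinue_time) if self.discontinue_time else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OrderEvent":
        disc = d.get("discontinue_time")
        return cls(
            order_id=str(d["order_id"]),
            patient_id=str(d["patient_id"]),
            department=d["department"],
            medication=d["medication"],
            dose=DoseSpec(float(d["dose_low"]),
                          None if d.get("dose_high") in (None, "") else float(d["dose_high"]),
                          d["unit"]),
            order_time=parse_timestamp(d["order_time"]),
            entry_time=parse_timestamp(d["entry_time"]),
            status=d.get("status", "active"),
            discontinue_time=parse_timestamp(disc) if disc else None,
        )


@dataclass(frozen=True)
class AuditEvent:
    """A structured modification of an existing order (old dose -> new dose).

    ``audit_time`` is the EHR entry time of the modification and the instant
    from which the new dose is in force.  ``old_dose`` may be None for
    extracts that do not retain pre-modification values; original-value
    recovery then degrades for the affected orders.
    """

    order_id: str
    audit_time: datetime
    old_dose: Optional[DoseSpec]
    new_dose: DoseSpec

    def violations(self) -> list[str]:
        out = self.new_dose.violations()
        if self.old_dose is not None:
            out += self.old_dose.violations()
        if not _is_aware(self.audit_time):
            out.append("audit_time must be a timezone-aware datetime")
        if not self.order_id:
            out.append("order_id must be non-empty")
        return out

    def to_dict(self) -> dict:
        return {
            "order_id": self.order_id,
            "audit_time": format_timestamp(self.audit_time),
            "old_dose_low": None if self.old_dose is None else self.old_dose.low,
            "old_dose_high": None if self.old_dose is None else self.old_dose.high,
            "new_dose_low": self.new_dose.low,
            "new_dose_high": self.new_dose.high,
            "unit": self.new_dose.unit,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AuditEvent":
        unit = d["unit"]
        old_low = d.get("old_dose_low")
        old = None
        if old_low not in (None, ""):
            oh = d.get("old_dose_high")
            old = DoseSpec(float(old_low), None if oh in (None, "") else float(oh), unit)
        nh = d.get("new_dose_high")
        return cls(
            order_id=str(d["order_id"]),
            audit_time=parse_timestamp(d["audit_time"]),
            old_dose=old,
            new_dose=DoseSpec(float(d["new_dose_low"]), None if nh in (None, "") else float(nh), unit),
        )


@dataclass(frozen=True)
class MAREvent:
    """One MAR documentation row: action, observed dose/rate, time."""

    mar_id: str
    patient_id: str
    department: str
    medication: str
    action: str
    observed_dose: float
    unit: str
    mar_time: datetime

    def violations(self) -> list[str]:
        out = []
        if self.observed_dose < 0:
            out.append("observed_dose must be non-negative")
        if self.action not in MAR_ACTION_VOCAB:
            out.append(f"unknown MAR action {self.action!r}")
        if not _is_aware(self.mar_time):
            out.append("mar_time must be a timezone-aware datetime")
        if self.department not in DEPARTMENTS:
            out.append(f"unknown department {self.department!r}")
        if not self.unit:
            out.append("unit must be non-empty")
        return out

    def to_dict(self) -> dict:
        return {
            "mar_id": self.mar_id,
            "patient_id": self.patient_id,
            "department": self.department,
            "medication": self.medication,
            "action": self.action,
            "observed_dose": self.observed_dose,
            "unit": self.unit,
            "mar_time": format_timestamp(self.mar_time),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MAREvent":
        return cls(
            mar_id=str(d["mar_id"]),
            patient_id=str(d["patient_id"]),
            department=d["department"],
            medication=d["medication"],
            action=d["action"],
            observed_dose=float(d["observed_dose"]),
            unit=d["unit"],
            mar_time=parse_timestamp(d["mar_time"]),
        )


@dataclass(frozen=True)
class CommOrderText:
    """A free-text physician-to-nurse communication order."""

    patient_id: str
    text: str
    comm_time: datetime
    medication: Optional[str] = None
    comm_id: str = ""

    def violations(self) -> list[str]:
        out = []
        if not self.text or not self.text.strip():
            out.append("text must be non-empty")
        if not _is_aware(self.comm_time):
            out.append("comm_time must be a timezone-aware datetime")
        return out

    def to_dict(self) -> dict:
        return {
            "comm_id": self.comm_id,
            "patient_id": self.patient_id,
            "medication": self.medication,
            "text": self.text,
            "comm_time": format_timestamp(self.comm_time),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CommOrderText":
        med = d.get("medication")
        return cls(
            patient_id=str(d["patient_id"]),
            text=d["text"],
            comm_time=parse_timestamp(d["comm_time"]),
            medication=med or None,
            comm_id=str(d.get("comm_id", "")),
        )


@dataclass(frozen=True)
class DoseDirective:
    """A discrete dose/rate instruction extracted from free text.

    ``kind`` is one of ``set-to`` (absolute), ``increase-by`` or
    ``decrease-by`` (relative to the current dose).  ``amount_high`` is
    populated when the text specified a range (e.g. "titrate 2-4").
    """

    patient_id: str
    medication: str
    kind: str
    amount: float
    unit: str
    effective_time: datetime
    provenance: str = ""
    amount_high: Optional[float] = None
    source_span: tuple[int, int] = (0, 0)

    def violations(self) -> list[str]:
        out = []
        if self.amount < 0:
            out.append("amount must be non-negative")
        if self.kind not in DIRECTIVE_KINDS:
            out.append(f"unknown directive kind {self.kind!r}")
        if not _is_aware(self.effective_time):
            out.append("effective_time must be a timezone-aware datetime")
        return out

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "medication": self.medication,
            "kind": self.kind,
            "amount": self.amount,
            "amount_high": self.amount_high,
            "unit": self.unit,
            "effective_time": format_timestamp(self.effective_time),
            "provenance": self.provenance,
            "source_span": list(self.source_span),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DoseDirective":
        ah = d.get("amount_high")
        span = d.get("source_span", (0, 0))
        return cls(
            patient_id=str(d["patient_id"]),
            medication=d["medication"],
            kind=d["kind"],
            amount=float(d["amount"]),
            unit=d["unit"],
            effective_time=parse_timestamp(d["effective_time"]),
            provenance=str(d.get("provenance", "")),
            amount_high=None if ah in (None, "") else float(ah),
            source_span=(int(span[0]), int(span[1])),
        )


@dataclass(frozen=True)
class DiscrepancyCall:
    """One detector output.

    ``suppressed`` marks calls silenced by the previous-MAR rule (the
    observed value repeats the value of an immediately preceding MAR that
    was already called discrepant).  Suppressed calls are emitted for
    auditability but never counted in discrepancy rates.
    """

    mar: MAREvent
    expected: Optional[DoseSpec]
    observed: float
    reason: str
    suppressed: bool = False

    def violations(self) -> list[str]:
        out = []
        if self.reason not in REASON_CODES:
            out.append(f"unknown reason {self.reason!r}")
        return out

    def to_dict(self) -> dict:
        return {
            "mar_id": self.mar.mar_id,
            "patient_id": self.mar.patient_id,
            "department": self.mar.department,
            "medication": self.mar.medication,
            "mar_time": format_timestamp(self.mar.mar_time),
            "expected_low": None if self.expected is None else self.expected.low,
            "expected_high": None if self.expected is None else self.expected.high,
            "expected_unit": None if self.expected is None else self.expected.unit,
            "observed": self.observed,
            "reason": self.reason,
            "suppressed": self.suppressed,
        }


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable detection behavior.

    grace_window_minutes
        Time allowance after an MAR during which a late-entered matching
        order/audit clears a candidate discrepancy (verbal-order lag).
    range_mode
        ``"range-aware"`` accepts any observed value inside a range order;
        ``"legacy-lower-bound"`` compares only against the range's first
        value, reproducing the original single-dose behavior.
    dose_tolerance, comparison_decimals
        Parameters of tolerance equality (see :func:`values_equal`).
    mar_action_filter
        MAR actions retained for analysis.
    """

    grace_window_minutes: int = 30
    range_mode: str = "range-aware"
    dose_tolerance: float = 1e-6
    mar_action_filter: frozenset = field(default_factory=lambda: MAR_ACTIONS)
    comparison_decimals: int = 4

    def violations(self) -> list[str]:
        out = []
        if self.grace_window_minutes < 0:
            out.append("grace_window_minutes must be >= 0")
        if self.dose_tolerance < 0:
            out.append("dose_tolerance must be >= 0")
        if self.range_mode not in ("range-aware", "legacy-lower-bound"):
            out.append(f"unknown range_mode {self.range_mode!r}")
        return out

    def values_equal(self, a: float, b: float) -> bool:
        return values_equal(a, b, self.dose_tolerance, self.comparison_decimals)

    def doses_equal(self, a: Optional[DoseSpec], b: Optional[DoseSpec]) -> bool:
        return doses_equal(a, b, self.dose_tolerance, self.comparison_decimals)

    def to_dict(self) -> dict:
        return {
            "grace_window_minutes": self.grace_window_minutes,
            "range_mode": self.range_mode,
            "dose_tolerance": self.dose_tolerance,
            "mar_action_filter": sorted(self.mar_action_filter),
            "comparison_decimals": self.comparison_decimals,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DetectorConfig":
        kw = dict(d)
        if "mar_action_filter" in kw:
            kw["mar_action_filter"] = frozenset(kw["mar_action_filter"])
        return cls(**kw)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    ok: bool
    errors: list[str] = field(default_factory=list)


_VALIDATABLE = (DoseSpec, OrderEvent, AuditEvent, MAREvent, CommOrderText,
                DoseDirective, DiscrepancyCall, DetectorConfig)


def validate_event(event: Any) -> ValidationReport:
    """Check an event (or config/dose spec) against its invariants.

    Returns a pass/fail report with per-field violation messages; never
    mutates its argument.  Unknown kinds are rejected with an explanatory
    message rather than raising.
    """
    if not isinstance(event, _VALIDATABLE):
        return ValidationReport(False, [f"unknown event kind: {type(event).__name__}"])
    errors = event.violations()
    return ValidationReport(not errors, errors)
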