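"""Per-patient, per-medication chronology of prescribed dose states.

Two responsibilities live here:

* :func:`recover_original_orders` — undo the retrospective-database ETL
  artifact in which every order modification overwrites the order's stored
  original value, leaving the order carrying its *last* audit's value.
  The overwrite signature is detectable from the audit chain itself: the
  stored dose equals the last audit's new value but differs from the first
  audit's old value, in which case the first audit's old value *is* the
  original prescription.
* :func:`build_timeline` / :func:`effective_dose_at` — assemble the ordered
  sequence of prescribed dose states per (patient, medication) from orders,
  audits and resolved free-text directives, and answer "what dose was in
  force at time t", which is what the detector compares each MAR against.

Tie-breaking at equal timestamps follows source precedence
audit > order > directive: a modification entered at the same instant
supersedes, and an MAR at the same instant as a state change is judged
against the new state.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Optional, Sequence

from .datamodel import (
    AuditEvent,
    DetectorConfig,
    DoseDirective,
    DoseSpec,
    MAREvent,
    OrderEvent,
)
from .textorders import UnresolvedDirectiveError, directive_to_audit

__all__ = [
    "DoseState",
    "Timeline",
    "TimelineSet",
    "RecoveryReport",
    "recover_original_orders",
    "build_timeline",
    "effective_dose_at",
]

# source precedence at equal effective_from; larger sorts later and wins
_SOURCE_RANK = {"directive": 0, "order": 1, "audit": 2}


@dataclass(frozen=True)
class DoseState:
    """One prescribed-dose interval start.

    ``dose`` is None for a discontinuation sentinel (no active
    prescription).  ``entry_time`` is the EHR documentation instant of the
    underlying event and is what the detector's grace window examines; for
    audits and directives it coincides with ``effective_from``.
    """

    effective_from: datetime
    dose: Optional[DoseSpec]
    source: str  # order | audit | directive
    source_ref: str
    entry_time: datetime


@dataclass
class Timeline:
    patient_id: str
    medication: str
    states: list[DoseState] = field(default_factory=list)
    mars: list[MAREvent] = field(default_factory=list)

    # cached effective_from instants for bisection
    _times: list[datetime] = field(default_factory=list, repr=False)

    def finalize(self) -> None:
        self._times = [s.effective_from for s in self.states]


@dataclass
class TimelineSet:
    timelines: dict[tuple[str, str], Timeline] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        for key in sorted(self.timelines):
            yield self.timelines[key]

    def __len__(self) -> int:
        return len(self.timelines)

    def get(self, patient_id: str, medication: str) -> Optional[Timeline]:
        return self.timelines.get((patient_id, medication))


# ---------------------------------------------------------------------------
# Original-order-value recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Every rewrite performed, plus orders that could not be assessed."""

    rewrites: list[dict] = field(default_factory=list)
    unrecoverable: list[str] = field(default_factory=list)  # order_ids lacking old values

    def to_tsv(self) -> str:
        lines = ["order_id\tstored_low\tstored_high\trecovered_low\trecovered_high\tn_audits"]
        for r in self.rewrites:
            lines.append(
                f"{r['order_id']}\t{r['stored'].low}\t{r['stored'].high or ''}"
                f"\t{r['recovered'].low}\t{r['recovered'].high or ''}\t{r['n_audits']}"
            )
        return "\n".join(lines) + "\n"


def recover_original_orders(
    orders: Sequence[OrderEvent],
    audits: Sequence[AuditEvent],
    config: Optional[DetectorConfig] = None,
) -> tuple[list[OrderEvent], RecoveryReport]:
    """Reverse ETL overwriting of original order values.

    For each order with at least one audit whose stored dose equals the
    *last* audit's new value but differs from the *first* audit's old value,
    the stored dose is replaced by the first audit's old value.  All other
    orders pass through unchanged.  Audits with unknown old values leave
    their order unchanged and flagged unrecoverable.  Idempotent: a second
    application is a no-op.
    """
    config = config or DetectorConfig()
    by_order: dict[str, list[AuditEvent]] = {}
    for a in audits:
        by_order.setdefault(a.order_id, []).append(a)
    for chain in by_order.values():
        chain.sort(key=lambda a: a.audit_time)

    report = RecoveryReport()
    out: list[OrderEvent] = []
    for order in orders:
        chain = by_order.get(order.order_id)
        if not chain:
            out.append(order)
            continue
        if any(a.old_dose is None for a in chain):
            report.unrecoverable.append(order.order_id)
            out.append(order)
            continue
        first, last = chain[0], chain[-1]
        if config.doses_equal(order.dose, last.new_dose) and not config.doses_equal(
            order.dose, first.old_dose
        ):
            recovered = replace(order, dose=first.old_dose)
            report.rewrites.append(
                {"order_id": order.order_id, "stored": order.dose,
                 "recovered": first.old_dose, "n_audits": len(chain)}
            )
            out.append(recovered)
        else:
            out.append(order)
    return out, report


# ---------------------------------------------------------------------------
# Timeline assembly
# ---------------------------------------------------------------------------

def build_timeline(
    orders: Sequence[OrderEvent],
    audits: Sequence[AuditEvent],
    directives: Sequence[DoseDirective],
    mars: Sequence[MAREvent],
    config: Optional[DetectorConfig] = None,
) -> TimelineSet:
    """Assemble one Timeline per (patient, medication).

    Dose states derive from order entry (effective from ``order_time``),
    audits (effective from ``audit_time``, carrying the new dose) and
    directives resolvable against the dose in force at their effective
    time.  MARs are restricted to ``config.mar_action_filter``.  Orphan
    audits (unknown order_id) and unresolvable directives are skipped with
    a warning, never guessed.  The result is invariant to input ordering.
    """
    config = config or DetectorConfig()
    ts = TimelineSet()

    order_index: dict[str, OrderEvent] = {}
    for o in sorted(orders, key=lambda o: (o.entry_time, o.order_id)):
        if o.order_id in order_index:
            ts.warnings.append(f"duplicate order_id {o.order_id!r}: first by entry_time wins")
            continue
        order_index[o.order_id] = o

    def timeline_for(patient_id: str, medication: str) -> Timeline:
        key = (patient_id, medication)
        tl = ts.timelines.get(key)
        if tl is None:
            tl = Timeline(patient_id=patient_id, medication=medication)
            ts.timelines[key] = tl
        return tl

    staging: dict[tuple[str, str], list[DoseState]] = {}

    def stage(patient_id: str, medication: str, state: DoseState) -> None:
        staging.setdefault((patient_id, medication), []).append(state)

    seen_orders: dict[tuple[str, str], list[OrderEvent]] = {}
    for o in order_index.values():
        key = (o.patient_id, o.medication)
        for prev in seen_orders.get(key, []):
            prev_end = prev.discontinue_time
            if prev_end is None or o.order_time < prev_end:
                ts.warnings.append(
                    f"overlapping orders for {key}: {prev.order_id!r} and {o.order_id!r}")
        seen_orders.setdefault(key, []).append(o)
        stage(*key, DoseState(o.order_time, o.dose, "order", o.order_id, o.entry_time))
        if o.discontinue_time is not None:
            stage(*key, DoseState(o.discontinue_time, None, "order", o.order_id, o.discontinue_time))

    for a in sorted(audits, key=lambda a: (a.audit_time, a.order_id)):
        o = order_index.get(a.order_id)
        if o is None:
            ts.warnings.append(f"orphan audit for unknown order_id {a.order_id!r}: skipped")
            continue
        stage(o.patient_id, o.medication,
              DoseState(a.audit_time, a.new_dose, "audit", a.order_id, a.audit_time))

    def sort_key(s: DoseState):
        return (s.effective_from, _SOURCE_RANK[s.source], s.source_ref)

    for key, states in staging.items():
        states.sort(key=sort_key)

    # Directives resolve against the dose in force at their effective time,
    # considering earlier directives too, so process them chronologically.
    for d in sorted(directives, key=lambda d: (d.effective_time, d.provenance)):
        key = (d.patient_id, d.medication)
        states = staging.get(key)
        if states is None:
            ts.warnings.append(
                f"directive for {key} has no order context: skipped")
            continue
        current = None
        for s in states:
            if s.effective_from <= d.effective_time:
                current = s.dose
            else:
                break
        try:
            new_dose = directive_to_audit(d, current)
        except UnresolvedDirectiveError as exc:
            ts.warnings.append(f"unresolved directive for {key}: {exc}")
            continue
        bisect.insort(
            states,
            DoseState(d.effective_time, new_dose, "directive", d.provenance, d.effective_time),
            key=sort_key,
        )

    for (patient_id, medication), states in staging.items():
        tl = timeline_for(patient_id, medication)
        collapsed: list[DoseState] = []
        for s in states:
            if collapsed and collapsed[-1].source == s.source and _same_dose(collapsed[-1].dose, s.dose, config):
                continue  # consecutive equal doses from the same source collapse
            collapsed.append(s)
        tl.states = collapsed

    for m in sorted(mars, key=lambda m: (m.mar_time, m.mar_id)):
        if m.action not in config.mar_action_filter:
            continue
        timeline_for(m.patient_id, m.medication).mars.append(m)

    # drop keys that ended up with neither states nor MARs
    ts.timelines = {k: v for k, v in ts.timelines.items() if v.states or v.mars}
    for tl in ts.timelines.values():
        tl.finalize()
    return ts


def _same_dose(a: Optional[DoseSpec], b: Optional[DoseSpec], config: DetectorConfig) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return config.doses_equal(a, b)


def effective_dose_at(timeline: Timeline, t: datetime) -> Optional[DoseSpec]:
    """Dose of the latest state with ``effective_from <= t``; None if no
    state precedes ``t`` or the prescription was discontinued."""
    if not timeline._times:
        timeline.finalize()
    idx = bisect.bisect_right(timeline._times, t)
    if idx == 0:
        return None
    return timeline.states[idx - 1].dose
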