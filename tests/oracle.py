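"""Independent brute-force reference detector and random stream generator.

The oracle re-derives the expected dose by a full rescan of all order and
audit events at every MAR, with its own inline equality/range/grace/
suppression logic.  It shares only the domain types with the production
detector, never its timeline index or matching code, so agreement between
the two is a meaningful check.
"""

from __future__ import annotations

from datetime import timedelta, timezone, datetime
import numpy as np

from marrec.datamodel import (
    AuditEvent,
    DetectorConfig,
    DoseSpec,
    MAREvent,
    OrderEvent,
)
from marrec.io_mapping import EventBundle


def _eq(a: float, b: float, cfg: DetectorConfig) -> bool:
    ra = round(a, cfg.comparison_decimals)
    rb = round(b, cfg.comparison_decimals)
    return abs(ra - rb) <= cfg.dose_tolerance * max(1.0, abs(rb))


def _matches(spec: DoseSpec, observed: float, cfg: DetectorConfig) -> bool:
    if spec.high is not None and cfg.range_mode == "range-aware":
        d = cfg.comparison_decimals
        ro = round(observed, d)
        lo, hi = round(spec.low, d), round(spec.high, d)
        tol = cfg.dose_tolerance
        return lo - tol * max(1.0, abs(lo)) <= ro <= hi + tol * max(1.0, abs(hi))
    return _eq(observed, spec.low, cfg)


def _state_events(orders, audits):
    """(effective_from, rank, ref, dose-or-None, entry_time) tuples."""
    order_by_id = {o.order_id: o for o in orders}
    out = []
    for o in orders:
        out.append((o.order_time, 1, o.order_id, o.dose, o.entry_time))
        if o.discontinue_time is not None:
            out.append((o.discontinue_time, 1, o.order_id, None, o.discontinue_time))
    for a in audits:
        if a.order_id in order_by_id:
            out.append((a.audit_time, 2, a.order_id, a.new_dose, a.audit_time))
    return out


def brute_force_detect(bundle: EventBundle, cfg: DetectorConfig):
    """Full-rescan detection; returns [(mar_id, reason, suppressed)]."""
    order_key = {o.order_id: (o.patient_id, o.medication) for o in bundle.orders}
    calls = []
    keys = sorted(
        {(o.patient_id, o.medication) for o in bundle.orders}
        | {(m.patient_id, m.medication) for m in bundle.mars
           if m.action in cfg.mar_action_filter}
    )
    for key in keys:
        orders = [o for o in bundle.orders if (o.patient_id, o.medication) == key]
        audits = [a for a in bundle.audits if order_key.get(a.order_id) == key]
        events = sorted(_state_events(orders, audits), key=lambda e: (e[0], e[1], e[2]))
        mars = sorted(
            (m for m in bundle.mars
             if (m.patient_id, m.medication) == key and m.action in cfg.mar_action_filter),
            key=lambda m: (m.mar_time, m.mar_id),
        )
        prev_obs = None
        prev_bad = False
        for m in mars:
            expected = None
            for ev in events:  # full rescan, latest event at or before the MAR
                if ev[0] <= m.mar_time:
                    expected = ev[3]
            if expected is None:
                reason = "no-active-order"
            elif expected.unit.strip().lower() != m.unit.strip().lower():
                reason = "unit-mismatch"
            elif not _matches(expected, m.observed_dose, cfg):
                reason = "dose-mismatch"
            else:
                reason = None
            if reason is not None and cfg.grace_window_minutes > 0:
                horizon = m.mar_time + timedelta(minutes=cfg.grace_window_minutes)
                for ev in events:
                    dose, entry = ev[3], ev[4]
                    if dose is None:
                        continue
                    if m.mar_time < entry <= horizon \
                            and dose.unit.strip().lower() == m.unit.strip().lower() \
                            and _matches(dose, m.observed_dose, cfg):
                        reason = None
                        break
            if reason is None:
                prev_bad = False
            else:
                suppressed = prev_bad and prev_obs is not None and _eq(
                    m.observed_dose, prev_obs, cfg)
                calls.append((m.mar_id, reason, suppressed))
                prev_bad = True
            prev_obs = m.observed_dose
    return calls


def random_stream(rng: np.random.Generator, max_events: int = 50) -> EventBundle:
    """A small adversarial stream: ties, ranges, orphan-free audits,
    wrong units, MARs before/after orders, occasional discontinuation."""
    unit = "Units/hr"
    base = datetime(2018, 1, 1, tzinfo=timezone.utc)
    n_patients = int(rng.integers(1, 4))
    bundle = EventBundle()
    budget = max_events
    grid = np.arange(1.0, 10.5, 0.5)
    for p in range(n_patients):
        if budget <= 2:
            break
        pid = f"P{p}"
        n_orders = int(rng.integers(0, 3))
        order_ids = []
        for oi in range(n_orders):
            if budget <= 0:
                break
            t = base + timedelta(minutes=int(rng.integers(0, 2000)))
            is_range = rng.random() < 0.3
            if is_range:
                lo, hi = sorted(rng.choice(grid, 2, replace=False))
                dose = DoseSpec(float(lo), float(hi), unit)
            else:
                dose = DoseSpec(float(rng.choice(grid)), None, unit)
            disc = None
            if rng.random() < 0.2:
                disc = t + timedelta(minutes=int(rng.integers(60, 1500)))
            oid = f"P{p}O{oi}"
            bundle.orders.append(OrderEvent(
                oid, pid, "NICU", "insulin", dose, t,
                t + timedelta(minutes=int(rng.integers(0, 45))),
                status="discontinued" if disc else "active", discontinue_time=disc))
            order_ids.append((oid, t))
            budget -= 1
        for oid, t in order_ids:
            for _ in range(int(rng.integers(0, 3))):
                if budget <= 0:
                    break
                at = t + timedelta(minutes=int(rng.integers(0, 2000)))
                old = DoseSpec(float(rng.choice(grid)), None, unit)
                new = DoseSpec(float(rng.choice(grid)), None, unit)
                bundle.audits.append(AuditEvent(oid, at, old, new))
                budget -= 1
        for mi in range(int(rng.integers(0, 12))):
            if budget <= 0:
                break
            t = base + timedelta(minutes=int(rng.integers(-100, 3000)))
            mar_unit = unit if rng.random() > 0.1 else "mL/hr"
            action = str(rng.choice(["start", "rate verify", "rate change", "other"]))
            bundle.mars.append(MAREvent(
                f"P{p}M{mi}", pid, "NICU", "insulin", action,
                float(rng.choice(grid)) if rng.random() > 0.2 else round(float(rng.uniform(0, 12)), 3),
                mar_unit, t))
            budget -= 1
    return bundle
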