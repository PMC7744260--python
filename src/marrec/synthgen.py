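"""Seeded generator of synthetic medication-use event streams.

Real medication-use extracts are proprietary, so every test and demo runs
on synthetic streams that reproduce the *structures* the detector cares
about, with full ground truth:

* per-department/medication order volumes, audit-per-order rates and MAR
  cadences (including the high-frequency hourly rate-verify pattern);
* dose-range orders with within-range titration;
* verbal-order documentation lag: the bedside change is documented on the
  MAR first and the corresponding order audit is entered minutes later —
  only entry times are shifted, clinical intent times stay truthful;
* the ETL overwrite corruption in which an order's stored value is
  replaced by its last audit's new value;
* true administration discrepancies injected per-MAR with a controllable
  probability (injected values are drawn off the medication's plausible
  dose grid and outside any range bounds so they are unambiguously wrong).

Everything is driven by one integer seed through a single
:class:`numpy.random.Generator`; the same profile and seed produce
byte-identical extracts.  Dose values come from per-medication grids
(e.g. 0.5-step Units/hr for insulin) so tolerance logic is exercised
without float pathologies.  No clinical realism beyond what the detector
consumes: no labs, weights or demographics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .datamodel import (
    AuditEvent,
    CommOrderText,
    DoseSpec,
    MAREvent,
    Medication,
    MedicationRegistry,
    OrderEvent,
    default_registry,
)
from .io_mapping import EventBundle

__all__ = [
    "StreamProfile",
    "SiteProfile",
    "GroundTruth",
    "Scenario",
    "generate_site",
    "inject_overwrite_corruption",
    "make_scenarios",
    "load_profile",
    "demo_profile",
]

_EPOCH = datetime(2018, 1, 1, tzinfo=timezone.utc)

#: plausible dose grids per medication (values in the canonical unit)
_DOSE_GRIDS: dict[str, np.ndarray] = {
    "insulin": np.arange(0.5, 10.01, 0.5),
    "dopamine": np.arange(2.0, 20.01, 1.0),
    "dobutamine": np.arange(2.0, 20.01, 1.0),
    "epinephrine": np.arange(0.05, 1.001, 0.05),
    "fentanyl": np.arange(0.5, 5.01, 0.5),
    "morphine": np.arange(0.5, 5.01, 0.5),
    "milrinone": np.arange(0.25, 1.001, 0.25),
    "vasopressin": np.arange(0.1, 1.001, 0.1),
    "intravenous fluids": np.arange(10.0, 200.01, 5.0),
    "lipids": np.arange(5.0, 30.01, 2.5),
    "total parenteral nutrition": np.arange(10.0, 150.01, 5.0),
}
_DEFAULT_GRID = np.arange(1.0, 10.01, 0.5)

_MAR_ACTION_CHOICES = np.array(["rate verify", "new bag", "restart", "rate change"])
_MAR_ACTION_PROBS = np.array([0.75, 0.10, 0.05, 0.10])


def _grid_for(medication: str) -> np.ndarray:
    return np.round(_DOSE_GRIDS.get(medication, _DEFAULT_GRID), 4)


@dataclass
class StreamProfile:
    """Generation parameters for one (department, medication) stream."""

    department: str
    medication: str
    n_orders: int = 30
    audits_per_order: float = 1.0  # Poisson mean modifications per order
    mar_interval_minutes: float = 60.0  # mean inter-MAR interval (exponential)
    order_span_hours: float = 48.0  # dosing episode length per order
    range_order_fraction: float = 0.0
    titration_interval_minutes: float = 240.0  # within-range retitration cadence
    discrepancy_probability: float = 0.0  # per-MAR injection probability
    verbal_order_fraction: float = 0.0  # fraction of audits entered late
    verbal_lag_minutes_mean: float = 45.0

    def violations(self) -> list[str]:
        out = []
        for name in ("range_order_fraction", "discrepancy_probability", "verbal_order_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                out.append(f"{name} must be in [0, 1], got {v}")
        if self.n_orders < 0:
            out.append("n_orders must be >= 0")
        if self.n_orders > 0 and self.mar_interval_minutes <= 0:
            out.append("mar_interval_minutes must be positive when orders are generated")
        if self.order_span_hours <= 0:
            out.append("order_span_hours must be positive")
        return out


@dataclass
class SiteProfile:
    site_label: str
    seed: int
    streams: list[StreamProfile]
    overwrite_corruption: bool = False

    def violations(self) -> list[str]:
        out = []
        if self.seed is None:
            out.append("seed is mandatory")
        for i, s in enumerate(self.streams):
            out += [f"stream {i}: {v}" for v in s.violations()]
        return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the detector must rediscover."""

    injected_mar_ids: list[str] = field(default_factory=list)
    verbal_pairs: list[dict] = field(default_factory=list)  # order_id, change_time, lag_minutes
    range_order_ids: list[str] = field(default_factory=list)
    original_doses: dict[str, DoseSpec] = field(default_factory=dict)  # pre-corruption
    configured_counts: dict[str, int] = field(default_factory=dict)  # "dept|med" -> n_orders

    def to_records(self) -> list[dict]:
        recs: list[dict] = [
            {"kind": "configured", "stratum": k, "n_orders": v}
            for k, v in sorted(self.configured_counts.items())
        ]
        recs += [{"kind": "injected", "mar_id": m} for m in self.injected_mar_ids]
        recs += [{"kind": "verbal", **p} for p in self.verbal_pairs]
        recs += [{"kind": "range_order", "order_id": o} for o in self.range_order_ids]
        recs += [
            {"kind": "original_dose", "order_id": o, **d.to_dict()}
            for o, d in sorted(self.original_doses.items())
        ]
        return recs


def inject_overwrite_corruption(
    orders: Sequence[OrderEvent], audits: Sequence[AuditEvent]
) -> tuple[list[OrderEvent], dict[str, DoseSpec]]:
    """Simulate the retrospective-database ETL artifact.

    Every order with at least one audit has its stored dose replaced by its
    *last* audit's new value; orders without audits are untouched.  Returns
    the corrupted orders plus the map of original doses for ground truth.
    """
    from dataclasses import replace

    last_new: dict[str, tuple[datetime, DoseSpec]] = {}
    for a in audits:
        cur = last_new.get(a.order_id)
        if cur is None or a.audit_time >= cur[0]:
            last_new[a.order_id] = (a.audit_time, a.new_dose)
    out: list[OrderEvent] = []
    originals: dict[str, DoseSpec] = {}
    for o in orders:
        hit = last_new.get(o.order_id)
        if hit is None:
            out.append(o)
        else:
            originals[o.order_id] = o.dose
            out.append(replace(o, dose=hit[1]))
    return out, originals


def _pick_dose(rng: np.random.Generator, grid: np.ndarray,
               exclude: Optional[float] = None) -> float:
    """Uniform grid choice, avoiding ``exclude`` when possible."""
    if exclude is not None and len(grid) > 1:
        grid = grid[np.round(np.abs(grid - exclude), 6) > 1e-9]
    return float(rng.choice(grid))


def _pick_range(rng: np.random.Generator, grid: np.ndarray) -> tuple[float, float]:
    i, j = sorted(rng.choice(len(grid), size=2, replace=False))
    return float(grid[i]), float(grid[j])


def _off_grid_value(rng: np.random.Generator, base: float) -> float:
    """A value strictly above ``base`` that sits off every dose grid."""
    k = int(rng.integers(131, 770))
    if k % 50 == 0:  # keep clear of grid-step multiples
        k += 7
    return round(base + k / 1000.0, 4)


def generate_site(profile: SiteProfile, registry: Optional[MedicationRegistry] = None
                  ) -> tuple[EventBundle, GroundTruth]:
    """Generate one site's four event streams plus ground truth.

    Deterministic in ``profile.seed``: the same profile yields identical
    events, identifiers and extract bytes.
    """
    problems = profile.violations()
    if problems:
        raise ValueError("infeasible site profile: " + "; ".join(problems))
    registry = registry if registry is not None else default_registry()
    rng = np.random.default_rng(profile.seed)
    bundle = EventBundle()
    truth = GroundTruth()

    for si, sp in enumerate(profile.streams):
        med = registry.get(sp.medication)
        unit = med.canonical_unit if med else "mL/hr"
        grid = _grid_for(sp.medication)
        truth.configured_counts[f"{sp.department}|{sp.medication}"] = sp.n_orders

        for oi in range(sp.n_orders):
            order_id = f"O{si}-{oi}"
            patient_id = f"P{si}-{oi}"
            start = _EPOCH + timedelta(minutes=float(rng.uniform(0, 364 * 24 * 60)))
            span = timedelta(hours=sp.order_span_hours)

            is_range = bool(rng.random() < sp.range_order_fraction)
            if is_range:
                low, high = _pick_range(rng, grid)
                dose = DoseSpec(low, high, unit)
                truth.range_order_ids.append(order_id)
            else:
                dose = DoseSpec(_pick_dose(rng, grid), None, unit)

            order = OrderEvent(
                order_id=order_id, patient_id=patient_id,
                department=sp.department, medication=sp.medication,
                dose=dose, order_time=start, entry_time=start,
            )
            bundle.orders.append(order)

            # --- audit chain (clinical change times; entry may lag) ---
            n_audits = int(rng.poisson(sp.audits_per_order))
            change_offsets = np.sort(rng.uniform(60.0, span.total_seconds() / 60.0 - 60.0,
                                                 size=n_audits)) if n_audits else []
            changes: list[tuple[datetime, DoseSpec]] = [(start, dose)]
            current = dose
            for off in change_offsets:
                change_time = start + timedelta(minutes=float(off))
                if is_range:
                    lo, hi = _pick_range(rng, grid)
                    new = DoseSpec(lo, hi, unit)
                else:
                    new = DoseSpec(_pick_dose(rng, grid, exclude=current.low), None, unit)
                lag = 0.0
                if rng.random() < sp.verbal_order_fraction:
                    lag = float(np.clip(rng.exponential(sp.verbal_lag_minutes_mean), 5.0, 240.0))
                    truth.verbal_pairs.append({
                        "order_id": order_id,
                        "change_time": change_time.isoformat(),
                        "lag_minutes": round(lag, 2),
                    })
                bundle.audits.append(AuditEvent(
                    order_id=order_id,
                    audit_time=change_time + timedelta(minutes=lag),
                    old_dose=current, new_dose=new,
                ))
                changes.append((change_time, new))
                current = new

            # --- MAR documentation ---
            change_times = [c[0] for c in changes]
            titration_value: Optional[float] = None
            next_titration = start
            t = start + timedelta(minutes=1)
            seq = 0
            first = True
            while t < start + span:
                # dose clinically in force at t (bedside truth, not entry times)
                ci = int(np.searchsorted(np.array([ct.timestamp() for ct in change_times]),
                                         t.timestamp(), side="right")) - 1
                in_force = changes[max(ci, 0)][1]
                if in_force.is_range:
                    if titration_value is None or t >= next_titration or not (
                        in_force.low <= titration_value <= in_force.high
                    ):
                        sub = grid[(grid >= in_force.low) & (grid <= in_force.high)]
                        titration_value = float(rng.choice(sub)) if len(sub) else in_force.low
                        next_titration = t + timedelta(minutes=sp.titration_interval_minutes)
                    observed = titration_value
                else:
                    observed = in_force.low

                mar_id = f"M{si}-{oi}-{seq}"
                if rng.random() < sp.discrepancy_probability:
                    base = in_force.high if in_force.is_range else in_force.low
                    observed = _off_grid_value(rng, base)
                    truth.injected_mar_ids.append(mar_id)

                action = "start" if first else str(
                    rng.choice(_MAR_ACTION_CHOICES, p=_MAR_ACTION_PROBS))
                bundle.mars.append(MAREvent(
                    mar_id=mar_id, patient_id=patient_id,
                    department=sp.department, medication=sp.medication,
                    action=action, observed_dose=observed, unit=unit, mar_time=t,
                ))
                first = False
                seq += 1
                t += timedelta(minutes=max(1.0, float(rng.exponential(sp.mar_interval_minutes))))

    if profile.overwrite_corruption:
        bundle.orders, originals = inject_overwrite_corruption(bundle.orders, bundle.audits)
        truth.original_doses.update(originals)

    return bundle, truth


# ---------------------------------------------------------------------------
# Worked scenario fixtures
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A small deterministic fixture reproducing one failure mode."""

    name: str
    bundle: EventBundle
    pristine_orders: list[OrderEvent] = field(default_factory=list)
    notes: str = ""


def _t(month: int, day: int, hour: int, minute: int = 0) -> datetime:
    return datetime(2018, month, day, hour, minute, tzinfo=timezone.utc)


def make_scenarios() -> dict[str, Scenario]:
    """The three worked failure-mode fixtures.

    ``range_order``
        An insulin order for 1-10 Units/hr, widened to 1-20 Units/hr about
        six hours later, with in-range bedside titrations on the MAR.
        Legacy lower-bound interpretation flags every titration; range-aware
        interpretation flags nothing.
    ``overwrite``
        An insulin order originally for 5.0 Units/hr whose stored value was
        overwritten by its audit chain (5 -> 4, then 4 -> 3) down to
        3.0 Units/hr.  Without recovery, the earliest MARs documenting 5.0
        look discrepant (only the first is called; repeats are suppressed).
    ``verbal_lag``
        A verbal rate change to 4.0 Units/hr documented on the MAR 76
        minutes before the order audit was entered.  Under the default
        30-minute window the MAR is flagged; a window of at least 76
        minutes clears it.
    """
    unit = "Units/hr"
    scenarios: dict[str, Scenario] = {}

    # -- range_order --
    t0 = _t(3, 5, 8)
    order = OrderEvent("O-RNG-1", "P-RNG", "NICU", "insulin",
                       DoseSpec(1.0, 10.0, unit), t0, t0)
    audit = AuditEvent("O-RNG-1", t0 + timedelta(hours=6),
                       old_dose=DoseSpec(1.0, 10.0, unit),
                       new_dose=DoseSpec(1.0, 20.0, unit))
    mars = [
        MAREvent("M-RNG-0", "P-RNG", "NICU", "insulin", "start", 1.0, unit,
                 t0 + timedelta(minutes=5)),
        MAREvent("M-RNG-1", "P-RNG", "NICU", "insulin", "rate change", 4.0, unit,
                 t0 + timedelta(hours=2)),
        MAREvent("M-RNG-2", "P-RNG", "NICU", "insulin", "rate verify", 6.0, unit,
                 t0 + timedelta(hours=4)),
        MAREvent("M-RNG-3", "P-RNG", "NICU", "insulin", "rate change", 15.0, unit,
                 t0 + timedelta(hours=8)),
    ]
    scenarios["range_order"] = Scenario(
        "range_order",
        EventBundle(orders=[order], audits=[audit], mars=mars),
        notes="in-range titrations; discrepant only under legacy-lower-bound",
    )

    # -- overwrite --
    t0 = _t(4, 10, 9)
    pristine = OrderEvent("O-OVR-1", "P-OVR", "NICU", "insulin",
                          DoseSpec(5.0, None, unit), t0, t0)
    audits = [
        AuditEvent("O-OVR-1", t0 + timedelta(hours=4),
                   old_dose=DoseSpec(5.0, None, unit), new_dose=DoseSpec(4.0, None, unit)),
        AuditEvent("O-OVR-1", t0 + timedelta(hours=8),
                   old_dose=DoseSpec(4.0, None, unit), new_dose=DoseSpec(3.0, None, unit)),
    ]
    corrupted, _ = inject_overwrite_corruption([pristine], audits)
    mars = [
        MAREvent("M-OVR-0", "P-OVR", "NICU", "insulin", "start", 5.0, unit,
                 t0 + timedelta(minutes=10)),
        MAREvent("M-OVR-1", "P-OVR", "NICU", "insulin", "rate verify", 5.0, unit,
                 t0 + timedelta(hours=1)),
        MAREvent("M-OVR-2", "P-OVR", "NICU", "insulin", "rate verify", 5.0, unit,
                 t0 + timedelta(hours=2)),
        MAREvent("M-OVR-3", "P-OVR", "NICU", "insulin", "rate change", 4.0, unit,
                 t0 + timedelta(hours=4, minutes=5)),
        MAREvent("M-OVR-4", "P-OVR", "NICU", "insulin", "rate change", 3.0, unit,
                 t0 + timedelta(hours=8, minutes=5)),
    ]
    scenarios["overwrite"] = Scenario(
        "overwrite",
        EventBundle(orders=corrupted, audits=audits, mars=mars),
        pristine_orders=[pristine],
        notes="stored order value reflects last audit; original recoverable from first audit",
    )

    # -- verbal_lag --
    t0 = _t(6, 20, 14)
    order = OrderEvent("O-VRB-1", "P-VRB", "NICU", "insulin",
                       DoseSpec(5.0, None, unit), t0, t0)
    change = t0 + timedelta(hours=3)
    audit = AuditEvent("O-VRB-1", change + timedelta(minutes=76),
                       old_dose=DoseSpec(5.0, None, unit), new_dose=DoseSpec(4.0, None, unit))
    mars = [
        MAREvent("M-VRB-0", "P-VRB", "NICU", "insulin", "start", 5.0, unit,
                 t0 + timedelta(minutes=10)),
        MAREvent("M-VRB-1", "P-VRB", "NICU", "insulin", "rate change", 4.0, unit, change),
    ]
    scenarios["verbal_lag"] = Scenario(
        "verbal_lag",
        EventBundle(orders=[order], audits=[audit], mars=mars),
        notes="bedside change documented 76 minutes before the audit entry",
    )
    return scenarios


# ---------------------------------------------------------------------------
# Profile config files
# ---------------------------------------------------------------------------

def load_profile(path: str | Path) -> SiteProfile:
    """Load a site profile from YAML and validate it."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "streams" not in raw or "seed" not in raw:
        raise ValueError(f"profile {path} must define 'seed' and 'streams'")
    streams = [StreamProfile(**s) for s in raw["streams"]]
    profile = SiteProfile(
        site_label=str(raw.get("site_label", "site")),
        seed=int(raw["seed"]),
        streams=streams,
        overwrite_corruption=bool(raw.get("overwrite_corruption", False)),
    )
    problems = profile.violations()
    if problems:
        raise ValueError("invalid profile: " + "; ".join(problems))
    return profile


def demo_profile(seed: int, site_label: str = "synthetic-site") -> SiteProfile:
    """A small multi-department demo site exercising every mechanism."""
    return SiteProfile(
        site_label=site_label,
        seed=seed,
        streams=[
            StreamProfile("NICU", "insulin", n_orders=12, audits_per_order=0.9,
                          range_order_fraction=0.4, discrepancy_probability=0.02,
                          verbal_order_fraction=0.1),
            StreamProfile("NICU", "milrinone", n_orders=8, audits_per_order=0.5,
                          mar_interval_minutes=60.0),
            StreamProfile("NICU", "dopamine", n_orders=10, audits_per_order=3.0,
                          discrepancy_probability=0.01),
            StreamProfile("PICU", "fentanyl", n_orders=10, audits_per_order=1.2,
                          verbal_order_fraction=0.1),
            StreamProfile("adult medical ICU", "insulin", n_orders=8,
                          range_order_fraction=0.6),
        ],
    )
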