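"""Timeline assembly, original-value recovery, effective-dose queries."""

import random
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from marrec.datamodel import (
    AuditEvent,
    DetectorConfig,
    DoseDirective,
    DoseSpec,
    MAREvent,
    OrderEvent,
)
from marrec.synthgen import (
    SiteProfile,
    StreamProfile,
    generate_site,
    inject_overwrite_corruption,
)
from marrec.timeline import build_timeline, effective_dose_at, recover_original_orders

T0 = datetime(2018, 4, 10, 9, 0, tzinfo=timezone.utc)
U = "Units/hr"


def dose(low, high=None):
    return DoseSpec(low, high, U)


def make_order(d, order_id="O1", **kw):
    defaults = dict(patient_id="P1", department="NICU", medication="insulin",
                    order_time=T0, entry_time=T0)
    defaults.update(kw)
    return OrderEvent(order_id=order_id, dose=d, **defaults)


class TestRecovery:
    def audits(self):
        return [
            AuditEvent("O1", T0 + timedelta(hours=4), dose(5.0), dose(4.0)),
            AuditEvent("O1", T0 + timedelta(hours=8), dose(4.0), dose(3.0)),
        ]

    def test_overwritten_order_recovers_first_audits_old_value(self):
        stored = make_order(dose(3.0))  # stored value reflects the last audit
        recovered, report = recover_original_orders([stored], self.audits())
        assert recovered[0].dose == dose(5.0)
        assert report.rewrites[0]["order_id"] == "O1"
        assert report.rewrites[0]["n_audits"] == 2

    def test_order_without_audits_unchanged(self):
        o = make_order(dose(3.0), order_id="O9")
        recovered, report = recover_original_orders([o], self.audits())
        assert recovered == [o]
        assert report.rewrites == []

    def test_order_not_matching_overwrite_signature_unchanged(self):
        # stored dose already equals the first audit's old value: nothing to fix
        o = make_order(dose(5.0))
        recovered, report = recover_original_orders([o], self.audits())
        assert recovered == [o]
        assert report.rewrites == []

    def test_unknown_old_values_leave_order_flagged_unrecoverable(self):
        audits = [AuditEvent("O1", T0 + timedelta(hours=4), None, dose(3.0))]
        stored = make_order(dose(3.0))
        recovered, report = recover_original_orders([stored], audits)
        assert recovered == [stored]
        assert report.unrecoverable == ["O1"]

    def test_recovery_is_idempotent(self):
        stored = make_order(dose(3.0))
        once, _ = recover_original_orders([stored], self.audits())
        twice, report = recover_original_orders(once, self.audits())
        assert twice == once
        assert report.rewrites == []

    def test_corruption_recovery_round_trip_many_seeded_orders(self):
        profile = SiteProfile("site", seed=42, streams=[
            StreamProfile("NICU", "insulin", n_orders=500, audits_per_order=1.5,
                          mar_interval_minutes=600.0, range_order_fraction=0.3),
            StreamProfile("PICU", "dopamine", n_orders=500, audits_per_order=2.0,
                          mar_interval_minutes=600.0),
        ], overwrite_corruption=True)
        bundle, truth = generate_site(profile)
        assert len(bundle.orders) == 1000
        recovered, _ = recover_original_orders(bundle.orders, bundle.audits)
        by_id = {o.order_id: o for o in recovered}
        assert truth.original_doses  # corruption actually happened
        for order_id, original in truth.original_doses.items():
            assert by_id[order_id].dose == original

    def test_recovery_report_tsv_lists_every_rewrite(self):
        stored = make_order(dose(3.0))
        _, report = recover_original_orders([stored], self.audits())
        tsv = report.to_tsv()
        assert tsv.splitlines()[0].startswith("order_id\t")
        assert "O1\t3.0\t\t5.0\t\t2" in tsv


class TestBuildTimeline:
    def test_no_events_yield_empty_collection(self):
        ts = build_timeline([], [], [], [], DetectorConfig())
        assert len(ts) == 0

    def test_range_doses_preserved_through_audit(self):
        # a 1-10 range order widened to 1-20 six hours later: two states
        o = make_order(dose(1.0, 10.0))
        a = AuditEvent("O1", T0 + timedelta(hours=6), dose(1.0, 10.0), dose(1.0, 20.0))
        ts = build_timeline([o], [a], [], [], DetectorConfig())
        tl = ts.get("P1", "insulin")
        assert [s.dose for s in tl.states] == [dose(1.0, 10.0), dose(1.0, 20.0)]

    def test_orphan_audit_is_skipped_with_warning(self):
        a = AuditEvent("NOPE", T0, dose(5.0), dose(4.0))
        ts = build_timeline([make_order(dose(5.0))], [a], [], [], DetectorConfig())
        assert any("orphan audit" in w for w in ts.warnings)
        assert len(ts.get("P1", "insulin").states) == 1

    def test_mars_filtered_by_action(self):
        mars = [
            MAREvent("M1", "P1", "NICU", "insulin", "rate verify", 5.0, U, T0),
            MAREvent("M2", "P1", "NICU", "insulin", "other", 5.0, U, T0),
        ]
        ts = build_timeline([make_order(dose(5.0))], [], [], mars, DetectorConfig())
        assert [m.mar_id for m in ts.get("P1", "insulin").mars] == ["M1"]

    def test_input_order_invariance(self):
        rng = random.Random(5)
        orders = [make_order(dose(5.0)),
                  make_order(dose(2.0), order_id="O2", patient_id="P2")]
        audits = [AuditEvent("O1", T0 + timedelta(hours=i), dose(5.0), dose(4.0 + i))
                  for i in range(1, 5)]
        mars = [MAREvent(f"M{i}", "P1", "NICU", "insulin", "rate verify", 4.0, U,
                         T0 + timedelta(minutes=30 * i)) for i in range(6)]
        reference = build_timeline(orders, audits, [], mars, DetectorConfig())
        for _ in range(5):
            o, a, m = orders[:], audits[:], mars[:]
            rng.shuffle(o); rng.shuffle(a); rng.shuffle(m)
            ts = build_timeline(o, a, [], m, DetectorConfig())
            for key, tl in reference.timelines.items():
                other = ts.timelines[key]
                assert other.states == tl.states
                assert other.mars == tl.mars

    def test_audit_supersedes_order_at_equal_instant(self):
        o = make_order(dose(5.0))
        a = AuditEvent("O1", T0, dose(5.0), dose(4.0))
        tl = build_timeline([o], [a], [], [], DetectorConfig()).get("P1", "insulin")
        assert effective_dose_at(tl, T0) == dose(4.0)

    def test_discontinued_order_ends_its_dose_state(self):
        end = T0 + timedelta(days=1)
        o = make_order(dose(5.0), status="discontinued", discontinue_time=end)
        tl = build_timeline([o], [], [], [], DetectorConfig()).get("P1", "insulin")
        assert effective_dose_at(tl, end - timedelta(minutes=1)) == dose(5.0)
        assert effective_dose_at(tl, end + timedelta(minutes=1)) is None

    def test_resolvable_directive_becomes_a_state(self):
        o = make_order(dose(2.0))
        d = DoseDirective("P1", "insulin", "increase-by", 1.5, U,
                          T0 + timedelta(hours=2), provenance="C1")
        tl = build_timeline([o], [], [d], [], DetectorConfig()).get("P1", "insulin")
        assert effective_dose_at(tl, T0 + timedelta(hours=3)) == dose(3.5)

    def test_unresolved_directive_excluded_with_warning(self):
        # relative directive before any order: current dose unknown
        d = DoseDirective("P1", "insulin", "increase-by", 1.5, U,
                          T0 - timedelta(hours=2), provenance="C1")
        ts = build_timeline([make_order(dose(2.0))], [], [d], [], DetectorConfig())
        assert any("unresolved directive" in w for w in ts.warnings)
        assert len(ts.get("P1", "insulin").states) == 1


class TestEffectiveDoseAt:
    def test_before_first_state_is_none(self):
        tl = build_timeline([make_order(dose(5.0))], [], [], [], DetectorConfig()).get("P1", "insulin")
        assert effective_dose_at(tl, T0 - timedelta(seconds=1)) is None

    def test_boundary_belongs_to_the_new_state(self):
        a = AuditEvent("O1", T0 + timedelta(hours=1), dose(5.0), dose(4.0))
        tl = build_timeline([make_order(dose(5.0))], [a], [], [], DetectorConfig()).get("P1", "insulin")
        assert effective_dose_at(tl, T0 + timedelta(hours=1)) == dose(4.0)

    def test_agrees_with_linear_scan_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        audits = [
            AuditEvent("O1", T0 + timedelta(minutes=int(m)), dose(5.0),
                       dose(float(rng.integers(1, 10))))
            for m in sorted(rng.choice(np.arange(10, 5000), size=40, replace=False))
        ]
        tl = build_timeline([make_order(dose(5.0))], audits, [], [], DetectorConfig()).get("P1", "insulin")

        def oracle(t):
            best = None
            for s in tl.states:
                if s.effective_from <= t:
                    best = s.dose
            return best

        for _ in range(1000):
            t = T0 + timedelta(minutes=float(rng.uniform(-100, 5200)))
            assert effective_dose_at(tl, t) == oracle(t)
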