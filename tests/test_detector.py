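"""Discrepancy detection: matching, grace window, suppression, rates."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from conftest import run_pipeline
from marrec.datamodel import (
    AuditEvent,
    DetectorConfig,
    DiscrepancyCall,
    DoseSpec,
    MAREvent,
    OrderEvent,
)
from marrec.detector import (
    detect,
    discrepancy_rate,
    expected_comparison_value,
    match_dose,
)
from marrec.io_mapping import EventBundle
from marrec.synthgen import SiteProfile, StreamProfile, generate_site
from marrec.timeline import build_timeline

T0 = datetime(2018, 6, 1, 8, 0, tzinfo=timezone.utc)
U = "Units/hr"
LEGACY = DetectorConfig(range_mode="legacy-lower-bound")


def dose(low, high=None):
    return DoseSpec(low, high, U)


def mar(mar_id, observed, minutes, action="rate verify", unit=U):
    return MAREvent(mar_id, "P1", "NICU", "insulin", action, observed, unit,
                    T0 + timedelta(minutes=minutes))


def order(d, **kw):
    defaults = dict(order_id="O1", patient_id="P1", department="NICU",
                    medication="insulin", order_time=T0, entry_time=T0)
    defaults.update(kw)
    return OrderEvent(dose=d, **defaults)


class TestMatchDose:
    @pytest.mark.parametrize(
        "expected, observed, cfg, matches",
        [
            (dose(1.0, 10.0), 6.0, LEGACY, False),  # legacy compares the lower bound only
            (dose(1.0, 10.0), 6.0, DetectorConfig(), True),  # range-aware accepts in-range
            (dose(1.0, 10.0), 1.0, LEGACY, True),
            (dose(1.0, 10.0), 10.0, DetectorConfig(), True),  # inclusive at bounds
            (dose(1.0, 10.0), 10.5, DetectorConfig(), False),
            (dose(1.0, 10.0), 0.5, DetectorConfig(), False),
            (dose(4.0), 4.0, DetectorConfig(), True),
            (dose(4.0), 4.5, DetectorConfig(), False),
            (dose(4.0), 4.0 + 1e-9, DetectorConfig(), True),  # ingestion noise
        ],
    )
    def test_matching_semantics(self, expected, observed, cfg, matches):
        assert match_dose(expected, observed, cfg) is matches

    def test_legacy_comparison_value_is_the_range_lower_bound(self):
        assert expected_comparison_value(dose(1.0, 10.0), LEGACY) == 1.0
        assert expected_comparison_value(dose(4.0), DetectorConfig()) == 4.0

    def test_range_aware_range_has_no_single_comparison_value(self):
        with pytest.raises(ValueError):
            expected_comparison_value(dose(1.0, 10.0), DetectorConfig())


class TestScenarioOverwrite:
    def test_only_first_mar_called_without_recovery(self, scenarios):
        calls = run_pipeline(scenarios["overwrite"].bundle)
        unsuppressed = [c for c in calls if not c.suppressed]
        assert [c.mar.mar_id for c in unsuppressed] == ["M-OVR-0"]
        assert unsuppressed[0].reason == "dose-mismatch"
        # repeats of the same wrong value are emitted but suppressed
        assert [c.mar.mar_id for c in calls if c.suppressed] == ["M-OVR-1", "M-OVR-2"]

    def test_recovery_removes_every_call(self, scenarios):
        assert run_pipeline(scenarios["overwrite"].bundle, recover=True) == []


class TestScenarioVerbalLag:
    def test_flagged_under_default_window(self, scenarios):
        calls = run_pipeline(scenarios["verbal_lag"].bundle)
        assert [(c.mar.mar_id, c.suppressed) for c in calls] == [("M-VRB-1", False)]

    @pytest.mark.parametrize("window, n_calls", [(0, 1), (30, 1), (75, 1), (76, 0), (120, 0)])
    def test_window_sweep_clears_at_the_documented_lag(self, scenarios, window, n_calls):
        cfg = DetectorConfig(grace_window_minutes=window)
        assert len(run_pipeline(scenarios["verbal_lag"].bundle, cfg)) == n_calls


class TestScenarioRangeOrder:
    def test_legacy_mode_flags_in_range_titrations(self, scenarios):
        calls = run_pipeline(scenarios["range_order"].bundle, LEGACY)
        assert [c.mar.mar_id for c in calls] == ["M-RNG-1", "M-RNG-2", "M-RNG-3"]
        assert all(not c.suppressed for c in calls)  # distinct values never suppress

    def test_range_aware_mode_is_silent_on_the_same_stream(self, scenarios):
        assert run_pipeline(scenarios["range_order"].bundle) == []


class TestGraceWindow:
    def test_late_entered_order_clears_earlier_mar(self):
        # MAR documented 30 min before the matching order was typed in
        o = order(dose(4.0), order_time=T0, entry_time=T0 + timedelta(minutes=20))
        m_early = mar("M0", 4.0, minutes=-10)
        bundle = EventBundle(orders=[o], mars=[m_early])
        assert run_pipeline(bundle) == []  # default 30-min window covers the lag
        calls = run_pipeline(bundle, DetectorConfig(grace_window_minutes=10))
        assert [c.reason for c in calls] == ["no-active-order"]

    def test_clearing_requires_matching_value(self):
        o = order(dose(4.0), order_time=T0, entry_time=T0 + timedelta(minutes=20))
        m = mar("M0", 3.0, minutes=-10)  # wrong value: entry does not clear it
        calls = run_pipeline(EventBundle(orders=[o], mars=[m]))
        assert [c.reason for c in calls] == ["no-active-order"]

    def test_window_is_one_sided(self):
        # an entry BEFORE the MAR never clears it
        o = order(dose(5.0))
        a = AuditEvent("O1", T0 + timedelta(minutes=30), dose(5.0), dose(4.0))
        m = mar("M1", 6.0, minutes=60)  # matches nothing, audit entry is in the past
        calls = run_pipeline(EventBundle(orders=[o], audits=[a], mars=[m]))
        assert len(calls) == 1

    def test_negative_window_is_a_config_error(self):
        ts = build_timeline([], [], [], [], DetectorConfig())
        with pytest.raises(ValueError, match="grace_window_minutes"):
            detect(ts, DetectorConfig(grace_window_minutes=-1))


class TestSuppression:
    def base(self):
        return order(dose(5.0))

    def test_repeated_wrong_value_suppressed_until_value_changes(self):
        mars = [mar("M0", 4.0, 10), mar("M1", 4.0, 20), mar("M2", 3.0, 30),
                mar("M3", 3.0, 40)]
        calls = run_pipeline(EventBundle(orders=[self.base()], mars=mars))
        assert [(c.mar.mar_id, c.suppressed) for c in calls] == [
            ("M0", False), ("M1", True), ("M2", False), ("M3", True)]

    def test_non_discrepant_mar_resets_suppression(self):
        mars = [mar("M0", 4.0, 10), mar("M1", 5.0, 20), mar("M2", 4.0, 30)]
        calls = run_pipeline(EventBundle(orders=[self.base()], mars=mars))
        assert [(c.mar.mar_id, c.suppressed) for c in calls] == [
            ("M0", False), ("M2", False)]

    def test_perfect_adherence_stream_yields_no_calls(self):
        mars = [mar(f"M{i}", 5.0, 10 * i) for i in range(1, 20)]
        assert run_pipeline(EventBundle(orders=[self.base()], mars=mars)) == []


class TestReasons:
    def test_unit_mismatch_is_distinct_and_never_coerced(self):
        m = mar("M1", 5.0, 30, unit="mL/hr")
        calls = run_pipeline(EventBundle(orders=[order(dose(5.0))], mars=[m]))
        assert [c.reason for c in calls] == ["unit-mismatch"]

    def test_mar_after_discontinuation_is_no_active_order(self):
        end = T0 + timedelta(hours=5)
        o = order(dose(5.0), status="discontinued", discontinue_time=end)
        m = mar("M1", 5.0, minutes=6 * 60)
        calls = run_pipeline(EventBundle(orders=[o], mars=[m]))
        assert [c.reason for c in calls] == ["no-active-order"]


class TestDiscrepancyRate:
    def c(self, suppressed):
        m = mar("M1", 4.0, 10)
        return DiscrepancyCall(m, dose(5.0), 4.0, "dose-mismatch", suppressed)

    def test_zero_calls(self):
        assert discrepancy_rate([], 200) == 0.0

    def test_suppressed_calls_are_excluded_from_the_numerator(self):
        calls = [self.c(False)] * 3 + [self.c(True)] * 2
        assert discrepancy_rate(calls, 100) == 3.0

    def test_zero_mars_is_undefined_not_zero(self):
        assert discrepancy_rate([self.c(False)], 0) is None


class TestStreamProperties:
    def test_determinism_identical_input_identical_calls(self):
        bundle, _ = generate_site(SiteProfile("s", seed=3, streams=[
            StreamProfile("NICU", "insulin", n_orders=10, audits_per_order=1.0,
                          discrepancy_probability=0.05, range_order_fraction=0.3,
                          verbal_order_fraction=0.2)]))
        a = run_pipeline(bundle)
        b = run_pipeline(bundle)
        assert a == b

    def test_range_aware_calls_subset_of_legacy_calls(self):
        bundle, _ = generate_site(SiteProfile("s", seed=9, streams=[
            StreamProfile("NICU", "insulin", n_orders=15, audits_per_order=1.0,
                          range_order_fraction=0.6, discrepancy_probability=0.05,
                          verbal_order_fraction=0.1)]))
        aware = {c.mar.mar_id for c in run_pipeline(bundle)}
        legacy = {c.mar.mar_id for c in run_pipeline(bundle, LEGACY)}
        assert aware <= legacy
        assert len(legacy) > len(aware)  # the stream does contain in-range titrations

    def test_unsuppressed_count_non_increasing_in_grace_window(self):
        bundle, _ = generate_site(SiteProfile("s", seed=21, streams=[
            StreamProfile("NICU", "insulin", n_orders=20, audits_per_order=1.5,
                          verbal_order_fraction=0.5, verbal_lag_minutes_mean=60.0,
                          discrepancy_probability=0.02)]))
        counts = []
        for w in (0, 15, 30, 45, 60, 90):
            cfg = DetectorConfig(grace_window_minutes=w)
            counts.append(sum(1 for c in run_pipeline(bundle, cfg) if not c.suppressed))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[-1]  # the sweep actually clears something
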