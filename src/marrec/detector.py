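"""Logic-based discrepancy detection between prescribed doses and MARs.

For every analyzed MAR (chronologically, per patient and medication) the
detector looks up the prescribed dose in force at the MAR's time and asks
whether the documented dose/rate matches it.  Three refinements prevent
over-calling:

* **Range modes** — range orders (e.g. insulin 1-10 Units/hr) are judged
  range-aware by default: any observed value inside the inclusive range
  matches.  ``legacy-lower-bound`` reproduces the original behavior of
  comparing only against the range's first value, which flags in-range
  titrations as false positives.
* **Grace window** — a candidate discrepancy is cleared when a matching
  order/audit is *entered* into the EHR within ``grace_window_minutes``
  after the MAR.  This absorbs the documentation lag of verbal orders
  executed at the bedside before they are typed in (default 30 minutes).
  The window is one-sided: only future entries clear a past MAR.
* **Suppression** — when consecutive MARs repeat the same discrepant
  value, only the first is called; the rest are emitted with
  ``suppressed=True`` and excluded from rates ("check the value with the
  previous MAR").  Suppression resets as soon as the MAR value changes or
  a non-discrepant MAR intervenes.

Reason codes: ``dose-mismatch``, ``no-active-order`` (no prescription in
force at the MAR, e.g. after discontinuation), ``unit-mismatch`` (never
silently coerced).
"""

from __future__ import annotations

from datetime import timedelta
from typing import Iterable, Optional, Sequence

from .datamodel import DetectorConfig, DiscrepancyCall, DoseSpec, MAREvent
from .timeline import Timeline, TimelineSet, effective_dose_at

__all__ = [
    "match_dose",
    "expected_comparison_value",
    "detect",
    "discrepancy_rate",
]


def _norm_unit(unit: str) -> str:
    return unit.strip().lower()


def expected_comparison_value(expected: DoseSpec, config: DetectorConfig) -> float:
    """The single discrete value the detector compares an MAR against.

    Discrete specs compare against their value.  Under
    ``legacy-lower-bound`` a range order collapses to its first (lower
    bound) value — the behavior that makes in-range titrations look
    discrepant.  A range under ``range-aware`` mode has no single
    comparison value; asking for one is an error.
    """
    if not expected.is_range or config.range_mode == "legacy-lower-bound":
        return expected.low
    raise ValueError("a range order in range-aware mode has no single comparison value")


def match_dose(expected: DoseSpec, observed: float, config: DetectorConfig) -> bool:
    """Does an observed MAR value satisfy the expected dose spec?"""
    if expected.is_range and config.range_mode == "range-aware":
        d = config.comparison_decimals
        ro = round(observed, d)
        rl, rh = round(expected.low, d), round(expected.high, d)
        tol = config.dose_tolerance
        return (rl - tol * max(1.0, abs(rl))) <= ro <= (rh + tol * max(1.0, abs(rh)))
    return config.values_equal(observed, expected_comparison_value(expected, config))


def _cleared_by_grace(timeline: Timeline, mar: MAREvent, config: DetectorConfig) -> bool:
    """A matching dose state entered within the window after the MAR?"""
    if config.grace_window_minutes == 0:
        return False
    horizon = mar.mar_time + timedelta(minutes=config.grace_window_minutes)
    for s in timeline.states:
        if s.dose is None:
            continue
        if not (mar.mar_time < s.entry_time <= horizon):
            continue
        if _norm_unit(s.dose.unit) != _norm_unit(mar.unit):
            continue
        if match_dose(s.dose, mar.observed_dose, config):
            return True
    return False


def detect(timelines: TimelineSet | Iterable[Timeline], config: Optional[DetectorConfig] = None) -> list[DiscrepancyCall]:
    """Run discrepancy detection over built timelines.

    Returns every call, suppressed ones included (flagged), in
    deterministic (patient, medication, time) order.  Only unsuppressed
    calls feed discrepancy rates.
    """
    config = config or DetectorConfig()
    problems = config.violations()
    if problems:
        raise ValueError("invalid detector config: " + "; ".join(problems))

    calls: list[DiscrepancyCall] = []
    for tl in timelines:
        prev_observed: Optional[float] = None
        prev_discrepant = False
        for mar in tl.mars:
            expected = effective_dose_at(tl, mar.mar_time)
            reason: Optional[str] = None
            if expected is None:
                reason = "no-active-order"
            elif _norm_unit(expected.unit) != _norm_unit(mar.unit):
                reason = "unit-mismatch"
            elif not match_dose(expected, mar.observed_dose, config):
                reason = "dose-mismatch"

            if reason is not None and _cleared_by_grace(tl, mar, config):
                reason = None

            if reason is None:
                prev_discrepant = False
            else:
                suppressed = (
                    prev_discrepant
                    and prev_observed is not None
                    and config.values_equal(mar.observed_dose, prev_observed)
                )
                calls.append(
                    DiscrepancyCall(
                        mar=mar,
                        expected=expected,
                        observed=mar.observed_dose,
                        reason=reason,
                        suppressed=suppressed,
                    )
                )
                prev_discrepant = True
            prev_observed = mar.observed_dose
    return calls


def discrepancy_rate(calls: Sequence[DiscrepancyCall], mars_analyzed: int) -> Optional[float]:
    """Unsuppressed calls as a percentage of analyzed (filtered) MARs.

    Returns None (reported as N/A, never 0) when the stratum has no MARs.
    """
    if mars_analyzed == 0:
        return None
    unsuppressed = sum(1 for c in calls if not c.suppressed)
    return 100.0 * unsuppressed / mars_analyzed
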