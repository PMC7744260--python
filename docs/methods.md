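# Methods

## Problem and model

Continuous-infusion medications (insulin, vasopressors, opioids, fluids)
are prescribed as a rate, adjusted through structured order modifications
("audits"), occasionally adjusted verbally at the bedside, and documented
on the medication administration record (MAR) each time a nurse starts,
verifies or changes the pump. A *discrepancy* is a mismatch between the
dose/rate prescribed at a moment and the dose/rate documented as
administered at that moment. Discrepancies are a screening signal: most
are documentation or workflow artifacts, and only chart review can promote
one to a medication administration error. The package therefore optimizes
for auditability — every suppressed call, cleared candidate, rejected row
and recovered order value is surfaced, not discarded.

The prescribed-dose model is a step function per (patient, medication):
states begin at order time (clinical intent), at audit entry time, and at
the effective time of a parsed free-text directive. At equal instants the
precedence is audit > order > directive, and an MAR coinciding exactly
with a state change is judged against the new state, matching how a
modification entered at the same instant supersedes the order it modifies.
Discontinued orders end their final state; MARs beyond it with no other
active prescription are called `no-active-order`.

## Detection parameters

| parameter | default | meaning |
|---|---|---|
| `grace_window_minutes` | 30 | one-sided allowance after an MAR during which a matching late EHR entry clears a candidate (verbal-order lag); institutions with laxer verbal-order policy may need 45–60 |
| `range_mode` | `range-aware` | accept any observed value inside a dose-range order; `legacy-lower-bound` reproduces the single-dose behavior that compares only the range's first value |
| `dose_tolerance` | 1e-6 | relative tolerance of dose equality, guarding float ingestion noise; clinical equality is intended to be exact |
| `comparison_decimals` | 4 | rounding applied before comparison |
| `mar_action_filter` | new bag, start, restart, rate verify, rate change | MAR actions in which administration errors can manifest |

The discrepancy-rate denominator is the post-filter MAR count of the
stratum; suppressed calls are excluded from the numerator. Strata with no
analyzed MARs report N/A, never 0. `no-active-order` MARs count as
unsuppressed calls once the grace window expires; this decision is echoed
in every call-list header because reasonable sites could instead exclude
them from rates.

## Original-order-value recovery

Some EHR warehouse ETL pipelines overwrite an order's stored value with
each audit's new value, so the retrospective extract shows the *last*
audit value as the "original" order. The signature is detectable per
order: stored dose = last audit's new value ≠ first audit's old value.
Recovery replaces the stored dose with the first audit's old value, which
by construction of the audit chain is the true original. The procedure is
idempotent, reports every rewrite, and degrades gracefully: extracts that
do not retain audit old values leave their orders unchanged and flagged
unrecoverable. Orders whose audit chain returns to the original value
(e.g. 5→4 then 4→5) need no rewrite and get none.

## Free-text directive grammar

The directive parser is a deliberately small regular grammar —
`<verb> [medication] [to|at|by] <number>[-<number>] [unit]` — with verb
polarity deciding relative directions and a YAML lexicon (verbs,
medication abbreviations, unit spellings) that sites extend without code
changes. It is a site-customizable starting point, not clinical NLP:
negation, temporality and misspellings are out of scope, a "by" after a
polarity-neutral verb is refused as ambiguous, and a textual range becomes
a set-to range only in range-aware mode. Unmatched or unresolvable text is
reported as a skip, never guessed at.

## Synthetic data: what it emulates and what it does not

The generator emulates the event *structures* the detector consumes:
per-stratum order volumes (exact), Poisson audit counts per order,
exponential MAR inter-arrival times (hourly rate-verify cadence by
default), dose-range orders with periodic in-range titration, verbal-order
lag (the audit's entry time trails the bedside change that the MAR
documents; clinical intent times stay truthful), the ETL overwrite
corruption, and injected true discrepancies whose values are drawn off the
medication's plausible dose grid and beyond any range bound so they are
unambiguously wrong and recallable against ground truth. Dose values come
from per-medication grids (0.5-step Units/hr insulin, 1-step mcg/kg/min
dopamine, …) so tolerance logic is exercised without float pathologies.

It does **not** emulate patient weights, labs, titration protocols keyed
to physiology, cross-medication interactions, duplicate overlapping
orders, or dirty extract formatting. Passing tests therefore demonstrate
the correctness of the reconciliation and detection logic under the stated
event structures, not performance on any institution's real data, where
rates depend on local prescribing and documentation practice.

Default generator conditions used across the test suite: 48-hour dosing
episodes, 60-minute mean MAR intervals, 45-minute mean verbal lag
(exponential, clipped to 5–240 min), one modification per order. The large
behavioral checks use 100 seeded sites of ~800 MARs for the grace-window
sweep, 500 random adversarial streams of ≤50 events for oracle
equivalence, ~10,500-MAR single-stream sites for injected-rate recovery,
and 1,000 orders for the corruption round trip — sizes chosen so each
property is measured with comfortable statistical margin while the whole
suite runs in seconds.

## Numerical and design choices

- Dose equality is `|a−b| ≤ τ·max(1,|b|)` after rounding both sides to 4
  decimals; range bounds are tolerance-inclusive.
- Timestamps are timezone-aware instants throughout; grace-window
  arithmetic is done on instants and survives DST.
- The grace window keys on the *entry* time of the late order/audit, not
  its clinical time — the lag being excused is a documentation lag. The
  window is one-sided: entries before the MAR never clear it.
- Suppression compares the observed value against the immediately
  preceding analyzed MAR and requires that MAR to have been called;
  a matching or cleared MAR in between resets the chain.
- Unit mismatches are a distinct reason code and never coerced.
- Unsuppressed-call monotonicity in the grace window holds for streams
  whose clearing entries post-date the run of equal-valued discrepant MARs
  they clear (the verbal-lag structure the generator produces, where the
  cleared MARs are always a suffix of the run). It is not a theorem for
  arbitrary adversarial streams: clearing an *interior* member of an
  equal-value discrepant run can split one suppression chain into two.
  The property suite tests it on generator streams, where it holds.
- The detector's incremental implementation is checked call-for-call
  against an independent full-rescan reference detector on random
  adversarial streams (ties, ranges, wrong units, MARs outside order
  windows, discontinuations).

## Known limitations

- The discrepancy-rate denominator and the treatment of `no-active-order`
  calls are package definitions, stated in output headers; other
  reasonable conventions exist.
- Overlapping duplicate orders for the same (patient, medication) are
  warned about and resolved first-by-entry-time rather than reconciled.
- The directive grammar ignores directives it cannot anchor to a known
  medication even when context could disambiguate across sentences.
- Site mappings translate column names and categorical values; structural
  transformations (one row per dose component, wide formats) must be
  handled upstream.
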