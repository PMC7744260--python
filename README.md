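# marrec — medication administration record reconciliation

`marrec` detects dosing discrepancies in continuous-infusion medication use
by chronologically matching what was prescribed (orders, structured order
modifications, free-text dose directives) against what was documented as
administered (MAR entries). It is aimed at medication-safety and clinical
informatics teams who want an automated, auditable first pass over EHR
extracts: discrepancies are starting points for review, not confirmed
administration errors.

## What it computes

For each patient and medication, the prescribed dose in force at time *t*
is the latest of the order dose, audit (modification) values and parsed
free-text directives with effective time ≤ *t*. An analyzed MAR entry
(actions *new bag, start, restart, rate verify, rate change*) with observed
value *v* at time *t* is discrepant when *v* fails to match the expected
dose spec:

- a discrete expectation *d* matches iff |*v* − *d*| ≤ τ·max(1, |*d*|)
  after rounding (τ = 10⁻⁶ by default);
- a range order [*lo*, *hi*] matches any *lo* ≤ *v* ≤ *hi* in `range-aware`
  mode; `legacy-lower-bound` mode compares against *lo* only, reproducing
  the single-dose behavior that flags in-range titrations.

Two mechanisms prevent over-calling:

- **grace window** — a candidate is cleared if a matching order/audit is
  *entered* into the EHR within *w* minutes after the MAR (default
  *w* = 30), absorbing verbal-order documentation lag;
- **suppression** — consecutive MARs repeating the same discrepant value
  produce one call; repeats are emitted flagged `suppressed` and excluded
  from rates.

The per-stratum **discrepancy rate** is
100 × unsuppressed calls / analyzed MARs. Two fit statistics characterize
a site's workflows: the **audit/order ratio** (modifications per order) and
the **MAR/(order + audit) ratio** (documentations per order or
modification).

Retrospective extracts from some EHR warehouses overwrite an order's
original value with each modification, so the stored order carries its
*last* audit's value. `recover_original_orders` reverses this: when the
stored dose equals the last audit's new value but differs from the first
audit's old value, the first audit's old value is restored as the original
prescription.

## Worked example

No patient data ships with the package; the `synthgen` module generates
seeded synthetic sites with known ground truth. The profile below builds a
NICU-like site whose extract suffers the order-value overwrite artifact:

```yaml
# profile.yaml
site_label: demo-nicu
seed: 42
overwrite_corruption: true
streams:
  - department: NICU
    medication: insulin
    n_orders: 12
    audits_per_order: 1.5
    range_order_fraction: 0.4
    discrepancy_probability: 0.02
    verbal_order_fraction: 0.1
  - department: NICU
    medication: dopamine
    n_orders: 10
    audits_per_order: 3.0
    discrepancy_probability: 0.01
```

```sh
marrec generate profile.yaml site
# wrote 1106 events to site
marrec detect site out-norec --no-recover --site-label demo-nicu
# 419 call(s), 40 unsuppressed
marrec detect site out-rec --recover --site-label demo-nicu
# recovery: 19 order value(s) restored, 0 unrecoverable
# 13 call(s), 13 unsuppressed
marrec compare out-norec/stats.json out-rec/stats.json cmp
```

`out-rec/stats.tsv` after recovery:

```
department  medication  n_orders  n_audits  n_mars  n_discrepancies  audit_order_ratio  mar_per_order_audit_ratio  discrepancy_rate
NICU        dopamine    10        26        496     3                2.6                13.8                       0.6
NICU        insulin     12        14        548     10               1.2                21.1                       1.8
```

and `cmp/comparison.tsv` shows the before/after effect of the recovery
patch — every rate falls because recovery removes only false positives:

```
department  medication  rate_before  rate_after  absolute_change
NICU        dopamine    2.8          0.6         -2.2
NICU        insulin     4.7          1.8         -2.9
```

Without recovery, every order whose stored value was overwritten makes its
earliest MARs look wrong (40 unsuppressed calls). After recovery the 13
remaining calls are the injected true discrepancies plus verbal-order lags
exceeding the 30-minute window. `marrec fixtures out/` writes three small
worked fixtures (dose-range misinterpretation, order-value overwrite,
76-minute verbal-order lag) as CSV extracts for experimentation, and
`marrec detect --mapping site.yaml` applies a site-mapping config (column
names and value-translation tables) to non-canonical extracts.

The same pipeline is available as a library:

```python
from marrec import (DetectorConfig, build_timeline, detect,
                    recover_original_orders, summarize)
```

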