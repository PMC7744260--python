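"""Descriptive fit statistics and cross-site comparison.

Beyond discrepancy rates, two ratios summarize how a clinical unit
prescribes and documents, and therefore how well the detection logic fits
its workflow:

* **audit/order ratio** — average number of times an order is modified
  during its life cycle (prescribing pattern: modify existing orders vs
  place new ones);
* **MAR/(order + audit) ratio** — average number of MAR documentations per
  order or modification (documentation pattern, e.g. hourly rate-verify
  charting inflates it).

Ratios are reported to one decimal in human tables and at full precision
in machine output; a ratio whose denominator is zero is N/A, never 0.
Department aggregation pools raw counts before computing ratios, not means
of ratios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .datamodel import DetectorConfig, DiscrepancyCall
from .detector import discrepancy_rate
from .io_mapping import EventBundle

__all__ = [
    "StratumStats",
    "SiteStats",
    "summarize",
    "pool_departments",
    "compare_sites",
    "ComparisonTable",
    "plot_rate_vs_volume",
]


@dataclass
class StratumStats:
    """Counts and derived statistics for one (department, medication)."""

    n_orders: int = 0
    n_audits: int = 0
    n_mars: int = 0  # post-action-filter
    n_discrepancies: int = 0  # unsuppressed calls only

    @property
    def audit_order_ratio(self) -> Optional[float]:
        return self.n_audits / self.n_orders if self.n_orders else None

    @property
    def mar_per_order_audit_ratio(self) -> Optional[float]:
        denom = self.n_orders + self.n_audits
        return self.n_mars / denom if denom else None

    @property
    def discrepancy_rate(self) -> Optional[float]:
        if self.n_mars == 0:
            return None
        return 100.0 * self.n_discrepancies / self.n_mars

    def to_dict(self) -> dict:
        return {
            "n_orders": self.n_orders,
            "n_audits": self.n_audits,
            "n_mars": self.n_mars,
            "n_discrepancies": self.n_discrepancies,
            "audit_order_ratio": self.audit_order_ratio,
            "mar_per_order_audit_ratio": self.mar_per_order_audit_ratio,
            "discrepancy_rate": self.discrepancy_rate,
        }


@dataclass
class SiteStats:
    site_label: str
    strata: dict[tuple[str, str], StratumStats] = field(default_factory=dict)

    def stratum(self, department: str, medication: str) -> StratumStats:
        key = (department, medication)
        st = self.strata.get(key)
        if st is None:
            st = StratumStats()
            self.strata[key] = st
        return st

    def to_dict(self) -> dict:
        return {
            "site_label": self.site_label,
            "strata": [
                {"department": d, "medication": m, **st.to_dict()}
                for (d, m), st in sorted(self.strata.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteStats":
        out = cls(site_label=d["site_label"])
        for row in d["strata"]:
            out.strata[(row["department"], row["medication"])] = StratumStats(
                n_orders=row["n_orders"], n_audits=row["n_audits"],
                n_mars=row["n_mars"], n_discrepancies=row["n_discrepancies"],
            )
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SiteStats":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_tsv(self) -> str:
        header = ("department\tmedication\tn_orders\tn_audits\tn_mars\tn_discrepancies"
                  "\taudit_order_ratio\tmar_per_order_audit_ratio\tdiscrepancy_rate")
        lines = [header]
        for (d, m), st in sorted(self.strata.items()):
            lines.append("\t".join([
                d, m, str(st.n_orders), str(st.n_audits), str(st.n_mars),
                str(st.n_discrepancies),
                _fmt(st.audit_order_ratio), _fmt(st.mar_per_order_audit_ratio),
                _fmt(st.discrepancy_rate),
            ]))
        return "\n".join(lines) + "\n"


def _fmt(x: Optional[float], decimals: int = 1) -> str:
    return "N/A" if x is None else f"{x:.{decimals}f}"


def summarize(
    bundle: EventBundle,
    calls: Sequence[DiscrepancyCall],
    config: Optional[DetectorConfig] = None,
    site_label: str = "site",
) -> SiteStats:
    """Tally per-(department, medication) counts, ratios and rates.

    ``calls`` must come from running the detector on the same events and
    config; a call referencing an MAR absent from the bundle is a
    consistency error.  Audits inherit their stratum from the order they
    modify; audits whose order is unknown are not counted.
    """
    config = config or DetectorConfig()
    stats = SiteStats(site_label=site_label)

    order_stratum: dict[str, tuple[str, str]] = {}
    for o in bundle.orders:
        stats.stratum(o.department, o.medication).n_orders += 1
        order_stratum[o.order_id] = (o.department, o.medication)
    for a in bundle.audits:
        key = order_stratum.get(a.order_id)
        if key is not None:
            stats.stratum(*key).n_audits += 1
    known_mars = set()
    for m in bundle.mars:
        if m.action in config.mar_action_filter:
            stats.stratum(m.department, m.medication).n_mars += 1
            known_mars.add(m.mar_id)
    for c in calls:
        if c.mar.mar_id not in known_mars:
            raise ValueError(
                f"call references MAR {c.mar.mar_id!r} absent from the analyzed events")
        if not c.suppressed:
            stats.stratum(c.mar.department, c.mar.medication).n_discrepancies += 1
    return stats


def pool_departments(stats: SiteStats, label: Optional[str] = None,
                     department_label: str = "all ICUs") -> SiteStats:
    """Pool counts across departments per medication, then derive ratios."""
    out = SiteStats(site_label=label or stats.site_label)
    for (_, med), st in stats.strata.items():
        agg = out.stratum(department_label, med)
        agg.n_orders += st.n_orders
        agg.n_audits += st.n_audits
        agg.n_mars += st.n_mars
        agg.n_discrepancies += st.n_discrepancies
    return out


@dataclass
class ComparisonTable:
    site_a: str
    site_b: str
    rows: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = [f"department\tmedication\trate_{self.site_a}\trate_{self.site_b}\tabsolute_change"]
        for r in self.rows:
            lines.append("\t".join([
                r["department"], r["medication"],
                _fmt(r["rate_a"]), _fmt(r["rate_b"]), _fmt(r["change"]),
            ]))
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        head = (f"| department | medication | {self.site_a} (%) | {self.site_b} (%) | change |\n"
                "|---|---|---|---|---|\n")
        body = "".join(
            f"| {r['department']} | {r['medication']} | {_fmt(r['rate_a'])} "
            f"| {_fmt(r['rate_b'])} | {_fmt(r['change'])} |\n"
            for r in self.rows
        )
        return head + body


def compare_sites(a: SiteStats, b: SiteStats) -> ComparisonTable:
    """Per-stratum discrepancy-rate comparison (b minus a).

    N/A on either side propagates to the change column; strata present in
    only one input are listed with the other side N/A.  Disjoint strata
    yield an empty table with a warning rather than an error.
    """
    table = ComparisonTable(site_a=a.site_label, site_b=b.site_label)
    keys = sorted(set(a.strata) | set(b.strata))
    overlap = set(a.strata) & set(b.strata)
    if not overlap:
        table.warnings.append("no overlapping (department, medication) strata")
    for key in keys:
        ra = a.strata[key].discrepancy_rate if key in a.strata else None
        rb = b.strata[key].discrepancy_rate if key in b.strata else None
        change = None if ra is None or rb is None else rb - ra
        table.rows.append({
            "department": key[0], "medication": key[1],
            "rate_a": ra, "rate_b": rb, "change": change,
        })
    return table


def plot_rate_vs_volume(stats_list: Sequence[SiteStats], path: Optional[str | Path] = None):
    """Scatter discrepancy rate by medication per site, marker area
    proportional to the stratum's order count.  Returns the Figure."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(stats_list)
    fig, axes = plt.subplots(1, n, figsize=(4.5 * n, 4), squeeze=False, sharey=True)
    for ax, stats in zip(axes[0], stats_list):
        meds = sorted({m for (_, m) in stats.strata})
        xs, ys, areas = [], [], []
        for i, med in enumerate(meds):
            for (dept, m), st in sorted(stats.strata.items()):
                if m != med or st.discrepancy_rate is None:
                    continue
                xs.append(i)
                ys.append(st.discrepancy_rate)
                areas.append(float(st.n_orders))
        ax.scatter(xs, ys, s=areas, alpha=0.6)
        ax.set_xticks(range(len(meds)))
        ax.set_xticklabels(meds, rotation=60, ha="right", fontsize=7)
        ax.set_title(stats.site_label)
        ax.set_ylabel("discrepancy rate (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
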