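"""Regex extraction of discrete dose/rate directives from free text.

Physician-to-nurse communication orders carry dose adjustments in prose
("increase dopamine to 7.5 mcg/kg/min", "wean fentanyl by 0.5").  This
module turns them into structured :class:`~marrec.datamodel.DoseDirective`
records via a small, documented grammar:

    <verb> [<medication>] [to|at|by] <number>[-<number>] [<unit>]

* preposition "to"/"at" => an absolute ``set-to`` directive;
* "by" => a relative directive whose kind follows the verb's polarity
  (increase/titrate => ``increase-by``; decrease/wean/reduce =>
  ``decrease-by``); a "by" after a polarity-neutral verb is skipped as
  ambiguous;
* a bare range ("titrate 2-4") becomes a ``set-to`` with a dose range when
  ``range_mode`` is ``"range-aware"``, mirroring the detector's range
  handling, and is otherwise skipped with a warning.

The verb lexicon, medication abbreviations and unit spellings live in a
YAML grammar file so sites can extend them without code changes.  Parsing
is deterministic and order-stable; text with no parseable directive yields
an empty list, never an error.  This grammar is a site-customizable
starting point, not a general clinical NLP system: negation, temporality
and misspellings are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .datamodel import (
    CommOrderText,
    DoseDirective,
    DoseSpec,
    MedicationRegistry,
    default_registry,
)

__all__ = [
    "Grammar",
    "load_grammar",
    "default_grammar",
    "parse_comm_order",
    "directive_to_audit",
    "UnresolvedDirectiveError",
]


class UnresolvedDirectiveError(ValueError):
    """A relative directive cannot be applied (current dose unknown or a range)."""


@dataclass
class Grammar:
    increase_verbs: list[str]
    decrease_verbs: list[str]
    neutral_verbs: list[str]
    set_preps: list[str]
    relative_prep: str
    abbreviations: dict[str, str]
    unit_aliases: dict[str, str]
    _pattern: Optional[re.Pattern] = field(default=None, repr=False)

    @property
    def verbs(self) -> list[str]:
        return self.increase_verbs + self.decrease_verbs + self.neutral_verbs

    def medication_aliases(self, registry: MedicationRegistry) -> dict[str, str]:
        """All recognizable medication spellings -> canonical names."""
        out = {name.lower(): name for name in registry.names()}
        for abbr, name in self.abbreviations.items():
            if name in registry:
                out[abbr.lower()] = name
        return out

    def pattern(self, registry: MedicationRegistry) -> re.Pattern:
        if self._pattern is None:
            med_alt = "|".join(
                re.escape(m) for m in sorted(self.medication_aliases(registry), key=len, reverse=True)
            )
            verb_alt = "|".join(re.escape(v) for v in sorted(self.verbs, key=len, reverse=True))
            prep_alt = "|".join([re.escape(p) for p in self.set_preps] + [re.escape(self.relative_prep)])
            unit_alt = "|".join(
                re.escape(u) for u in sorted(self.unit_aliases, key=len, reverse=True)
            )
            self._pattern = re.compile(
                rf"\b(?P<verb>{verb_alt})\s+"
                rf"(?:the\s+)?"
                rf"(?:(?P<med>{med_alt})\s+)?"
                rf"(?:drip\s+|infusion\s+|rate\s+)?"
                rf"(?:(?P<prep>{prep_alt})\s+)?"
                rf"(?P<num>\d*\.?\d+)"
                rf"(?:\s*-\s*(?P<num2>\d*\.?\d+))?"
                rf"(?:\s*(?P<unit>{unit_alt}))?",
                re.IGNORECASE,
            )
        return self._pattern

    def loose_pattern(self) -> re.Pattern:
        """Verb..number shapes with an unrecognized medication token, used
        only to report unresolved directives (never to extract one)."""
        verb_alt = "|".join(re.escape(v) for v in sorted(self.verbs, key=len, reverse=True))
        return re.compile(
            rf"\b(?:{verb_alt})\s+(?:[A-Za-z][\w%]*\s+){{1,3}}?"
            rf"(?:to|at|by)\s+\d*\.?\d+",
            re.IGNORECASE,
        )


def load_grammar(path: str | Path) -> Grammar:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return Grammar(
        increase_verbs=[v.lower() for v in raw["increase_verbs"]],
        decrease_verbs=[v.lower() for v in raw["decrease_verbs"]],
        neutral_verbs=[v.lower() for v in raw["neutral_verbs"]],
        set_preps=[p.lower() for p in raw["set_preps"]],
        relative_prep=str(raw["relative_prep"]).lower(),
        abbreviations={str(k).lower(): str(v) for k, v in (raw.get("abbreviations") or {}).items()},
        unit_aliases={str(k).lower(): str(v) for k, v in (raw.get("unit_aliases") or {}).items()},
    )


_DEFAULT: Optional[Grammar] = None


def default_grammar() -> Grammar:
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(resources.files("marrec.data") / "grammar.yaml") as p:
            _DEFAULT = load_grammar(p)
    return _DEFAULT


def _find_context_medication(text: str, aliases: dict[str, str]) -> Optional[str]:
    """First medication mention anywhere in the text (longest-alias first)."""
    low = text.lower()
    best: tuple[int, str] | None = None
    for alias, name in aliases.items():
        m = re.search(rf"\b{re.escape(alias)}\b", low)
        if m and (best is None or m.start() < best[0]):
            best = (m.start(), name)
    return best[1] if best else None


def parse_comm_order(
    comm: CommOrderText,
    registry: Optional[MedicationRegistry] = None,
    grammar: Optional[Grammar] = None,
    range_mode: str = "range-aware",
    skips: Optional[list] = None,
) -> list[DoseDirective]:
    """Extract zero or more dose directives from one communication order.

    Directives are returned in text order, each citing its source span.
    A match that cannot be resolved (no medication in text or context, an
    ambiguous relative verb, a range under legacy mode) is appended to
    ``skips`` (if given) as ``{"text", "span", "reason"}`` and produces no
    directive.  Nothing here raises on unparseable content.
    """
    registry = registry if registry is not None else default_registry()
    grammar = grammar if grammar is not None else default_grammar()
    if skips is None:
        skips = []
    aliases = grammar.medication_aliases(registry)
    directives: list[DoseDirective] = []
    if not comm.text or not comm.text.strip():
        return directives
    for m in grammar.pattern(registry).finditer(comm.text):
        span = m.span()

        def skip(reason: str) -> None:
            skips.append({"text": comm.text, "span": list(span), "reason": reason})

        med_token = m.group("med")
        med = (
            aliases.get(med_token.lower())
            if med_token
            else (_find_context_medication(comm.text, aliases) or comm.medication)
        )
        if med is None or med not in registry:
            skip("unresolved medication")
            continue
        medication = registry.get(med)
        verb = m.group("verb").lower()
        prep = (m.group("prep") or "").lower()
        amount = float(m.group("num"))
        amount_high = float(m.group("num2")) if m.group("num2") else None
        unit_token = (m.group("unit") or "").lower()
        unit = grammar.unit_aliases.get(unit_token, medication.canonical_unit)

        if amount_high is not None:
            # a textual range is only meaningful as an absolute target
            if range_mode != "range-aware":
                skip("range directive under legacy mode")
                continue
            if amount_high < amount:
                skip("descending range")
                continue
            kind = "set-to"
        elif prep in grammar.set_preps:
            kind = "set-to"
        elif prep == grammar.relative_prep:
            if verb in grammar.increase_verbs:
                kind = "increase-by"
            elif verb in grammar.decrease_verbs:
                kind = "decrease-by"
            else:
                skip(f"ambiguous relative verb {verb!r}")
                continue
        else:
            skip("no preposition and no range")
            continue

        directives.append(
            DoseDirective(
                patient_id=comm.patient_id,
                medication=med,
                kind=kind,
                amount=amount,
                unit=unit,
                effective_time=comm.comm_time,
                provenance=comm.comm_id or comm.text[span[0]:span[1]],
                amount_high=amount_high,
                source_span=span,
            )
        )
    if not directives:
        # verb..number shapes the strict grammar could not anchor to a
        # known medication are surfaced as unresolved, not dropped silently
        matched = {tuple(s["span"]) for s in skips}
        for m in grammar.loose_pattern().finditer(comm.text):
            if m.span() not in matched:
                skips.append({"text": comm.text, "span": list(m.span()),
                              "reason": "unresolved medication"})
    return directives


def directive_to_audit(directive: DoseDirective, current: Optional[DoseSpec]) -> DoseSpec:
    """Resolve a directive against the current dose, yielding the new dose.

    ``set-to`` ignores ``current``; relative kinds require a known discrete
    current dose.  A decrease below zero clamps to 0 (the pump cannot run
    backwards) — callers see the clamp in the returned value.
    """
    if directive.kind == "set-to":
        return DoseSpec(directive.amount, directive.amount_high, directive.unit)
    if current is None:
        raise UnresolvedDirectiveError(
            f"relative directive {directive.kind} needs a known current dose")
    if current.is_range:
        raise UnresolvedDirectiveError(
            f"relative directive {directive.kind} cannot apply to a range order")
    if directive.kind == "increase-by":
        return DoseSpec(current.low + directive.amount, None, directive.unit)
    if directive.kind == "decrease-by":
        return DoseSpec(max(0.0, current.low - directive.amount), None, directive.unit)
    raise UnresolvedDirectiveError(f"unknown directive kind {directive.kind!r}")
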