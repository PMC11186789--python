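"""Flagging: component-wise semantic comparison of two directions.

Used at data entry to warn, in real time, when the direction a technician
is typing diverges clinically from the prescriber's direction.  Both
directions pass through the same normalization and extraction stages,
extracted surfaces are mapped to canonical values (library synonym maps
plus number-word unification), and the canonical values are compared
label by label.  The verdict is Boolean — equivalent or not — with
per-component discrepancy records.

Two modes model the typing workflow:

* ``final``: both directions are complete; a label present on one side
  only is a discrepancy (missing-in-a / missing-in-b).
* ``partial``: the second direction is still being typed; labels it has
  not reached yet are *pending*, not errors, but a label it has already
  typed that contradicts the prescriber is flagged immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Catalog, CatalogEntry, NOT_FOUND
from .factory import ComponentLibrary
from .normalizer import RuleSet, normalize
from .schema import ComponentLabel, ExtractionResult

__all__ = [
    "Discrepancy",
    "FlagReport",
    "CanonicalComponents",
    "ERROR_CATEGORIES",
    "canonicalize",
    "compare",
    "categorize_errors",
    "evaluate_flagger",
]

# The six error categories clinically distinguished at review: the dose
# label splits into quantity vs form, the five auxi-* labels aggregate.
ERROR_CATEGORIES = (
    "verb", "dose-quantity", "dose-form", "route", "frequency", "auxiliary",
)

_NUMBER_WORDS = {
    "1": "one", "2": "two", "3": "three", "4": "four", "5": "five",
    "6": "six", "7": "seven", "8": "eight", "9": "nine", "10": "ten",
    "11": "eleven", "12": "twelve",
    "1/2": "half", "0.5": "half",
}
_NUMERIC_WORDS = frozenset(_NUMBER_WORDS.values()) | {
    "half", "once", "twice",
}


@dataclass(frozen=True)
class Discrepancy:
    label: ComponentLabel
    value_a: str | None
    value_b: str | None
    kind: str  # "mismatch" | "missing-in-a" | "missing-in-b"


@dataclass
class FlagReport:
    equivalent: bool
    discrepancies: list[Discrepancy] = field(default_factory=list)
    pending: list[ComponentLabel] = field(default_factory=list)
    mode: str = "final"

    def to_dict(self) -> dict:
        return {
            "equivalent": self.equivalent,
            "mode": self.mode,
            "discrepancies": [
                {
                    "label": d.label.value,
                    "value_a": d.value_a,
                    "value_b": d.value_b,
                    "kind": d.kind,
                }
                for d in self.discrepancies
            ],
            "pending": [label.value for label in self.pending],
        }


@dataclass
class CanonicalComponents:
    """label -> canonical value; multi-value labels are kept for reporting
    and always compare as a mismatch."""

    values: dict[ComponentLabel, tuple[str, ...]] = field(default_factory=dict)

    def get(self, label: ComponentLabel) -> tuple[str, ...]:
        return self.values.get(label, ())


def _canonical_token(token: str) -> str:
    return _NUMBER_WORDS.get(token, token)


def canonicalize(
    extraction: ExtractionResult,
    libraries: dict[ComponentLabel, ComponentLibrary] | None = None,
    entry: CatalogEntry | None = None,
) -> CanonicalComponents:
    """Map each extracted surface to its canonical comparison form.

    Surfaces pass through the label's canonical map (identity fallback),
    then number words are unified token-wise ("1 tab" and "one tab"
    compare equal).  Deterministic and total.
    """
    out: dict[ComponentLabel, tuple[str, ...]] = {}
    for label, vals in extraction.values.items():
        canon_vals = []
        for val in vals:
            value = val.surface.strip().lower()
            if libraries and label in libraries:
                value = libraries[label].canonical_value(value)
            value = " ".join(_canonical_token(t) for t in value.split())
            canon_vals.append(value)
        if canon_vals:
            out[label] = tuple(canon_vals)
    return CanonicalComponents(values=out)


def _extract_canonical(
    text: str,
    drug_id: str | None,
    rules: RuleSet,
    tagger,
    libraries: dict[ComponentLabel, ComponentLibrary] | None,
    catalog: Catalog | None,
) -> CanonicalComponents:
    normalized = normalize(text, rules)
    extraction = tagger.tag(normalized.normalized)
    entry = None
    if catalog is not None and drug_id:
        found = catalog.lookup(drug_id)
        entry = None if found is NOT_FOUND else found
    return canonicalize(extraction, libraries, entry)


def compare(
    direction_a: str,
    direction_b: str,
    drug_id: str | None,
    rules: RuleSet,
    tagger,
    libraries: dict[ComponentLabel, ComponentLibrary] | None = None,
    catalog: Catalog | None = None,
    mode: str = "final",
) -> FlagReport:
    """Compare two directions component-wise.

    ``direction_a`` is the reference (prescriber) direction and
    ``direction_b`` the candidate (typed) one.  In final mode the verdict
    is symmetric up to swapping discrepancy sides.
    """
    if mode not in ("final", "partial"):
        raise ValueError(f"unknown mode {mode!r}")
    comp_a = _extract_canonical(direction_a, drug_id, rules, tagger,
                                libraries, catalog)
    comp_b = _extract_canonical(direction_b, drug_id, rules, tagger,
                                libraries, catalog)
    discrepancies: list[Discrepancy] = []
    pending: list[ComponentLabel] = []
    for label in ComponentLabel:
        a_vals, b_vals = comp_a.get(label), comp_b.get(label)
        if not a_vals and not b_vals:
            continue
        if a_vals and not b_vals:
            if mode == "partial":
                pending.append(label)
            else:
                discrepancies.append(
                    Discrepancy(label, a_vals[0], None, "missing-in-b")
                )
            continue
        if b_vals and not a_vals:
            discrepancies.append(
                Discrepancy(label, None, b_vals[0], "missing-in-a")
            )
            continue
        if len(a_vals) > 1 or len(b_vals) > 1 or a_vals[0] != b_vals[0]:
            discrepancies.append(
                Discrepancy(label, " / ".join(a_vals), " / ".join(b_vals),
                            "mismatch")
            )
    return FlagReport(
        equivalent=not discrepancies,
        discrepancies=discrepancies,
        pending=pending,
        mode=mode,
    )


def _dose_parts(value: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split a dose value into (numeric tokens, unit tokens)."""
    numeric, unit = [], []
    for token in value.split():
        if (
            token in _NUMERIC_WORDS
            or any(ch.isdigit() for ch in token)
        ):
            numeric.append(_canonical_token(token))
        else:
            unit.append(token)
    return tuple(numeric), tuple(unit)


def categorize_errors(report: FlagReport) -> list[str]:
    """Map a report's discrepancies onto the six clinical error categories.

    The dose label splits by comparing numeric and unit parts: differing
    numbers give a quantity error, differing units a form error, both
    give quantity (the more dangerous axis).  The five auxi-* labels
    aggregate into "auxiliary".
    """
    categories: list[str] = []
    for disc in report.discrepancies:
        if disc.label is ComponentLabel.DOSE:
            if disc.value_a is None or disc.value_b is None:
                categories.append("dose-quantity")
                continue
            num_a, unit_a = _dose_parts(disc.value_a)
            num_b, unit_b = _dose_parts(disc.value_b)
            if num_a != num_b:
                categories.append("dose-quantity")
            elif unit_a != unit_b:
                categories.append("dose-form")
            else:
                categories.append("dose-quantity")
        elif disc.label in ComponentLabel.auxiliary():
            categories.append("auxiliary")
        else:
            categories.append(disc.label.value)
    # preserve order, drop duplicates
    seen: set[str] = set()
    unique = []
    for cat in categories:
        if cat not in seen:
            seen.add(cat)
            unique.append(cat)
    return unique


def evaluate_flagger(
    pairs: list[tuple[str, str, str | None, str]],
    rules: RuleSet,
    tagger,
    libraries: dict[ComponentLabel, ComponentLibrary] | None = None,
    catalog: Catalog | None = None,
) -> dict:
    """Detection rates over labeled error pairs.

    Each pair is (direction_a, direction_b, drug_id, gold_category) with
    gold_category in :data:`ERROR_CATEGORIES`.  Returns per-category
    detection rates (fraction of pairs flagged with a discrepancy in the
    gold category) and the overall flagged rate.
    """
    if not pairs:
        raise ValueError("no evaluation pairs given")
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    flagged = 0
    for a, b, drug_id, gold_cat in pairs:
        if gold_cat not in ERROR_CATEGORIES:
            raise ValueError(f"unknown error category {gold_cat!r}")
        report = compare(a, b, drug_id, rules, tagger, libraries, catalog)
        cats = categorize_errors(report)
        totals[gold_cat] = totals.get(gold_cat, 0) + 1
        if not report.equivalent:
            flagged += 1
        if gold_cat in cats:
            hits[gold_cat] = hits.get(gold_cat, 0) + 1
    return {
        "per_category": {
            cat: hits.get(cat, 0) / totals[cat] for cat in totals
        },
        "overall_detection_rate": (
            sum(hits.values()) / len(pairs)
        ),
        "flagged_rate": flagged / len(pairs),
        "n": len(pairs),
    }
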