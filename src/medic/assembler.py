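"""Semantic assembly and safety enforcement.

The final suggestion stage: fill components the prescriber omitted from
the medication catalog, assemble the standardized direction in canonical
component order, and — before anything is suggested — evaluate five
ordered patient-safety guardrails.  Any triggered guardrail halts the
suggestion entirely; a halt is an outcome, not an error.

Guardrails, in evaluation order:

GR1  an extracted value contradicts the catalog value for that component
     (compared on canonical forms, so "1 tablet" vs "one tablet" is not
     a conflict);
GR2  the extractor found multiple values for some component — the
     signature of a multi-line direction this stage must not assemble;
GR3  a dose is present but no verb, for a drug whose catalog entry
     requires a verb;
GR4  no frequency, even after catalog fill-in;
GR5  no dose while the dose form is tablet or capsule.

GR1 and GR2 look at the raw (pre-fill) extraction — they judge the
extractor's output; GR3–GR5 look at the post-fill view, since a catalog
default legitimately satisfies a requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .catalog import Catalog, CatalogEntry, NOT_FOUND
from .factory import ComponentLibrary
from .normalizer import RuleSet, normalize
from .schema import (
    ComponentLabel,
    ExtractedValue,
    ExtractionResult,
    RawDirection,
)

__all__ = [
    "GuardrailID",
    "GuardrailReport",
    "SuggestionOutcome",
    "fill_missing",
    "apply_guardrails",
    "assemble",
    "suggest",
]


class GuardrailID(str, Enum):
    GR1 = "GR1"  # catalog conflict
    GR2 = "GR2"  # multiple values per component
    GR3 = "GR3"  # dose without required verb
    GR4 = "GR4"  # missing frequency
    GR5 = "GR5"  # no dose for tablet/capsule form


@dataclass(frozen=True)
class GuardrailReport:
    triggered: GuardrailID | None
    reason: str = ""
    all_triggered: tuple[tuple[GuardrailID, str], ...] = ()

    @property
    def halted(self) -> bool:
        return self.triggered is not None


@dataclass
class SuggestionOutcome:
    """Either an assembled direction or a typed guardrail halt."""

    record_id: str
    status: str  # "suggested" | "halted"
    direction: str | None = None
    guardrail: GuardrailReport | None = None
    components: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    normalized: str = ""

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "status": self.status,
            "direction": self.direction,
            "guardrail": (
                {
                    "id": self.guardrail.triggered.value,
                    "reason": self.guardrail.reason,
                }
                if self.guardrail is not None and self.guardrail.halted
                else None
            ),
            "components": self.components,
            "notes": self.notes,
        }


def fill_missing(
    extraction: ExtractionResult, entry: CatalogEntry
) -> ExtractionResult:
    """Add catalog defaults for required components with no extracted value.

    Extracted values are never overwritten; filled values carry
    ``catalog-filled`` provenance and no span.  A required component with
    no catalog default stays missing — the guardrails decide its fate.
    """
    values = {label: list(vals) for label, vals in extraction.values.items()}
    for label in entry.required:
        if values.get(label):
            continue
        default = entry.defaults.get(label)
        if default is not None:
            values[label] = [
                ExtractedValue(surface=default, span=None,
                               provenance="catalog-filled")
            ]
    return ExtractionResult(values=values, backend=extraction.backend)


def _canonical(
    label: ComponentLabel, surface: str,
    libraries: dict[ComponentLabel, ComponentLibrary] | None,
) -> str:
    value = surface.strip().lower()
    if libraries and label in libraries:
        value = libraries[label].canonical_value(value)
    return value


def apply_guardrails(
    extraction: ExtractionResult,
    raw_extraction: ExtractionResult,
    entry: CatalogEntry | None,
    libraries: dict[ComponentLabel, ComponentLibrary] | None = None,
) -> GuardrailReport:
    """Evaluate GR1..GR5 in order; the first hit is primary.

    ``extraction`` is the post-fill view, ``raw_extraction`` the pre-fill
    view.  With no catalog entry, the catalog-dependent guardrails
    (GR1, GR3, GR5) are vacuously silent.
    """
    hits: list[tuple[GuardrailID, str]] = []

    if entry is not None:
        for label in ComponentLabel:
            default = entry.defaults.get(label)
            raw_vals = raw_extraction.get(label)
            if default is None or not raw_vals:
                continue
            want = _canonical(label, default, libraries)
            for val in raw_vals:
                got = _canonical(label, val.surface, libraries)
                if got != want:
                    hits.append((
                        GuardrailID.GR1,
                        f"{label.value}: extracted {val.surface!r} conflicts "
                        f"with catalog {default!r}",
                    ))
                    break
            if hits and hits[-1][0] is GuardrailID.GR1:
                break

    for label in ComponentLabel:
        raw_vals = raw_extraction.get(label)
        if len(raw_vals) >= 2:
            hits.append((
                GuardrailID.GR2,
                f"{label.value}: multiple values "
                f"{[v.surface for v in raw_vals]} (multi-line direction?)",
            ))
            break

    if entry is not None:
        if (
            extraction.get(ComponentLabel.DOSE)
            and not extraction.get(ComponentLabel.VERB)
            and ComponentLabel.VERB in entry.required
        ):
            hits.append((
                GuardrailID.GR3,
                "dose present but no verb, and the catalog requires a verb",
            ))

    if not extraction.get(ComponentLabel.FREQUENCY):
        hits.append((GuardrailID.GR4, "no frequency component"))

    if entry is not None:
        if (
            not extraction.get(ComponentLabel.DOSE)
            and entry.dose_form in ("tablet", "capsule")
        ):
            hits.append((
                GuardrailID.GR5,
                f"no dose for {entry.dose_form} dose form",
            ))

    hits.sort(key=lambda h: h[0].value)
    if hits:
        return GuardrailReport(triggered=hits[0][0], reason=hits[0][1],
                               all_triggered=tuple(hits))
    return GuardrailReport(triggered=None, all_triggered=())


def assemble(extraction: ExtractionResult) -> str:
    """Join the present components in canonical order with single spaces.

    Requires at most one value per label (GR2 has already enforced this)
    and at least one component overall.
    """
    parts: list[str] = []
    for label in ComponentLabel:
        vals = extraction.get(label)
        if not vals:
            continue
        if len(vals) > 1:
            raise ValueError(
                f"cannot assemble: {label.value} has {len(vals)} values"
            )
        parts.append(vals[0].surface)
    if not parts:
        raise ValueError("nothing to assemble: no components present")
    return " ".join(parts)


def suggest(
    raw: RawDirection,
    rules: RuleSet,
    tagger,
    catalog: Catalog,
    libraries: dict[ComponentLabel, ComponentLibrary] | None = None,
) -> SuggestionOutcome:
    """Run the full suggestion pipeline on one raw direction.

    normalize -> extract -> fill from catalog -> guardrails -> assemble
    (or halt).  ``tagger`` is anything with a ``tag(text)`` method — the
    dictionary matcher or a trained model.  A drug absent from the
    catalog degrades gracefully: no fill-in, catalog guardrails skipped,
    and the outcome notes "catalog-missing".
    """
    normalized = normalize(raw.text, rules)
    raw_extraction = tagger.tag(normalized.normalized)
    notes: list[str] = []
    entry = catalog.lookup(raw.drug_id) if raw.drug_id else NOT_FOUND
    if entry is NOT_FOUND:
        notes.append("catalog-missing")
        entry_obj = None
        filled = raw_extraction
    else:
        entry_obj = entry
        filled = fill_missing(raw_extraction, entry)
    report = apply_guardrails(filled, raw_extraction, entry_obj, libraries)
    components = [
        {
            "label": label.value,
            "value": val.surface,
            "provenance": val.provenance,
        }
        for label in ComponentLabel
        for val in filled.get(label)
    ]
    if report.halted:
        return SuggestionOutcome(
            record_id=raw.record_id,
            status="halted",
            guardrail=report,
            components=components,
            notes=notes,
            normalized=normalized.normalized,
        )
    return SuggestionOutcome(
        record_id=raw.record_id,
        status="suggested",
        direction=assemble(filled),
        components=components,
        notes=notes,
        normalized=normalized.normalized,
    )
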