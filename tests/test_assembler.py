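"""Catalog fill-in, the five safety guardrails, assembly and suggestion."""

import pytest

from medic.assembler import (
    GuardrailID,
    apply_guardrails,
    assemble,
    fill_missing,
    suggest,
)
from medic.schema import (
    ComponentLabel,
    ExtractedValue,
    ExtractionResult,
    RawDirection,
)


def _extraction(**kwargs):
    values = {}
    for name, surfaces in kwargs.items():
        label = ComponentLabel(name.replace("_", "-"))
        if isinstance(surfaces, str):
            surfaces = [surfaces]
        values[label] = [ExtractedValue(surface=s) for s in surfaces]
    return ExtractionResult(values=values)


class TestFillMissing:
    def test_missing_required_route_filled_from_catalog(self, catalog):
        entry = catalog.lookup("d001")
        filled = fill_missing(
            _extraction(verb="take", dose="one tablet", frequency="once daily"),
            entry,
        )
        (route,) = filled.get(ComponentLabel.ROUTE)
        assert route.surface == "by mouth"
        assert route.provenance == "catalog-filled"
        assert route.span is None

    def test_extracted_value_never_overwritten(self, catalog):
        entry = catalog.lookup("d001")
        filled = fill_missing(_extraction(route="under the tongue"), entry)
        (route,) = filled.get(ComponentLabel.ROUTE)
        assert route.surface == "under the tongue"
        assert route.provenance == "extracted"

    def test_required_without_default_stays_missing(self, catalog):
        entry = catalog.lookup("d001")  # dose required, no dose default
        filled = fill_missing(_extraction(verb="take"), entry)
        assert filled.get(ComponentLabel.DOSE) == []


class TestGuardrails:
    def test_gr1_catalog_conflict_on_verb_for_tablet(self, catalog, libraries):
        raw = _extraction(verb="apply", dose="one tablet",
                          frequency="once daily")
        entry = catalog.lookup("d001")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR1
        assert "apply" in report.reason

    def test_gr1_ignores_canonically_equal_values(self, catalog, libraries):
        # "orally" canonicalizes to "by mouth": not a conflict
        raw = _extraction(verb="take", dose="one tablet", route="orally",
                          frequency="once daily")
        entry = catalog.lookup("d001")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert not report.halted

    def test_gr2_multiple_dose_values(self, catalog, libraries):
        raw = _extraction(verb="take", dose=["one tablet", "two tablets"],
                          route="by mouth", frequency="once daily")
        entry = catalog.lookup("d001")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR2

    def test_gr3_dose_without_required_verb(self, catalog, libraries):
        raw = _extraction(dose="one tablet", route="by mouth",
                          frequency="once daily")
        entry = catalog.lookup("d009")  # verb required, default "take"...
        entry = type(entry)(  # strip the verb default to isolate GR3
            drug_id=entry.drug_id, description=entry.description,
            dose_form=entry.dose_form, strength=entry.strength,
            active_ingredients=entry.active_ingredients,
            required=entry.required,
            defaults={k: v for k, v in entry.defaults.items()
                      if k is not ComponentLabel.VERB},
        )
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR3

    def test_gr3_silent_when_verb_not_required(self, catalog, libraries):
        raw = _extraction(dose="10 units", frequency="once daily")
        entry = catalog.lookup("d005")  # insulin: verb not required
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is not GuardrailID.GR3

    def test_gr4_missing_frequency(self, catalog, libraries):
        raw = _extraction(verb="take", dose="one tablet", route="by mouth")
        entry = catalog.lookup("d009")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR4

    def test_gr5_no_dose_for_capsule_form(self, catalog, libraries):
        raw = _extraction(verb="take", route="by mouth",
                          frequency="once daily")
        entry = catalog.lookup("d002")  # capsule
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR5

    def test_catalog_default_satisfies_post_fill_guardrails(self, catalog,
                                                            libraries):
        # methotrexate: frequency omitted but defaulted to "once weekly"
        raw = _extraction(verb="take", dose="one tablet", route="by mouth")
        entry = catalog.lookup("d008")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert not report.halted

    def test_precedence_lowest_guardrail_wins(self, catalog, libraries):
        # conflict (GR1) + double dose (GR2) + no frequency (GR4)
        raw = _extraction(verb="apply", dose=["one tablet", "two tablets"])
        entry = catalog.lookup("d001")
        report = apply_guardrails(fill_missing(raw, entry), raw, entry,
                                  libraries)
        assert report.triggered is GuardrailID.GR1
        ids = [gr for gr, _reason in report.all_triggered]
        assert ids == sorted(ids, key=lambda g: g.value)
        assert GuardrailID.GR2 in ids and GuardrailID.GR4 in ids

    def test_no_catalog_entry_silences_catalog_guardrails(self, libraries):
        raw = _extraction(dose="one tablet")  # no verb, no frequency
        report = apply_guardrails(raw, raw, None, libraries)
        assert report.triggered is GuardrailID.GR4
        assert all(gr is GuardrailID.GR4 for gr, _ in report.all_triggered)


class TestAssemble:
    def test_scrambled_components_emerge_in_canonical_order(self):
        extraction = _extraction(
            frequency="once daily", verb="take", route="by mouth",
            dose="one tablet", auxi_indic="for pain",
        )
        assert assemble(extraction) == (
            "take one tablet by mouth once daily for pain"
        )

    def test_partial_component_set_keeps_canonical_order(self):
        extraction = _extraction(verb="apply", route="topically",
                                 frequency="twice daily")
        assert assemble(extraction) == "apply topically twice daily"

    def test_empty_extraction_is_an_error(self):
        with pytest.raises(ValueError):
            assemble(ExtractionResult())

    def test_multi_value_label_is_an_error(self):
        with pytest.raises(ValueError, match="dose"):
            assemble(_extraction(dose=["one tablet", "two tablets"]))


class TestSuggest:
    def test_end_to_end_suggestion(self, rules, dictionary_tagger, catalog,
                                   libraries):
        raw = RawDirection("r1", "d001", "TAKE 1 TAB PO QD for pain")
        outcome = suggest(raw, rules, dictionary_tagger, catalog, libraries)
        assert outcome.status == "suggested"
        assert outcome.direction == (
            "take one tablet by mouth once daily for pain"
        )

    def test_missing_frequency_halts_gr4(self, rules, dictionary_tagger,
                                         catalog, libraries):
        raw = RawDirection("r2", "d001", "500 mg before procedure")
        outcome = suggest(raw, rules, dictionary_tagger, catalog, libraries)
        assert outcome.status == "halted"
        assert outcome.guardrail.triggered is GuardrailID.GR4

    def test_multi_line_direction_halts_gr2(self, rules, dictionary_tagger,
                                            catalog, libraries):
        raw = RawDirection(
            "r3", "d001",
            "take one tablet by mouth in the morning and two tablets "
            "at bedtime",
        )
        outcome = suggest(raw, rules, dictionary_tagger, catalog, libraries)
        assert outcome.status == "halted"
        assert outcome.guardrail.triggered is GuardrailID.GR2

    def test_unknown_drug_degrades_gracefully(self, rules, dictionary_tagger,
                                              catalog, libraries):
        raw = RawDirection("r4", "zzz", "take one tablet by mouth once daily")
        outcome = suggest(raw, rules, dictionary_tagger, catalog, libraries)
        assert outcome.status == "suggested"
        assert "catalog-missing" in outcome.notes

    def test_every_outcome_is_suggested_or_halted(self, rules,
                                                  dictionary_tagger, catalog,
                                                  libraries, patterns,
                                                  noise_model):
        from medic.factory import degrade, generate_corpus

        for rec in generate_corpus(patterns, libraries, 120, seed=61):
            raw = degrade(rec, noise_model)
            outcome = suggest(raw, rules, dictionary_tagger, catalog,
                              libraries)
            assert outcome.status in ("suggested", "halted")
            if outcome.status == "halted":
                assert outcome.guardrail.triggered is not None
            else:
                assert outcome.direction

    def test_no_hallucination_provenance_of_every_token(
            self, rules, dictionary_tagger, catalog, libraries, patterns):
        from medic.factory import generate_corpus

        for rec in generate_corpus(patterns, libraries, 80, seed=62):
            raw = RawDirection(rec.record_id, "d009", rec.text)
            outcome = suggest(raw, rules, dictionary_tagger, catalog,
                              libraries)
            if outcome.status != "suggested":
                continue
            allowed = []
            for comp in outcome.components:
                assert comp["provenance"] in ("extracted", "catalog-filled")
                allowed.extend(comp["value"].split())
            assert outcome.direction.split() == allowed

    def test_suggestion_reextracts_to_the_same_components(
            self, rules, dictionary_tagger, catalog, libraries, patterns):
        from medic.factory import generate_corpus

        for rec in generate_corpus(patterns, libraries, 80, seed=63):
            raw = RawDirection(rec.record_id, None, rec.text)
            outcome = suggest(raw, rules, dictionary_tagger, catalog,
                              libraries)
            if outcome.status != "suggested":
                continue
            again = dictionary_tagger.tag(outcome.direction)
            got = {label.value: [v.surface for v in vals]
                   for label, vals in again.values.items()}
            want = {}
            for comp in outcome.components:
                want.setdefault(comp["label"], []).append(comp["value"])
            assert got == want
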