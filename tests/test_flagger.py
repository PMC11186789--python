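"""Component-wise flagging: equivalence, discrepancies, categories."""

import random

import pytest

from medic.flagger import (
    ERROR_CATEGORIES,
    canonicalize,
    categorize_errors,
    compare,
    evaluate_flagger,
)
from medic.factory import generate_corpus
from medic.schema import ComponentLabel, ExtractedValue, ExtractionResult


def _extraction(**kwargs):
    return ExtractionResult(values={
        ComponentLabel(name.replace("_", "-")): [
            ExtractedValue(surface=s)
            for s in ([v] if isinstance(v, str) else v)
        ]
        for name, v in kwargs.items()
    })


class TestCanonicalize:
    def test_number_words_unified(self, libraries):
        comp = canonicalize(_extraction(dose="1 tablet"), libraries)
        assert comp.get(ComponentLabel.DOSE) == ("one tablet",)

    def test_synonym_mapped_through_library(self, libraries):
        comp = canonicalize(_extraction(route="orally",
                                        frequency="daily"), libraries)
        assert comp.get(ComponentLabel.ROUTE) == ("by mouth",)
        assert comp.get(ComponentLabel.FREQUENCY) == ("once daily",)

    def test_already_canonical_is_identity(self, libraries):
        comp = canonicalize(
            _extraction(verb="take", dose="one tablet"), libraries)
        assert comp.get(ComponentLabel.VERB) == ("take",)
        assert comp.get(ComponentLabel.DOSE) == ("one tablet",)

    def test_multi_value_labels_keep_all_values(self, libraries):
        comp = canonicalize(
            _extraction(dose=["one tablet", "two tablets"]), libraries)
        assert len(comp.get(ComponentLabel.DOSE)) == 2


class TestCompare:
    def test_weekly_vs_daily_transcription_error_flagged(
            self, rules, dictionary_tagger, libraries, catalog):
        report = compare(
            "take 20 mg by mouth once weekly",
            "take 20 mg by mouth once daily",
            "d008", rules, dictionary_tagger, libraries, catalog,
        )
        assert not report.equivalent
        (disc,) = report.discrepancies
        assert disc.label is ComponentLabel.FREQUENCY
        assert disc.kind == "mismatch"

    def test_reflexivity_on_generated_directions(
            self, rules, dictionary_tagger, libraries, patterns):
        for rec in generate_corpus(patterns, libraries, 60, seed=71):
            report = compare(rec.text, rec.text, None, rules,
                             dictionary_tagger, libraries)
            assert report.equivalent

    def test_normalization_invariance_of_raw_variants(
            self, rules, dictionary_tagger, libraries, catalog):
        report = compare(
            "take one tablet by mouth once daily",
            "TAKE 1 TAB PO QD",
            "d001", rules, dictionary_tagger, libraries, catalog,
        )
        assert report.equivalent

    def test_final_mode_symmetry(self, rules, dictionary_tagger, libraries):
        a = "take one tablet by mouth once daily for pain"
        b = "chew two tablets by mouth twice daily"
        ab = compare(a, b, None, rules, dictionary_tagger, libraries)
        ba = compare(b, a, None, rules, dictionary_tagger, libraries)
        assert ab.equivalent == ba.equivalent is False
        assert {(d.label, d.value_a, d.value_b) for d in ab.discrepancies} \
            == {(d.label, d.value_b, d.value_a) for d in ba.discrepancies}

    def test_partial_mode_flags_typed_mismatch_but_not_incompleteness(
            self, rules, dictionary_tagger, libraries, catalog):
        report = compare(
            "take one tablet by mouth daily", "take two tablets",
            "d001", rules, dictionary_tagger, libraries, catalog,
            mode="partial",
        )
        assert not report.equivalent
        (disc,) = report.discrepancies
        assert disc.label is ComponentLabel.DOSE
        assert {p.value for p in report.pending} == {"route", "frequency"}

    def test_final_mode_counts_missing_components(
            self, rules, dictionary_tagger, libraries, catalog):
        report = compare(
            "take one tablet by mouth daily", "take two tablets",
            "d001", rules, dictionary_tagger, libraries, catalog,
        )
        kinds = {d.label: d.kind for d in report.discrepancies}
        assert kinds[ComponentLabel.ROUTE] == "missing-in-b"
        assert kinds[ComponentLabel.FREQUENCY] == "missing-in-b"

    def test_unknown_mode_rejected(self, rules, dictionary_tagger):
        with pytest.raises(ValueError):
            compare("a b", "a b", None, rules, dictionary_tagger,
                    mode="streaming")


class TestCategorize:
    def _report(self, a, b, rules, tagger, libraries):
        return compare(a, b, None, rules, tagger, libraries)

    def test_dose_quantity_error(self, rules, dictionary_tagger, libraries):
        report = self._report(
            "take one tablet by mouth once daily",
            "take two tablets by mouth once daily",
            rules, dictionary_tagger, libraries,
        )
        assert categorize_errors(report) == ["dose-quantity"]

    def test_dose_form_error(self, rules, dictionary_tagger, libraries):
        report = self._report(
            "take one tablet by mouth once daily",
            "take one capsule by mouth once daily",
            rules, dictionary_tagger, libraries,
        )
        assert categorize_errors(report) == ["dose-form"]

    def test_auxiliary_aggregation(self, rules, dictionary_tagger, libraries):
        report = self._report(
            "take one tablet by mouth once daily for pain",
            "take one tablet by mouth once daily for fever",
            rules, dictionary_tagger, libraries,
        )
        assert categorize_errors(report) == ["auxiliary"]

    def test_verb_route_frequency_map_to_their_own_category(
            self, rules, dictionary_tagger, libraries):
        report = self._report(
            "take one tablet by mouth once daily",
            "chew one tablet under the tongue twice daily",
            rules, dictionary_tagger, libraries,
        )
        assert categorize_errors(report) == ["verb", "route", "frequency"]


class TestEvaluateFlagger:
    def _single_perturbation_pairs(self, patterns, libraries, n_per=10,
                                   seed=81):
        rng = random.Random(seed)
        label_for = {
            "verb": ComponentLabel.VERB,
            "dose-quantity": ComponentLabel.DOSE,
            "route": ComponentLabel.ROUTE,
            "frequency": ComponentLabel.FREQUENCY,
            "auxiliary": ComponentLabel.AUXI_INDIC,
        }
        corpus = generate_corpus(patterns, libraries, 600, seed=seed)
        pairs = []
        for category, label in label_for.items():
            picked = 0
            for rec in corpus:
                if picked >= n_per:
                    break
                span = next((s for s in rec.spans if s.label == label), None)
                if span is None:
                    continue
                pool = sorted(libraries[label].surfaces - {span.surface})
                if label is ComponentLabel.DOSE:
                    # keep the unit: a pure quantity perturbation
                    unit = span.surface.split()[-1]
                    pool = [s for s in pool if s.split()[-1] == unit]
                if not pool:
                    continue
                swap = pool[rng.randrange(len(pool))]
                perturbed = (rec.text[:span.start] + swap
                             + rec.text[span.end:])
                pairs.append((rec.text, perturbed, None, category))
                picked += 1
        return pairs

    def test_single_perturbations_are_fully_localized(
            self, rules, dictionary_tagger, libraries, patterns):
        pairs = self._single_perturbation_pairs(patterns, libraries)
        result = evaluate_flagger(pairs, rules, dictionary_tagger, libraries)
        assert result["flagged_rate"] == 1.0
        for category, rate in result["per_category"].items():
            assert rate == 1.0, category

    def test_unperturbed_pairs_are_never_flagged(
            self, rules, dictionary_tagger, libraries, patterns):
        corpus = generate_corpus(patterns, libraries, 40, seed=82)
        for rec in corpus:
            report = compare(rec.text, rec.text, None, rules,
                             dictionary_tagger, libraries)
            assert report.equivalent

    def test_empty_pair_set_rejected(self, rules, dictionary_tagger):
        with pytest.raises(ValueError):
            evaluate_flagger([], rules, dictionary_tagger)

    def test_unknown_category_rejected(self, rules, dictionary_tagger):
        with pytest.raises(ValueError, match="category"):
            evaluate_flagger([("a b", "a b", None, "bogus")],
                             rules, dictionary_tagger)

    def test_all_six_categories_are_defined(self):
        assert ERROR_CATEGORIES == (
            "verb", "dose-quantity", "dose-form", "route", "frequency",
            "auxiliary",
        )
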