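# medic

A medication-direction copilot for pharmacy data entry: it converts raw
prescriber directions ("sigs") such as `TAKE 1 TAB PO QD` into
standardized, patient-safe directions such as
`take one tablet by mouth once daily`, and flags clinically meaningful
discrepancies between two directions (for example the prescriber's sig
versus what a data-entry technician typed).

Incorrect or ambiguous directions are a leading category of pharmacy
error: abbreviations and jargon must be interpreted and retyped by
technicians, and a single slip — `once weekly` typed as `once daily` —
can cause serious harm.  This package targets that data-entry stage.

## How it works

A direction decomposes into at most **nine components**, compared and
assembled in a fixed canonical order:

    verb · dose · route · frequency ·
    auxi-indic · auxi-time · auxi-period · auxi-action · auxi-maxdose

The suggestion pipeline has three stages:

1. **Pharmalexical normalization** — an ordered set of atomic,
   pattern-based transformation rules (plus conservative spell
   correction, Levenshtein distance ≤ 1 with a unique candidate) turns
   noisy raw text into clean standard English.
2. **Component extraction** — a sequence tagger over a BIO inventory of
   2 × 9 + 1 tags identifies the components *exactly as written*.  Two
   backends share the contract: a deterministic dictionary matcher over
   per-component surface libraries (greedy longest-match,
   leftmost-first), and a trainable linear-chain tagger (averaged
   structured perceptron with Viterbi decoding) trained on synthetically
   augmented labeled corpora.  Training data is produced by the corpus
   factory: sample a label *pattern* observed in labeled data, then a
   surface per component from its *component library* (L_c), and join —
   spans come out exact by construction.
3. **Semantic assembly and safety enforcement** — missing required
   components are filled from a medication catalog (drug id, dose form,
   required components, preferred defaults), the direction is assembled
   in canonical order, and five ordered guardrails can halt generation
   entirely: GR1 catalog conflict, GR2 multiple values for a component
   (multi-line direction), GR3 dose without a required verb, GR4 missing
   frequency, GR5 no dose for a tablet/capsule form.  A halt is an
   outcome, never an exception: the system prefers silence over a wrong
   suggestion.

**Flagging** reuses stages 1–2 on both directions, maps surfaces to
canonical values (synonym maps, number-word unification) and compares
component-wise, yielding a Boolean verdict plus per-component
discrepancies in six clinical categories (verb, dose quantity, dose
form, route, frequency, auxiliary).

## Worked example

```
$ cat raw.jsonl
{"record_id": "rx-1", "drug_id": "d001", "text": "TAKE 1 TAB PO QD for pain"}
{"record_id": "rx-2", "drug_id": "d001", "text": "500 mg before procedure"}

$ medic suggest --in raw.jsonl --out outcomes.jsonl
wrote outcomes.jsonl (1 halted)
```

The first record normalizes and assembles cleanly — every token of the
suggestion traces back to an extracted surface:

```json
{"record_id": "rx-1", "status": "suggested",
 "direction": "take one tablet by mouth once daily for pain",
 "components": [{"label": "verb", "value": "take", "provenance": "extracted"},
                {"label": "dose", "value": "one tablet", "provenance": "extracted"},
                {"label": "route", "value": "by mouth", "provenance": "extracted"},
                {"label": "frequency", "value": "once daily", "provenance": "extracted"},
                {"label": "auxi-indic", "value": "for pain", "provenance": "extracted"}]}
```

The second has no frequency anywhere (neither written nor defaulted in
the catalog), so guardrail GR4 halts rather than guess:

```json
{"record_id": "rx-2", "status": "halted",
 "guardrail": {"id": "GR4", "reason": "no frequency component"}}
```

Flagging the classic weekly/daily transcription error:

```
$ medic flag --a "take 20 mg by mouth once weekly" \
             --b "take 20 mg by mouth once daily" --drug d008
{"equivalent": false,
 "discrepancies": [{"label": "frequency", "value_a": "once weekly",
                    "value_b": "once daily", "kind": "mismatch"}]}
```

The library API mirrors the CLI: `normalize`, `tag_dictionary` /
`train_tagger` / `tag_model`, `generate_corpus`, `suggest`, `compare`,
`score_generation` (BLEU/METEOR), and `run_experiment` for end-to-end
harnesses.

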