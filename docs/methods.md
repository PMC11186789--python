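# Methods

This note documents the models, data-generating process and design
choices behind the package, and what the bundled tests do and do not
demonstrate about real pharmacy data.

## Component schema

A single-line medication direction conveys at most one value per
component.  We model nine components: four core (verb, dose, route,
frequency) and five refinements of the auxiliary information —
indication (`auxi-indic`), timing (`auxi-time`), period (`auxi-period`),
action (`auxi-action`) and maximum dose (`auxi-maxdose`).  Enumeration
order is the canonical assembly order and is fixed.  Character spans are
0-based, half-open (`surface == text[start:end]`) — the standard NER
corpus convention, chosen because the round trip through JSONL and
CoNLL-style BIO rows is then unambiguous.  Multi-line directions (two
doses, two frequencies) are detected — the extractor returns multiple
values for a label — and halted by guardrail GR2; assembling them is
deliberately out of scope.

## Pharmalexical normalization

Normalization is an ordered list of atomic rules, each a literal phrase
or a regular expression with an optional word-boundary wrapper, applied
case-insensitively left-to-right in rank order; the whole pass repeats
until a fixed point, capped at 5 passes.  A rule set that does not
converge (for example a self-feeding replacement) raises a
non-confluence error naming the rules still firing — silent
near-convergence would make the trace unreliable.  Every application is
recorded as `(rule_id, before, after)`; replaying the trace reproduces
the output, which is the audit contract.

Spell correction is deliberately conservative: a token is corrected only
to the *unique* vocabulary word within Levenshtein distance 1 (edlib),
never for numeric tokens, and the vocabulary is the token set of the
component libraries.  A missed typo degrades recall downstream and at
worst causes a guardrail halt; a wrong correction could change a dose.
Stop-word removal is not applied: dropping words from a prescription
risks dropping clinical content.

The bundled rule file (~46 rules) covers the common Latin sig
abbreviations (po, qd, bid, tid, qid, q4h–q12h, qhs, prn, tab/cap,
gtt, sl/sc/subq/im, dotted variants) and standalone numerals 1–9 to
words.  Production rule inventories are much larger and proprietary to
each pharmacy; the engine, file format and convergence policy are the
reusable part.  Rules are written so that every library surface is a
fixed point of the rule set — the libraries are in the normalized
dialect, the rules map raw text into it.

## Corpus factory

The factory emulates the data pipeline around a small expert-labeled
corpus:

* **Component libraries** (one per label) hold observed surface values,
  optionally with canonical-value maps (`"daily" → "once daily"`);
  expert additions merge by union.
* The **pattern library** holds each record's ordered label sequence
  with observed frequency.
* **Generation** draws a pattern, then a surface per component, and
  joins with single spaces; spans are computed exactly.  Draws are
  uniform by default (frequency weighting is available but off): where
  the sampling distribution is unspecified, uniform is the
  least-assumption choice and exercises rare patterns hardest.
  Generated directions are *not* filtered for clinical consistency —
  the extractor's job is to capture text as written, including
  erroneous prescriptions, and the catalog guardrails own correctness.
* The **noise model** inverts normalization: abbreviation substitution
  at word boundaries, seeded per-token typos (drop/swap/double at rate
  0.02 by default), and a casing policy.  Per-record RNG streams are
  derived with a stable CRC hash, so degradation is reproducible across
  processes.
* **Stratified splitting** embeds texts as term-frequency vectors,
  clusters with k-means (default k = 8) and splits each cluster
  proportionally — a simple faithful reading of "clustering a
  lower-dimensional representation"; k = 1 degrades to a plain seeded
  split.

The bundled fixture libraries (10–30 surfaces per label, 16 patterns)
are a synthetic stand-in for unpublished expert-labeled data.  They are
constructed collision-free: no surface is registered under two labels,
and no surface crosses a component boundary under greedy matching, so
the dictionary tagger is an exact oracle on generated corpora.  Real
prescriber text is messier — out-of-library values, ungrammatical
orderings, free-text auxiliaries — so passing closed-world tests bounds
the machinery's correctness, not real-world extraction accuracy.

## Extraction

The dictionary backend matches library surfaces greedily —
longest-match, leftmost-first, case-insensitive, at word boundaries —
and fails loudly on a surface registered under two labels rather than
guessing.  It is the deterministic oracle for tests and a usable
production fallback.

The trainable backend is a linear-chain tagger: an averaged structured
perceptron over word/context features (current, previous and next
token, the two adjacent bigrams, and a digit-shape flag) with learned
transition and start scores and Viterbi decoding over the 19-tag BIO
inventory.  Training honors the default hyper-parameters — batch size
16, learning rate 1e-4, 3 epochs, weight decay 1e-5 — as mini-batched
update accumulation, update scaling, a fixed epoch count and a
multiplicative per-batch shrink; iterate averaging damps oscillation.
A 90/10 seeded train/validation split is logged only; there is no early
stopping because the epoch count is part of the training contract.
Invalid BIO sequences at decode time are repaired by promoting orphan
`I-x` to `B-x`, favoring recall; repairs are logged.  Extracted
surfaces are always verbatim substrings of the input — the tagger never
rewrites text.

Evaluation is entity-level exact match (label and both boundaries):
per-label precision/recall/F1, micro averages, and a confusion matrix
over the nine labels plus the outside class whose rows sum to gold
entity counts.  A predictor that predicts nothing reports
precision 0 with a `degenerate` flag rather than a division error.

On corpora generated from the fixture libraries the task is nearly
separable, so the tagger reaches micro-F1 ≈ 1.0 already at 1,000
training samples; the augmentation-size sweep (1k/5k/10k over three
seeds) is therefore checked as non-decreasing with ties rather than as
a steep ramp, which on real hand-labeled data comes from genuine
lexical ambiguity the synthetic generator does not reproduce.

## Assembly and guardrails

Catalog fill-in adds defaults only for components the catalog marks
*required* and never overwrites an extracted value; filled values carry
`catalog-filled` provenance and no span, which makes the
no-hallucination property checkable: every token of a suggestion traces
to an extracted surface or a named catalog default.

Guardrails are evaluated in fixed order GR1→GR5 and the first hit is
primary (all hits are retained for audit).  GR1 and GR2 inspect the
*pre-fill* extraction — they judge the extractor's raw output; GR3–GR5
inspect the *post-fill* view, since a catalog default legitimately
satisfies a requirement.  This ordering reconciles "fill in first" with
"halt when nothing was extracted".  GR1 compares canonical forms
(library synonym maps plus lower-casing), so `orally` versus the
catalog's `by mouth` is not a conflict, and covers only components for
which the catalog actually has a value.  A drug id absent from the
catalog degrades gracefully: no fill-in, GR1/GR3/GR5 vacuously silent,
and the outcome annotated `catalog-missing` — halting on a catalog gap
would make coverage a hard dependency.

Assembly joins single-valued components with single spaces in canonical
order, lower-case, no terminal punctuation; display casing is a
presentation concern.

## Flagging

Semantic equivalence is equality of canonical strings — no embedding
similarity, because a false equivalence is a missed safety flag and
synonym knowledge should live in reviewable canonical maps.  Number
words are unified token-wise (`1 tab` ≡ `one tab`).  In `final` mode a
label present on one side only is a discrepancy; in `partial` mode
(modeling a half-typed entry as repeated whole-prefix calls) such
labels are *pending* and only contradictions flag.  Discrepancies map
onto six clinical categories; the dose label splits by comparing
numeric and unit token parts — differing numbers → quantity error,
differing units → form error, both → quantity, the more dangerous axis.

## Generation metrics

Sentence BLEU uses modified n-gram precisions up to 4-grams with a
brevity penalty; a zero count contributes an epsilon (0.1) numerator
because directions are short and unsmoothed BLEU collapses to 0.  The
METEOR variant is exact-match only: recall-weighted harmonic unigram
F-mean (9:1) times the standard fragmentation penalty
`0.5·(chunks/matches)³`; synonym/stemming matching is omitted, so
scores are marginally conservative for paraphrases.  Suggestion
experiments report guardrail halts separately and compute metrics over
the non-halted subset — a refusal is not a zero-quality suggestion and
must not be averaged as one.

## Problem sizes and determinism

The acceptance harness trains on 10,000 and 5,000 generated samples and
evaluates on a disjoint 10,000-sample corpus; property tests use
hundreds to a few thousand records.  All random draws — generation,
degradation, shuffling, splits — flow from explicit integer seeds, and
identical seeds give byte-identical corpora and reports.

## Known limitations

* Closed-world synthetic evaluation: fixture libraries cannot exhibit
  out-of-vocabulary surfaces, so reported F1 does not transfer to raw
  clinical text without a representative labeled sample.
* The transformer fine-tuning path is not included; the scratch tagger
  is the trainable backend.  The model artifact format (manifest +
  weights) leaves room for additional backends.
* No multi-line assembly, no dose-strength arithmetic (mg → tablets),
  no FHIR/EHR integration, and the catalog loader consumes a curated
  TSV rather than querying terminology services.
* Partial-mode flagging models typing as whole-prefix comparisons, not
  a keystroke stream.
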