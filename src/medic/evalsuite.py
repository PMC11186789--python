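"""Text-generation metrics and experiment orchestration.

Suggested directions are scored against pharmacist-verified references
with two machine-translation metrics on the [0, 1] scale:

* **BLEU** — sentence-level modified n-gram precision up to 4-grams with
  a brevity penalty; zero n-gram counts are epsilon-smoothed because
  directions are short and unsmoothed BLEU degenerates to 0.
* **METEOR** (exact-match variant) — harmonic mean of unigram precision
  and recall weighted toward recall, times a fragmentation penalty based
  on the number of contiguous matched chunks.

Guardrail halts are tallied separately: a halt is a refusal, not a bad
suggestion, so metrics are reported both over all records and over the
non-halted ("active") subset.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationEvalReport",
    "RunConfig",
    "sentence_bleu",
    "sentence_meteor",
    "score_generation",
    "run_experiment",
]

_BLEU_EPSILON = 0.1
_MAX_NGRAM = 4


def _ngrams(tokens: list[str], n: int) -> Counter:
    return Counter(
        tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)
    )


def sentence_bleu(candidate: str, reference: str,
                  max_n: int = _MAX_NGRAM) -> float:
    """Smoothed sentence-level BLEU in [0, 1].

    Geometric mean of modified n-gram precisions (n = 1..4) with a
    brevity penalty; an n-gram order with zero matches contributes an
    epsilon numerator instead of zeroing the score.
    """
    cand = candidate.split()
    ref = reference.split()
    if not cand or not ref:
        return 0.0
    log_sum = 0.0
    orders = 0
    for n in range(1, max_n + 1):
        cand_ngrams = _ngrams(cand, n)
        total = sum(cand_ngrams.values())
        if total == 0:
            break
        ref_ngrams = _ngrams(ref, n)
        clipped = sum(
            min(count, ref_ngrams.get(gram, 0))
            for gram, count in cand_ngrams.items()
        )
        numerator = clipped if clipped > 0 else _BLEU_EPSILON
        log_sum += math.log(numerator / total)
        orders += 1
    if orders == 0:
        return 0.0
    precision = math.exp(log_sum / orders)
    brevity = (
        1.0 if len(cand) >= len(ref)
        else math.exp(1.0 - len(ref) / len(cand))
    )
    return brevity * precision


def _chunks(cand: list[str], ref: list[str]) -> tuple[int, int]:
    """Greedy left-to-right unigram alignment; returns (matches, chunks)."""
    ref_positions: dict[str, list[int]] = {}
    for i, tok in enumerate(ref):
        ref_positions.setdefault(tok, []).append(i)
    used: set[int] = set()
    alignment: list[int | None] = []
    for tok in cand:
        target = None
        for pos in ref_positions.get(tok, []):
            if pos not in used:
                target = pos
                used.add(pos)
                break
        alignment.append(target)
    matches = sum(1 for a in alignment if a is not None)
    chunks = 0
    prev: int | None = None
    for a in alignment:
        if a is not None:
            if prev is None or a != prev + 1:
                chunks += 1
            prev = a
        else:
            prev = None
    return matches, chunks


def sentence_meteor(candidate: str, reference: str) -> float:
    """Exact-match METEOR in [0, 1]: recall-weighted harmonic unigram
    F-mean times a fragmentation penalty."""
    cand = candidate.split()
    ref = reference.split()
    if not cand or not ref:
        return 0.0
    matches, chunks = _chunks(cand, ref)
    if matches == 0:
        return 0.0
    precision = matches / len(cand)
    recall = matches / len(ref)
    f_mean = 10 * precision * recall / (recall + 9 * precision)
    penalty = 0.5 * (chunks / matches) ** 3
    return f_mean * (1.0 - penalty)


@dataclass
class GenerationEvalReport:
    bleu: list[float]
    meteor: list[float]
    degenerate: list[int]  # indices of empty candidates, scored 0
    n: int

    def _summary(self, scores: list[float]) -> dict[str, float]:
        arr = np.asarray(scores, dtype=float)
        return {
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "q1": float(np.percentile(arr, 25)),
            "q3": float(np.percentile(arr, 75)),
        }

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bleu": self._summary(self.bleu),
            "meteor": self._summary(self.meteor),
            "per_record": {"bleu": self.bleu, "meteor": self.meteor},
            "degenerate_records": self.degenerate,
        }


def score_generation(candidates: list[str],
                     references: list[str]) -> GenerationEvalReport:
    """Per-record BLEU and METEOR with corpus summary statistics."""
    if len(candidates) != len(references):
        raise ValueError(
            f"length mismatch: {len(candidates)} candidates vs "
            f"{len(references)} references"
        )
    if not candidates:
        raise ValueError("nothing to score")
    bleu, meteor, degenerate = [], [], []
    for i, (cand, ref) in enumerate(zip(candidates, references)):
        if not cand.strip():
            degenerate.append(i)
            bleu.append(0.0)
            meteor.append(0.0)
            continue
        bleu.append(sentence_bleu(cand, ref))
        meteor.append(sentence_meteor(cand, ref))
    return GenerationEvalReport(bleu=bleu, meteor=meteor,
                                degenerate=degenerate, n=len(candidates))


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths and seeds that fully determine an experiment run."""

    libraries: str = ""
    patterns: str = ""
    rules: str = ""
    catalog: str = ""
    noise: str = ""
    model: str = ""
    backend: str = "scratch"
    seed: int = 0
    n_train: int = 10_000
    n_test: int = 10_000
    out_dir: str = "medic-run"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _default_path(name: str) -> str:
    from importlib.resources import files

    return str(files("medic.data") / name)


def _load_resources(config: RunConfig):
    from . import factory, normalizer

    libraries = factory.load_libraries(
        config.libraries or _default_path("libraries.json")
    )
    patterns = factory.load_patterns(
        config.patterns or _default_path("patterns.json")
    )
    rules = normalizer.load_rules(config.rules or _default_path("rules.yaml"))
    vocab = {
        tok
        for lib in libraries.values()
        for surface in lib.surfaces
        for tok in surface.lower().split()
    }
    rules = rules.with_vocabulary(vocab)
    return libraries, patterns, rules


def run_experiment(config: RunConfig, experiment: str) -> dict:
    """Run a named end-to-end pipeline and write machine-readable reports.

    Experiments: ``augment-train-eval`` (generate corpora, train the
    scratch tagger, report entity-level scores), ``suggest-eval``
    (degrade generated gold directions, run suggestion, score against
    gold with BLEU/METEOR and tally guardrail halts), ``flag-eval``
    (single-perturbation pairs through the flagger).  Every report embeds
    the config fingerprint and seeds.
    """
    from . import extractor, factory

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    libraries, patterns, rules = _load_resources(config)
    report: dict = {
        "experiment": experiment,
        "config": config.to_dict(),
        "config_fingerprint": config.fingerprint(),
    }

    if experiment == "augment-train-eval":
        train = factory.generate_corpus(patterns, libraries, config.n_train,
                                        seed=config.seed)
        test = factory.generate_corpus(patterns, libraries, config.n_test,
                                       seed=config.seed + 1)
        hp = extractor.Hyperparameters(seed=config.seed)
        model = extractor.train_tagger(train, hp, backend=config.backend)
        if config.model:
            model.save(config.model)
        eval_report = extractor.evaluate_tagger(model, test)
        report["extraction"] = eval_report.to_dict()
    elif experiment == "suggest-eval":
        from . import assembler, catalog as catalog_mod
        from .factory import NoiseModel

        cat = catalog_mod.load_catalog(
            config.catalog or _default_path("catalog.tsv")
        )
        noise = (
            factory.load_noise_model(config.noise)
            if config.noise
            else NoiseModel(
                abbreviations={"by mouth": ["po"], "once daily": ["qd"],
                               "twice daily": ["bid"], "tablet": ["tab"],
                               "capsule": ["cap"]},
                typo_rate=0.02,
                casing="mixed",
                seed=config.seed,
            )
        )
        gold = factory.generate_corpus(patterns, libraries, config.n_test,
                                       seed=config.seed + 2)
        tagger = extractor.DictionaryTagger(libraries)
        candidates, references = [], []
        halts: dict[str, int] = {}
        for rec in gold:
            raw = factory.degrade(rec, noise)
            outcome = assembler.suggest(raw, rules, tagger, cat, libraries)
            if outcome.status == "halted":
                gr = outcome.guardrail.triggered.value
                halts[gr] = halts.get(gr, 0) + 1
            else:
                candidates.append(outcome.direction)
                references.append(rec.text)
        report["halts"] = halts
        report["n_active"] = len(candidates)
        report["n_total"] = len(gold)
        if candidates:
            report["generation_active"] = score_generation(
                candidates, references
            ).to_dict()
    elif experiment == "flag-eval":
        from . import flagger as flagger_mod

        gold = factory.generate_corpus(patterns, libraries, 60,
                                       seed=config.seed + 3)
        tagger = extractor.DictionaryTagger(libraries)
        pairs = _perturbation_pairs(gold, libraries, seed=config.seed)
        report["flagging"] = flagger_mod.evaluate_flagger(
            pairs, rules, tagger, libraries
        )
    else:
        raise ValueError(f"unknown experiment {experiment!r}")

    out_path = out_dir / f"{experiment}.json"
    with out_path.open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    logger.info("wrote %s", out_path)
    return report


def _perturbation_pairs(gold, libraries, seed: int):
    """Build single-perturbation flagging pairs from gold directions."""
    import random

    from .flagger import ERROR_CATEGORIES
    from .schema import ComponentLabel

    rng = random.Random(seed)
    label_for_category = {
        "verb": ComponentLabel.VERB,
        "dose-quantity": ComponentLabel.DOSE,
        "dose-form": ComponentLabel.DOSE,
        "route": ComponentLabel.ROUTE,
        "frequency": ComponentLabel.FREQUENCY,
        "auxiliary": ComponentLabel.AUXI_INDIC,
    }
    pairs = []
    for rec in gold:
        category = ERROR_CATEGORIES[len(pairs) % len(ERROR_CATEGORIES)]
        label = label_for_category[category]
        span = next((s for s in rec.spans if s.label == label), None)
        if span is None:
            continue
        pool = sorted(libraries[label].surfaces - {span.surface})
        if label is ComponentLabel.DOSE and pool:
            from .flagger import _dose_parts

            num, unit = _dose_parts(span.surface.lower())
            if category == "dose-quantity":
                narrowed = [
                    s for s in pool
                    if _dose_parts(s.lower())[1] == unit
                    and _dose_parts(s.lower())[0] != num
                ]
            else:  # dose-form: same quantity, different unit
                narrowed = [
                    s for s in pool
                    if _dose_parts(s.lower())[0] == num
                    and _dose_parts(s.lower())[1] != unit
                ]
            pool = narrowed or pool
        if not pool:
            continue
        replacement = pool[rng.randrange(len(pool))]
        perturbed = rec.text[: span.start] + replacement + rec.text[span.end:]
        pairs.append((rec.text, perturbed, None, category))
    return pairs
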