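"""Corpus factory: component libraries, pattern library, synthetic corpora.

Direction extraction is trained on synthetically augmented data.  From a
small hand-labeled corpus we harvest, per component label, the set of
observed surface values (the component libraries) and, per record, the
ordered label sequence (the pattern library).  A synthetic labeled
direction is then produced by drawing a pattern, drawing a surface for
each of its labels from the matching library, and joining the surfaces
with single spaces — spans are computed exactly, so generated corpora are
closed-world gold data for the extractor.

A seeded noise model degrades clean directions back into prescriber-style
raw text (abbreviations, typos, casing) so that the end-to-end pipeline
can be exercised without any proprietary data.
"""

from __future__ import annotations

import json
import random
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .schema import ComponentLabel, LabeledDirection, LabeledSpan, RawDirection

__all__ = [
    "ComponentLibrary",
    "PatternLibrary",
    "NoiseModel",
    "GenerationError",
    "build_libraries",
    "merge_expert_terms",
    "extract_patterns",
    "generate_corpus",
    "degrade",
    "stratified_split",
    "load_libraries",
    "save_libraries",
    "load_patterns",
    "save_patterns",
    "load_noise_model",
]


class GenerationError(ValueError):
    """Raised when generation is impossible (e.g., empty library)."""


@dataclass
class ComponentLibrary:
    """Observed surface values for one component label.

    ``canonical`` maps each surface to its canonical value and defaults to
    the identity; it is the synonym knowledge used by flagging.
    """

    label: ComponentLabel
    surfaces: set[str] = field(default_factory=set)
    canonical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.canonical:
            self.surfaces.add(key)

    def canonical_value(self, surface: str) -> str:
        return self.canonical.get(surface, surface)


@dataclass
class PatternLibrary:
    """Unique ordered label sequences with observed frequencies."""

    counts: dict[tuple[ComponentLabel, ...], int] = field(default_factory=dict)

    @property
    def patterns(self) -> list[tuple[ComponentLabel, ...]]:
        return list(self.counts)

    def add(self, pattern: tuple[ComponentLabel, ...], count: int = 1) -> None:
        if not pattern:
            raise GenerationError("empty pattern")
        self.counts[pattern] = self.counts.get(pattern, 0) + count

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class NoiseModel:
    """Prescriber-style degradation: abbreviations, typos, casing.

    ``abbreviations`` maps a clean phrase to raw variants (the inverse of
    the normalization rules); ``typo_rate`` is a per-token probability;
    ``casing`` is one of preserve | upper | lower | mixed.
    """

    abbreviations: dict[str, list[str]] = field(default_factory=dict)
    typo_rate: float = 0.0
    casing: str = "preserve"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ValueError("typo_rate must be in [0, 1]")
        if self.casing not in ("preserve", "upper", "lower", "mixed"):
            raise ValueError(f"unknown casing policy {self.casing!r}")


def build_libraries(
    corpus: list[LabeledDirection],
) -> dict[ComponentLabel, ComponentLibrary]:
    """Harvest one surface library per label from a labeled corpus.

    Always returns exactly nine libraries (possibly empty); duplicates
    collapse under set semantics.
    """
    libraries = {
        label: ComponentLibrary(label=label) for label in ComponentLabel
    }
    for rec in corpus:
        for span in rec.spans:
            libraries[span.label].surfaces.add(span.surface)
    return libraries


def merge_expert_terms(
    library: ComponentLibrary, additions: list[str]
) -> ComponentLibrary:
    """Extend a library with expert-curated surface values."""
    merged = ComponentLibrary(
        label=library.label,
        surfaces=set(library.surfaces),
        canonical=dict(library.canonical),
    )
    for term in additions:
        if not term or not term.strip():
            raise ValueError("cannot add an empty surface value")
        if term in merged.canonical and merged.canonical[term] != term:
            raise ValueError(
                f"surface {term!r} already canonical-mapped to "
                f"{merged.canonical[term]!r}"
            )
        merged.surfaces.add(term)
    return merged


def extract_patterns(corpus: list[LabeledDirection]) -> PatternLibrary:
    """Collect the ordered label sequence of every record."""
    lib = PatternLibrary()
    for rec in corpus:
        pattern = rec.pattern()
        if pattern:
            lib.add(pattern)
    return lib


def generate_corpus(
    patterns: PatternLibrary,
    libraries: dict[ComponentLabel, ComponentLibrary],
    n: int,
    seed: int,
    weighted: bool = False,
    id_prefix: str = "gen",
) -> list[LabeledDirection]:
    """Generate ``n`` labeled directions by pattern + surface sampling.

    Each record draws a pattern (uniform by default, frequency-weighted if
    ``weighted``), then a uniform surface per component; components join
    with single spaces and spans are computed exactly.  The same seed
    always yields the identical corpus.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    pattern_list = sorted(patterns.counts, key=lambda p: [l.value for l in p])
    if not pattern_list and n > 0:
        raise GenerationError("pattern library is empty")
    for pattern in pattern_list:
        for label in pattern:
            lib = libraries.get(label)
            if lib is None or not lib.surfaces:
                raise GenerationError(
                    f"pattern uses label {label.value!r} whose library is empty"
                )
    surface_lists = {
        label: sorted(lib.surfaces) for label, lib in libraries.items()
    }
    rng = random.Random(seed)
    weights = [patterns.counts[p] for p in pattern_list] if weighted else None
    records: list[LabeledDirection] = []
    for i in range(n):
        if weighted:
            pattern = rng.choices(pattern_list, weights=weights, k=1)[0]
        else:
            pattern = pattern_list[rng.randrange(len(pattern_list))]
        parts = [
            surface_lists[label][rng.randrange(len(surface_lists[label]))]
            for label in pattern
        ]
        spans: list[LabeledSpan] = []
        offset = 0
        for label, part in zip(pattern, parts):
            start = offset if offset == 0 else offset + 1
            end = start + len(part)
            spans.append(LabeledSpan(start=start, end=end, label=label,
                                     surface=part))
            offset = end
        text = " ".join(parts)
        records.append(
            LabeledDirection(
                record_id=f"{id_prefix}-{seed}-{i:06d}",
                text=text,
                spans=tuple(spans),
            )
        )
    return records


_TYPO_OPS = ("drop", "swap", "double")


def _typo(token: str, rng: random.Random) -> str:
    if len(token) < 3:
        return token
    op = _TYPO_OPS[rng.randrange(len(_TYPO_OPS))]
    # keep first character intact: leading-letter typos are rare in sigs
    pos = rng.randrange(1, len(token) - 1)
    if op == "drop":
        return token[:pos] + token[pos + 1:]
    if op == "swap":
        return token[:pos] + token[pos + 1] + token[pos] + token[pos + 2:]
    return token[:pos] + token[pos] + token[pos:]


def degrade(direction: LabeledDirection, noise: NoiseModel) -> RawDirection:
    """Produce prescriber-style raw text from a clean labeled direction.

    Applies abbreviation substitutions (longest phrase first), seeded
    per-token typos at ``noise.typo_rate``, then the casing policy.  With
    an empty abbreviation map and zero typo rate the text is unchanged.
    """
    # per-record stream derived with a stable hash so degradation is
    # reproducible across processes
    record_key = zlib.crc32(direction.record_id.encode("utf-8"))
    rng = random.Random((noise.seed * 2654435761 + record_key) & 0x7FFFFFFF)
    text = direction.text
    for phrase in sorted(noise.abbreviations, key=len, reverse=True):
        variants = noise.abbreviations[phrase]
        if not variants:
            continue
        pattern = re.compile(rf"\b{re.escape(phrase)}\b")
        if pattern.search(text):
            variant = variants[rng.randrange(len(variants))]
            text = pattern.sub(variant, text)
    if noise.typo_rate > 0:
        tokens = text.split(" ")
        tokens = [
            _typo(tok, rng) if rng.random() < noise.typo_rate else tok
            for tok in tokens
        ]
        text = " ".join(tokens)
    if noise.casing == "upper":
        text = text.upper()
    elif noise.casing == "lower":
        text = text.lower()
    elif noise.casing == "mixed":
        text = " ".join(
            tok.upper() if rng.random() < 0.3 else tok
            for tok in text.split(" ")
        )
    return RawDirection(record_id=direction.record_id,
                        drug_id=direction.drug_id, text=text)


def stratified_split(
    corpus: list[LabeledDirection],
    fractions: tuple[float, ...],
    k: int = 8,
    seed: int = 0,
) -> list[list[LabeledDirection]]:
    """Split a corpus into parts, stratified by text clusters.

    Records are embedded as term-frequency vectors, clustered with k-means
    into ``k`` groups, and each group is split proportionally, so every
    part sees a representative mix of direction shapes.  ``k=1`` reduces
    to a plain seeded random split.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(corpus) < len(fractions):
        raise ValueError("corpus smaller than the number of parts")
    rng = random.Random(seed)
    if k == 1 or len(corpus) <= k:
        cluster_ids = [0] * len(corpus)
    else:
        from sklearn.cluster import KMeans
        from sklearn.feature_extraction.text import CountVectorizer

        texts = [rec.text for rec in corpus]
        matrix = CountVectorizer().fit_transform(texts)
        cluster_ids = (
            KMeans(n_clusters=k, random_state=seed % (2**31), n_init=4)
            .fit_predict(matrix.toarray().astype(float))
            .tolist()
        )
    parts: list[list[LabeledDirection]] = [[] for _ in fractions]
    cumulative = np.cumsum(fractions)
    for cluster in sorted(set(cluster_ids)):
        members = [i for i, c in enumerate(cluster_ids) if c == cluster]
        rng.shuffle(members)
        bounds = [int(round(frac * len(members))) for frac in cumulative]
        start = 0
        for part, bound in zip(parts, bounds):
            part.extend(corpus[i] for i in members[start:bound])
            start = bound
        # rounding leftovers go to the last part
        parts[-1].extend(corpus[i] for i in members[start:])
    return parts


# ---------------------------------------------------------------------------
# File formats: libraries JSON {label: {surface: canonical}},
# patterns JSON [[label, ...], ...], noise model YAML.
# ---------------------------------------------------------------------------

def load_libraries(path: str | Path) -> dict[ComponentLabel, ComponentLibrary]:
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    libraries = {
        label: ComponentLibrary(label=label) for label in ComponentLabel
    }
    for name, mapping in raw.items():
        label = ComponentLabel(name)
        libraries[label] = ComponentLibrary(
            label=label,
            surfaces=set(mapping),
            canonical={k: v for k, v in mapping.items() if k != v},
        )
    return libraries


def save_libraries(
    libraries: dict[ComponentLabel, ComponentLibrary], path: str | Path
) -> None:
    obj = {
        label.value: {
            surface: lib.canonical_value(surface)
            for surface in sorted(lib.surfaces)
        }
        for label, lib in libraries.items()
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, ensure_ascii=False)


def load_patterns(path: str | Path) -> PatternLibrary:
    with Path(path).open(encoding="utf-8") as fh:
        raw = json.load(fh)
    lib = PatternLibrary()
    for item in raw:
        if isinstance(item, dict):
            labels, count = item["pattern"], int(item.get("count", 1))
        else:
            labels, count = item, 1
        lib.add(tuple(ComponentLabel(name) for name in labels), count)
    return lib


def save_patterns(patterns: PatternLibrary, path: str | Path) -> None:
    obj = [
        {"pattern": [label.value for label in pattern], "count": count}
        for pattern, count in sorted(
            patterns.counts.items(), key=lambda kv: [l.value for l in kv[0]]
        )
    ]
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)


def load_noise_model(path: str | Path) -> NoiseModel:
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return NoiseModel(
        abbreviations={
            str(k): [str(v) for v in vs]
            for k, vs in (raw.get("abbreviations") or {}).items()
        },
        typo_rate=float(raw.get("typo_rate", 0.0)),
        casing=str(raw.get("casing", "preserve")),
        seed=int(raw.get("seed", 0)),
    )
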