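"""Core domain types and corpus serialization for medication directions.

A medication direction ("sig") decomposes into at most nine components.
Four are core — the verb, the dose, the route of administration and the
frequency — and five refine the auxiliary information: indication, timing,
period, action and maximum dose.  Every downstream stage (normalization,
extraction, assembly, flagging) shares the span-annotated record types
defined here.

Character offsets are 0-based and half-open: for every span,
``surface == text[start:end]``.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentLabel",
    "RawDirection",
    "LabeledSpan",
    "LabeledDirection",
    "ExtractedValue",
    "ExtractionResult",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "to_conll",
    "from_conll",
    "tokenize",
]


class ComponentLabel(str, Enum):
    """The nine direction components, in canonical assembly order.

    The first four members are the core components; the remaining five
    form the auxiliary family.  Enumeration order *is* assembly order.
    """

    VERB = "verb"
    DOSE = "dose"
    ROUTE = "route"
    FREQUENCY = "frequency"
    AUXI_INDIC = "auxi-indic"
    AUXI_TIME = "auxi-time"
    AUXI_PERIOD = "auxi-period"
    AUXI_ACTION = "auxi-action"
    AUXI_MAXDOSE = "auxi-maxdose"

    @classmethod
    def core(cls) -> tuple["ComponentLabel", ...]:
        return (cls.VERB, cls.DOSE, cls.ROUTE, cls.FREQUENCY)

    @classmethod
    def auxiliary(cls) -> tuple["ComponentLabel", ...]:
        return (
            cls.AUXI_INDIC,
            cls.AUXI_TIME,
            cls.AUXI_PERIOD,
            cls.AUXI_ACTION,
            cls.AUXI_MAXDOSE,
        )

    @classmethod
    def canonical_order(cls) -> tuple["ComponentLabel", ...]:
        return tuple(cls)


CANONICAL_ORDER: tuple[ComponentLabel, ...] = ComponentLabel.canonical_order()


class CorpusError(ValueError):
    """Raised for malformed corpus records or span-invariant violations."""


@dataclass(frozen=True)
class RawDirection:
    """A raw prescriber direction attached to a drug identifier."""

    record_id: str
    drug_id: str | None
    text: str

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise CorpusError(
                f"record {self.record_id!r}: direction text is empty"
            )


@dataclass(frozen=True, order=True)
class LabeledSpan:
    """A labeled character span; 0-based, half-open."""

    start: int
    end: int
    label: ComponentLabel
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"span {self.label.value} [{self.start}, {self.end}): "
                "offsets must satisfy 0 <= start < end"
            )


@dataclass(frozen=True)
class LabeledDirection:
    """A direction with ordered, non-overlapping component spans."""

    record_id: str
    text: str
    spans: tuple[LabeledSpan, ...]
    drug_id: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise CorpusError(f"record {self.record_id!r}: empty text")
        spans = tuple(self.spans)
        object.__setattr__(self, "spans", spans)
        prev_end = -1
        for span in spans:
            if span.end > len(self.text):
                raise CorpusError(
                    f"record {self.record_id!r}: span [{span.start}, "
                    f"{span.end}) exceeds text length {len(self.text)}"
                )
            if span.start < prev_end:
                raise CorpusError(
                    f"record {self.record_id!r}: spans overlap or are "
                    f"unsorted at offset {span.start}"
                )
            if self.text[span.start : span.end] != span.surface:
                raise CorpusError(
                    f"record {self.record_id!r}: surface {span.surface!r} "
                    f"!= text[{span.start}:{span.end}] "
                    f"({self.text[span.start:span.end]!r})"
                )
            prev_end = span.end

    def pattern(self) -> tuple[ComponentLabel, ...]:
        """The ordered label sequence of this direction."""
        return tuple(s.label for s in self.spans)


@dataclass(frozen=True)
class ExtractedValue:
    """One extracted component value; catalog-filled values carry no span."""

    surface: str
    span: LabeledSpan | None = None
    provenance: str = "extracted"  # "extracted" | "catalog-filled"


@dataclass
class ExtractionResult:
    """Per-label extracted values.  A label absent from ``values`` was not
    extracted.  ``backend`` records which tagger produced the result."""

    values: dict[ComponentLabel, list[ExtractedValue]] = field(
        default_factory=dict
    )
    backend: str = "dictionary"

    def get(self, label: ComponentLabel) -> list[ExtractedValue]:
        return self.values.get(label, [])

    def single(self, label: ComponentLabel) -> ExtractedValue | None:
        vals = self.get(label)
        return vals[0] if len(vals) == 1 else None

    def extracted_only(self) -> "ExtractionResult":
        """A view holding only values that came out of the text itself."""
        out: dict[ComponentLabel, list[ExtractedValue]] = {}
        for label, vals in self.values.items():
            kept = [v for v in vals if v.provenance == "extracted"]
            if kept:
                out[label] = kept
        return ExtractionResult(values=out, backend=self.backend)


# ---------------------------------------------------------------------------
# JSONL corpus I/O
# ---------------------------------------------------------------------------

def _record_to_obj(rec: LabeledDirection) -> dict:
    return {
        "record_id": rec.record_id,
        "drug_id": rec.drug_id,
        "text": rec.text,
        "spans": [
            {"label": s.label.value, "start": s.start, "end": s.end}
            for s in rec.spans
        ],
    }


def _obj_to_record(obj: dict, lineno: int) -> LabeledDirection:
    try:
        record_id = obj["record_id"]
        text = obj["text"]
        raw_spans = obj.get("spans", [])
    except (KeyError, TypeError) as exc:
        raise CorpusError(f"line {lineno}: missing field {exc}") from exc
    spans = []
    for raw in raw_spans:
        try:
            label = ComponentLabel(raw["label"])
            start, end = int(raw["start"]), int(raw["end"])
        except (KeyError, ValueError, TypeError) as exc:
            raise CorpusError(
                f"record {record_id!r}: malformed span {raw!r}: {exc}"
            ) from exc
        try:
            spans.append(
                LabeledSpan(
                    start=start, end=end, label=label,
                    surface=(text[start:end]
                             if 0 <= start < end <= len(text) else ""),
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"record {record_id!r}: {exc}") from exc
    return LabeledDirection(
        record_id=record_id,
        drug_id=obj.get("drug_id"),
        text=text,
        spans=tuple(spans),
    )


def read_corpus(path: str | Path) -> list[LabeledDirection]:
    """Read a JSONL span-annotated corpus, preserving record order.

    Raises :class:`CorpusError` naming the record and field for malformed
    records; duplicate ``record_id`` values are warned about but kept.
    """
    path = Path(path)
    records: list[LabeledDirection] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON: {exc}") from exc
            rec = _obj_to_record(obj, lineno)
            if rec.record_id in seen:
                logger.warning("duplicate record_id %r at line %d",
                               rec.record_id, lineno)
            seen.add(rec.record_id)
            records.append(rec)
    return records


def write_corpus(corpus: Iterable[LabeledDirection], path: str | Path) -> None:
    """Write a corpus as JSONL; round-trips bit-exactly through read_corpus."""
    path = Path(path)
    seen: set[str] = set()
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            if rec.record_id in seen:
                logger.warning("duplicate record_id %r written", rec.record_id)
            seen.add(rec.record_id)
            fh.write(json.dumps(_record_to_obj(rec), ensure_ascii=False))
            fh.write("\n")


# ---------------------------------------------------------------------------
# CoNLL interop
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace + punctuation tokenizer returning (token, start, end)."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def to_conll(direction: LabeledDirection) -> list[tuple[str, str]]:
    """Encode a direction as (token, BIO-tag) rows.

    Spans must align to token boundaries; a span crossing a token raises
    :class:`CorpusError` naming the span.
    """
    tokens = tokenize(direction.text)
    rows: list[tuple[str, str]] = []
    span_iter = iter(direction.spans)
    current = next(span_iter, None)
    for tok, start, end in tokens:
        while current is not None and current.end <= start:
            current = next(span_iter, None)
        if current is None or end <= current.start:
            rows.append((tok, "O"))
            continue
        if start < current.start or end > current.end:
            raise CorpusError(
                f"record {direction.record_id!r}: span "
                f"{current.label.value} [{current.start}, {current.end}) "
                f"crosses token {tok!r} [{start}, {end})"
            )
        prefix = "B" if start == current.start else "I"
        rows.append((tok, f"{prefix}-{current.label.value}"))
    return rows


def from_conll(rows: Sequence[tuple[str, str]], record_id: str = "conll",
               drug_id: str | None = None) -> LabeledDirection:
    """Decode (token, BIO-tag) rows back into a labeled direction.

    Tokens are joined with single spaces; B/I runs become spans.
    """
    parts: list[str] = []
    bounds: list[tuple[str, int, int]] = []
    offset = 0
    for tok, _tag in rows:
        start = offset + (1 if parts else 0)
        parts.append(tok)
        bounds.append((tok, start, start + len(tok)))
        offset = start + len(tok)
    text = " ".join(parts)
    tags = [tag for _tok, tag in rows]
    spans = spans_from_bio(text, bounds, tags)
    return LabeledDirection(record_id=record_id, drug_id=drug_id,
                            text=text, spans=spans)


def write_conll(corpus: Iterable[LabeledDirection], path: str | Path) -> None:
    """Write token TAB tag rows, blank line between records."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in corpus:
            for tok, tag in to_conll(rec):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def spans_from_bio(text: str, tokens: Sequence[tuple[str, int, int]],
                   tags: Sequence[str],
                   repair_log: list[str] | None = None) -> tuple[LabeledSpan, ...]:
    """Decode BIO tags over tokens of ``text`` into character spans.

    Invalid sequences are repaired: an I-x without a preceding B-x/I-x is
    promoted to B-x (favoring recall); repairs are appended to ``repair_log``.
    """
    spans: list[LabeledSpan] = []
    open_label: ComponentLabel | None = None
    open_start = open_end = 0
    for (tok, start, end), tag in zip(tokens, tags):
        if tag == "O":
            label, prefix = None, None
        else:
            prefix, _, name = tag.partition("-")
            label = ComponentLabel(name)
        if label is not None and prefix == "I" and open_label != label:
            if repair_log is not None:
                repair_log.append(f"promoted I-{label.value} to B at {start}")
            prefix = "B"
        closes = open_label is not None and (
            label is None or prefix == "B" or label != open_label
        )
        if closes:
            spans.append(LabeledSpan(start=open_start, end=open_end,
                                     label=open_label,
                                     surface=text[open_start:open_end]))
            open_label = None
        if label is not None:
            if open_label is None:
                open_label, open_start = label, start
            open_end = end
    if open_label is not None:
        spans.append(LabeledSpan(start=open_start, end=open_end,
                                 label=open_label,
                                 surface=text[open_start:open_end]))
    return tuple(spans)
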