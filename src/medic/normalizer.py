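"""Pharmalexical normalization: noisy sig text to clean standard English.

Raw prescriber directions mix everyday English with pharmacy jargon,
Latin abbreviations ("1 tab po qd") and typos.  Normalization applies an
ordered set of atomic pattern-based transformation rules — each either a
literal phrase substitution or a regular expression — plus conservative
spell correction against a vocabulary of known component terms.  The
engine is deliberately auditable: every application is recorded in a
trace, and replaying the trace reproduces the output.

Rule passes repeat until a fixed point is reached (bounded by
``MAX_PASSES``); a rule set that oscillates raises
:class:`NonConfluenceError` naming the rules still firing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import yaml

__all__ = [
    "NormalizationRule",
    "RuleSet",
    "NormalizedDirection",
    "RuleError",
    "NonConfluenceError",
    "load_rules",
    "normalize",
    "spell_correct",
]

MAX_PASSES = 5

_NUMERIC_RE = re.compile(r"^\d+([./]\d+)?$")
_WS_RE = re.compile(r"\s+")


class RuleError(ValueError):
    """Raised when a rules file is malformed."""


class NonConfluenceError(RuntimeError):
    """Raised when rule passes fail to reach a fixed point."""


@dataclass(frozen=True)
class NormalizationRule:
    rule_id: str
    kind: str  # "literal" | "regex"
    match: str
    replace: str
    word_boundary: bool = True
    order: int = 0

    def compiled(self) -> re.Pattern:
        if self.kind == "regex":
            pattern = self.match
        else:
            pattern = re.escape(self.match)
        if self.word_boundary:
            pattern = rf"\b(?:{pattern})\b"
        try:
            return re.compile(pattern, re.IGNORECASE)
        except re.error as exc:
            raise RuleError(
                f"rule {self.rule_id!r}: pattern does not compile: {exc}"
            ) from exc

    def apply(self, text: str) -> str:
        return self.compiled().sub(self.replace, text)


@dataclass
class RuleSet:
    rules: list[NormalizationRule]
    vocabulary: frozenset[str] = frozenset()
    max_edit: int = 1

    def __post_init__(self) -> None:
        self.rules = sorted(self.rules, key=lambda r: r.order)
        self._compiled = [(r, r.compiled()) for r in self.rules]

    def with_vocabulary(self, vocabulary: set[str] | frozenset[str]) -> "RuleSet":
        return RuleSet(rules=list(self.rules),
                       vocabulary=frozenset(vocabulary),
                       max_edit=self.max_edit)


@dataclass
class NormalizedDirection:
    original: str
    normalized: str
    trace: list[tuple[str, str, str]] = field(default_factory=list)
    # trace entries are (rule_id, text_before, text_after)

    def replay(self) -> str:
        """Re-derive the normalized text from the trace (audit check)."""
        text = self.trace[0][1] if self.trace else self.normalized
        for _rule_id, before, after in self.trace:
            if text != before:
                raise RuntimeError("trace is inconsistent with input")
            text = after
        return text


def load_rules(path: str | Path) -> RuleSet:
    """Load a YAML rules file, preserving declared order.

    Raises :class:`RuleError` for duplicate ids or non-compiling patterns,
    naming the offending rule.
    """
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise RuleError(f"{path}: expected a YAML list of rules")
    rules: list[NormalizationRule] = []
    seen: set[str] = set()
    for order, item in enumerate(raw):
        rule_id = str(item.get("id", "")).strip()
        if not rule_id:
            raise RuleError(f"{path}: rule #{order} has no id")
        if rule_id in seen:
            raise RuleError(f"duplicate rule id {rule_id!r}")
        seen.add(rule_id)
        kind = item.get("kind", "literal")
        if kind not in ("literal", "regex"):
            raise RuleError(f"rule {rule_id!r}: unknown kind {kind!r}")
        rule = NormalizationRule(
            rule_id=rule_id,
            kind=kind,
            match=str(item["match"]),
            replace=str(item["replace"]),
            word_boundary=bool(item.get("word_boundary", True)),
            order=order,
        )
        rule.compiled()  # fail at load time, naming the rule
        rules.append(rule)
    return RuleSet(rules=rules)


def spell_correct(token: str, vocabulary: frozenset[str] | set[str],
                  max_edit: int = 1) -> str:
    """Correct ``token`` to the unique vocabulary word within ``max_edit``
    Levenshtein edits, if exactly one exists; otherwise return it unchanged.

    Numeric tokens are never corrected — a wrong dose is worse than a typo.
    """
    if not vocabulary or token in vocabulary or _NUMERIC_RE.match(token):
        return token
    candidates = []
    for word in vocabulary:
        if abs(len(word) - len(token)) > max_edit:
            continue
        dist = edlib.align(token, word, k=max_edit)["editDistance"]
        if 0 <= dist <= max_edit:
            candidates.append(word)
            if len(candidates) > 1:
                return token  # ambiguous: never guess
    return candidates[0] if len(candidates) == 1 else token


def _one_pass(text: str, ruleset: RuleSet,
              trace: list[tuple[str, str, str]]) -> str:
    for rule, compiled in ruleset._compiled:
        after = compiled.sub(rule.replace, text)
        if after != text:
            trace.append((rule.rule_id, text, after))
            text = after
    return text


def normalize(text: str, rules: RuleSet) -> NormalizedDirection:
    """Normalize a raw direction: lower-case, collapse whitespace, apply
    the rule set to a fixed point, then spell-correct unknown tokens.

    Deterministic: identical input and rule set give an identical output
    and trace.
    """
    if not text or not text.strip():
        raise ValueError("cannot normalize empty direction text")
    original = text
    trace: list[tuple[str, str, str]] = []
    current = _WS_RE.sub(" ", text.strip().lower())
    if current != text:
        trace.append(("case-whitespace", text, current))
    for pass_no in range(MAX_PASSES):
        after = _one_pass(current, rules, trace)
        if after == current:
            break
        current = after
    else:
        probe: list[tuple[str, str, str]] = []
        _one_pass(current, rules, probe)
        oscillating = sorted({rid for rid, _b, _a in probe})
        raise NonConfluenceError(
            f"no fixed point after {MAX_PASSES} passes; "
            f"rules still firing: {oscillating}"
        )
    if rules.vocabulary:
        tokens = current.split(" ")
        corrected = [
            spell_correct(tok, rules.vocabulary, rules.max_edit)
            for tok in tokens
        ]
        if corrected != tokens:
            after = " ".join(corrected)
            trace.append(("spell-correct", current, after))
            current = after
    return NormalizedDirection(original=original, normalized=current,
                               trace=trace)
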