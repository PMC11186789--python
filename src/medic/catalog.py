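"""Medication catalog: drug-level records powering fill-in and guardrails.

Each catalog entry records the drug's dose form and strength, which of the
nine direction components are required for that drug, and default surface
values for components the prescriber may omit (for example the preferred
verb "chew" for a chewable tablet).  The catalog is the verification
authority for the safety guardrails: an extracted value that contradicts a
catalog default halts suggestion generation.

The on-disk format is a UTF-8 TSV with a mandatory header:

    drug_id  description  dose_form  strength  active_ingredients
    required  default_verb  default_dose  default_route
    default_frequency  default_aux

``active_ingredients`` and ``required`` are semicolon-separated lists;
``required`` entries must be component-label names.  ``default_aux`` holds
``label=value`` pairs separated by semicolons for the auxiliary family.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .schema import ComponentLabel

logger = logging.getLogger(__name__)

__all__ = ["CatalogEntry", "Catalog", "CatalogError", "load_catalog", "NOT_FOUND"]

_HEADER = [
    "drug_id", "description", "dose_form", "strength",
    "active_ingredients", "required", "default_verb", "default_dose",
    "default_route", "default_frequency", "default_aux",
]

_DEFAULT_COLUMNS = {
    "default_verb": ComponentLabel.VERB,
    "default_dose": ComponentLabel.DOSE,
    "default_route": ComponentLabel.ROUTE,
    "default_frequency": ComponentLabel.FREQUENCY,
}


class CatalogError(ValueError):
    """Raised for unusable catalog files."""


class _NotFound:
    """Distinguishable not-found signal for catalog lookups."""

    __slots__ = ()

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "NOT_FOUND"


NOT_FOUND = _NotFound()


@dataclass(frozen=True)
class CatalogEntry:
    drug_id: str
    description: str = ""
    dose_form: str = ""
    strength: str = ""
    active_ingredients: tuple[str, ...] = ()
    required: frozenset[ComponentLabel] = frozenset()
    defaults: dict[ComponentLabel, str] = field(default_factory=dict)


@dataclass
class Catalog:
    entries: dict[str, CatalogEntry]
    source: str = ""
    loaded_at: str = ""
    dropped: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, drug_id: str) -> CatalogEntry | _NotFound:
        """Return the entry for ``drug_id`` or the NOT_FOUND signal."""
        return self.entries.get(drug_id, NOT_FOUND)


def _split_list(raw: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in raw.split(";") if p.strip())


def _parse_row(row: dict[str, str]) -> CatalogEntry | None:
    """Parse one TSV row; return None if the row must be dropped."""
    drug_id = (row.get("drug_id") or "").strip()
    if not drug_id:
        return None
    try:
        required = frozenset(
            ComponentLabel(name) for name in _split_list(row.get("required", ""))
        )
    except ValueError:
        return None
    defaults: dict[ComponentLabel, str] = {}
    for column, label in _DEFAULT_COLUMNS.items():
        value = (row.get(column) or "").strip()
        if value:
            defaults[label] = value
    aux_raw = (row.get("default_aux") or "").strip()
    if aux_raw:
        for pair in _split_list(aux_raw):
            name, sep, value = pair.partition("=")
            if not sep:
                return None
            try:
                label = ComponentLabel(name.strip())
            except ValueError:
                return None
            defaults[label] = value.strip()
    return CatalogEntry(
        drug_id=drug_id,
        description=(row.get("description") or "").strip(),
        dose_form=(row.get("dose_form") or "").strip().lower(),
        strength=(row.get("strength") or "").strip(),
        active_ingredients=_split_list(row.get("active_ingredients", "")),
        required=required,
        defaults=defaults,
    )


def load_catalog(path: str | Path) -> Catalog:
    """Load and validate a catalog TSV.

    Rows with a blank ``drug_id`` or unparseable ``required``/default
    fields are dropped and counted; on a duplicate ``drug_id`` the first
    row wins and the conflict is logged.
    """
    path = Path(path)
    entries: dict[str, CatalogEntry] = {}
    dropped = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty catalog file")
        missing = [col for col in _HEADER if col not in reader.fieldnames]
        if missing:
            raise CatalogError(f"{path}: header missing columns {missing}")
        rows = list(reader)
    if not rows:
        raise CatalogError(f"{path}: catalog has a header but no rows")
    for row in rows:
        entry = _parse_row(row)
        if entry is None:
            dropped += 1
            continue
        if entry.drug_id in entries:
            logger.warning("duplicate drug_id %r: keeping first row",
                           entry.drug_id)
            dropped += 1  # keeps dropped + retained == input rows
            continue
        entries[entry.drug_id] = entry
    return Catalog(
        entries=entries,
        source=str(path),
        loaded_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        dropped=dropped,
    )
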