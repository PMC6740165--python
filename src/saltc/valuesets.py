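"""Value-set registry: categories, canonical values, SNOMED codes, triggers.

Five categories of categorical laboratory tests are supported — urine color,
urine dipstick, blood type, presence finding and pathogenesis — plus an
``UNCLASSIFIED`` sentinel for tests that match none of them. Each category
holds an ordered list of canonical values; a canonical value carries a
display label, an optional SNOMED CT concept identifier, and the abbreviated
*comparison string* the similarity matcher actually vectorizes (``negative``
-> ``neg-``, ``positive`` -> ``posi`` — abbreviations chosen to minimize
shared characters between values of the same set).

The registry also carries per-category *trigger lexicons*: normalized strings
whose exact presence among a test's main values assigns the test to that
category during rule-based categorization.

A registry loads from the packaged default config or from a user YAML/JSON
file; loading is all-or-nothing, with errors naming the offending entry.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from ._scheme import SCHEME
from .preprocess import general_clean

__all__ = [
    "Category",
    "CATEGORY_ORDER",
    "CanonicalValue",
    "ValueSetRegistry",
    "RegistryConfigError",
    "RegistryLookupError",
    "load_registry",
    "lookup_snomed",
]


class Category(enum.Enum):
    """Laboratory-test category; members are listed in evaluation order."""

    URINE_COLOR = "urine_color"
    URINE_DIPSTICK = "urine_dipstick"
    BLOOD_TYPE = "blood_type"
    PRESENCE_FINDING = "presence_finding"
    PATHOGENESIS = "pathogenesis"
    UNCLASSIFIED = "unclassified"


#: The fixed order in which the categorizer tries the mappable categories.
CATEGORY_ORDER: tuple[Category, ...] = (
    Category.URINE_COLOR,
    Category.URINE_DIPSTICK,
    Category.BLOOD_TYPE,
    Category.PRESENCE_FINDING,
    Category.PATHOGENESIS,
)


class RegistryConfigError(ValueError):
    """A value-set config failed to parse or validate; message names the entry."""


class RegistryLookupError(KeyError):
    """A canonical value or label is not present in the registry."""


@dataclass(frozen=True)
class CanonicalValue:
    """One member of a value set.

    ``comparison_string`` is the text the matcher vectorizes; it defaults to
    the normalized label but is usually an abbreviation that strips characters
    shared with sibling values.
    """

    label: str
    category: Category
    comparison_string: str
    snomed_id: str | None = None


_ENTRY_FIELDS = {"label", "snomed_id", "comparison_string", "triggers"}
_SCHEME_SET = set(SCHEME)


def _norm(text: str) -> str:
    return general_clean(text).text


class ValueSetRegistry:
    """Validated, immutable collection of canonical values and trigger lexicons."""

    def __init__(
        self,
        entries: Mapping[Category, Iterable[CanonicalValue]],
        triggers: Mapping[Category, Iterable[str]],
    ) -> None:
        self._entries: dict[Category, tuple[CanonicalValue, ...]] = {
            cat: tuple(vals) for cat, vals in entries.items()
        }
        self._triggers: dict[Category, frozenset[str]] = {
            cat: frozenset(_norm(t) for t in trig) for cat, trig in triggers.items()
        }
        self._validate()
        # which canonical value each trigger was configured under; cosmetic,
        # only used to lay out to_config(). Unowned triggers attach to the
        # first value of their category.
        self._trigger_map: dict[tuple[Category, str], tuple[str, ...]] = {}
        self._by_label = {
            (cat, val.label): val for cat, vals in self._entries.items() for val in vals
        }

    def _validate(self) -> None:
        for cat in CATEGORY_ORDER:
            vals = self._entries.get(cat, ())
            if len(vals) < 2:
                raise RegistryConfigError(
                    f"category '{cat.value}' must define at least 2 canonical values, "
                    f"found {len(vals)}"
                )
            seen: set[str] = set()
            for val in vals:
                if val.label in seen:
                    raise RegistryConfigError(
                        f"duplicate label '{val.label}' in category '{cat.value}'"
                    )
                seen.add(val.label)
                if not val.comparison_string or not (
                    set(val.comparison_string) & _SCHEME_SET
                ):
                    raise RegistryConfigError(
                        f"comparison string for '{val.label}' in category "
                        f"'{cat.value}' contains no scheme character"
                    )
        if Category.UNCLASSIFIED in self._entries:
            raise RegistryConfigError("UNCLASSIFIED cannot hold canonical values")

    # -- access ---------------------------------------------------------------

    @property
    def categories(self) -> tuple[Category, ...]:
        return CATEGORY_ORDER

    def values_for(self, category: Category) -> tuple[CanonicalValue, ...]:
        """Canonical values of a category, in configured order."""
        try:
            return self._entries[category]
        except KeyError:
            raise RegistryLookupError(f"no value set for category '{category.value}'")

    def triggers_for(self, category: Category) -> frozenset[str]:
        """The normalized trigger lexicon of a category."""
        return self._triggers.get(category, frozenset())

    def get(self, category: Category, label: str) -> CanonicalValue:
        """Canonical value by (category, label), or ``RegistryLookupError``."""
        try:
            return self._by_label[(category, _norm(label))]
        except KeyError:
            raise RegistryLookupError(
                f"label '{label}' not in category '{category.value}'"
            )

    def lookup_snomed(self, value: CanonicalValue) -> str | None:
        """SNOMED CT concept identifier of a registry value (None if unmapped)."""
        member = self._by_label.get((value.category, value.label))
        if member is None or member != value:
            raise RegistryLookupError(
                f"value '{value.label}' ({value.category.value}) is not in this registry"
            )
        return member.snomed_id

    # -- serialization --------------------------------------------------------

    def to_config(self) -> dict:
        """Config-schema dict; ``load_registry`` round-trips it losslessly."""
        out: dict = {}
        for cat in CATEGORY_ORDER:
            vals = self._entries[cat]
            owned = {
                v.label: [
                    t
                    for t in self._trigger_map.get((cat, v.label), ())
                    if t in self._triggers[cat]
                ]
                for v in vals
            }
            claimed = {t for ts in owned.values() for t in ts}
            leftovers = sorted(self._triggers[cat] - claimed)
            entries = []
            for j, val in enumerate(vals):
                trigs = list(dict.fromkeys(owned[val.label]))
                if j == 0:
                    trigs.extend(leftovers)
                entry: dict = {"label": val.label}
                if val.snomed_id is not None:
                    entry["snomed_id"] = val.snomed_id
                entry["comparison_string"] = val.comparison_string
                entry["triggers"] = trigs
                entries.append(entry)
            out[cat.value] = entries
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_config(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ValueSetRegistry):
            return NotImplemented
        return self._entries == other._entries and self._triggers == other._triggers


def _parse_entry(cat: Category, raw: object, index: int) -> tuple[CanonicalValue, list[str]]:
    where = f"category '{cat.value}', entry {index + 1}"
    if not isinstance(raw, Mapping):
        raise RegistryConfigError(f"{where}: expected a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _ENTRY_FIELDS
    if unknown:
        raise RegistryConfigError(f"{where}: unknown field(s) {sorted(unknown)}")
    if "label" not in raw or raw["label"] is None:
        raise RegistryConfigError(f"{where}: missing required field 'label'")
    label = _norm(str(raw["label"]))
    if not label:
        raise RegistryConfigError(f"{where}: label is empty after normalization")
    snomed = raw.get("snomed_id")
    snomed_id = None if snomed is None else str(snomed)
    comparison = raw.get("comparison_string")
    comparison_string = _norm(str(comparison)) if comparison is not None else label
    triggers = raw.get("triggers", [label])
    if not isinstance(triggers, list) or not all(isinstance(t, str) for t in triggers):
        raise RegistryConfigError(f"{where}: 'triggers' must be a list of strings")
    value = CanonicalValue(
        label=label,
        category=cat,
        comparison_string=comparison_string,
        snomed_id=snomed_id,
    )
    return value, [_norm(t) for t in triggers]


def load_registry(source: str | Path | Mapping | None = None) -> ValueSetRegistry:
    """Load a value-set registry from a YAML/JSON file, a dict, or the default.

    With ``source=None`` the packaged default value sets are loaded. Loading is
    all-or-nothing: any malformed or unknown entry raises
    ``RegistryConfigError`` naming the offending entry and no partial registry
    is produced.
    """
    if source is None:
        text = (
            resources.files("saltc").joinpath("data/default_valuesets.yaml").read_text("utf-8")
        )
        data = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        data = source
    else:
        path = Path(source)
        try:
            data = yaml.safe_load(path.read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise RegistryConfigError(f"cannot parse '{path}': {exc}") from exc
    if not isinstance(data, Mapping):
        raise RegistryConfigError("value-set config must be a mapping of category -> entries")

    by_value = {c.value: c for c in CATEGORY_ORDER}
    entries: dict[Category, list[CanonicalValue]] = {c: [] for c in CATEGORY_ORDER}
    triggers: dict[Category, list[str]] = {c: [] for c in CATEGORY_ORDER}
    trigger_map: dict[tuple[Category, str], tuple[str, ...]] = {}
    for cat_name, raw_entries in data.items():
        cat = by_value.get(str(cat_name))
        if cat is None:
            raise RegistryConfigError(f"unknown category '{cat_name}'")
        if not isinstance(raw_entries, list):
            raise RegistryConfigError(
                f"category '{cat_name}': expected a list of entries"
            )
        for i, raw in enumerate(raw_entries):
            value, trigs = _parse_entry(cat, raw, i)
            entries[cat].append(value)
            triggers[cat].extend(trigs)
            trigger_map[(cat, value.label)] = tuple(trigs)

    registry = ValueSetRegistry(entries, triggers)
    registry._trigger_map = trigger_map
    return registry


def lookup_snomed(registry: ValueSetRegistry, value: CanonicalValue) -> str | None:
    """Module-level convenience wrapper around ``registry.lookup_snomed``."""
    return registry.lookup_snomed(value)
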