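"""Liver-toxicity screening over structured findings.

Opinions name the same liver parameter many ways (alanine aminotransferase /
serum glutamate-pyruvate transaminase / SGPT / GPT / ALAT / ALT) and the
same observation with different verbs (increase / raise / higher).  This
module normalizes both sides through a data-shipped lexicon so that
synonym-equivalent queries return identical hit sets.

Direction semantics: an entry printed "Increase/decrease" is its own
``mixed`` direction (not double-counted as both).  A query direction of
``increase`` matches increase *and* mixed; ``pure_increase`` matches
increase only.  Qualifier flags (incidental, dermal, human, ...) transcribe
the source table's footnotes; the default query excludes nothing, and
callers opt in to exclusions explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import yaml

from .errors import ProfileError

QUALIFIER_FLAGS = {
    "doubtful_or_unrelated",
    "not_histopath_supported",
    "incidental",
    "dermal",
    "human",
    "method_interference",
    "sccs_conclusion_only",
    "adaptive_compensatory",
    "non_OECD",
    "inhalation",
}

DIRECTIONS = ("increase", "decrease", "change", "mixed")
QUERY_DIRECTIONS = ("increase", "decrease", "change", "mixed", "any", "pure_increase")

#: which entry directions each query direction matches
_DIRECTION_MATCH = {
    "any": frozenset(DIRECTIONS),
    "increase": frozenset({"increase", "mixed"}),
    "decrease": frozenset({"decrease", "mixed"}),
    "change": frozenset({"change"}),
    "mixed": frozenset({"mixed"}),
    "pure_increase": frozenset({"increase"}),
}


@dataclass(frozen=True)
class EffectEntry:
    """One compound x parameter finding with direction and qualifier flags."""

    compound_id: str
    parameter: str
    direction: str
    qualifiers: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ProfileError(f"unknown direction {self.direction!r}")
        unknown = set(self.qualifiers) - QUALIFIER_FLAGS
        if unknown:
            raise ProfileError(f"unknown qualifier flags {sorted(unknown)}")


class ParameterLexicon:
    """Case-insensitive synonym -> canonical parameter lookup."""

    def __init__(self, parameters: list[dict], directions: dict[str, list[str]]):
        self.canonicals: list[str] = []
        self.ec_numbers: dict[str, str] = {}
        self._lookup: dict[str, str] = {}
        for entry in parameters:
            canonical = entry["canonical"]
            self.canonicals.append(canonical)
            if entry.get("ec_number"):
                self.ec_numbers[canonical] = entry["ec_number"]
            for term in [canonical, *entry.get("synonyms", ())]:
                key = term.strip().lower()
                owner = self._lookup.get(key)
                if owner is not None and owner != canonical:
                    raise ProfileError(
                        f"synonym {term!r} claimed by both {owner!r} and {canonical!r}"
                    )
                self._lookup[key] = canonical
        self._directions: dict[str, str] = {}
        for direction, terms in directions.items():
            if direction not in DIRECTIONS:
                raise ProfileError(f"unknown direction class {direction!r}")
            for term in terms:
                self._directions[term.strip().lower()] = direction

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterLexicon":
        return cls(data.get("parameters", ()), data.get("directions", {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterLexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def builtin(cls) -> "ParameterLexicon":
        text = (resources.files("toxinkg") / "data" / "liver_lexicon.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def normalize_parameter(self, term: str) -> str | None:
        """Canonical token for *term*, or None when the term is unknown."""
        if term is None:
            return None
        return self._lookup.get(str(term).strip().lower())

    def normalize_direction(self, term: str) -> str | None:
        """Map a direction keyword (or a compound "a/b" token) to its class."""
        if term is None:
            return None
        text = str(term).strip().lower()
        if "/" in text:
            parts = [self._directions.get(p.strip()) for p in text.split("/") if p.strip()]
            if None in parts or not parts:
                return None
            kinds = set(parts)
            if kinds == {"increase", "decrease"}:
                return "mixed"
            return kinds.pop() if len(kinds) == 1 else "mixed"
        return self._directions.get(text)


_DEFAULT_LEXICON: ParameterLexicon | None = None


def default_lexicon() -> ParameterLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = ParameterLexicon.builtin()
    return _DEFAULT_LEXICON


def normalize_parameter(term: str, lexicon: ParameterLexicon | None = None) -> str | None:
    return (lexicon or default_lexicon()).normalize_parameter(term)


def normalize_direction(term: str, lexicon: ParameterLexicon | None = None) -> str | None:
    return (lexicon or default_lexicon()).normalize_direction(term)


# -- querying ------------------------------------------------------------


@dataclass(frozen=True)
class FilterQuery:
    """A liver-toxicant search: parameter (canonical or synonym; None = any
    liver parameter), direction class, and qualifier flags to exclude."""

    parameter: str | None = None
    direction: str = "any"
    exclude_qualifiers: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.direction not in QUERY_DIRECTIONS:
            raise ProfileError(f"unknown query direction {self.direction!r}")
        unknown = set(self.exclude_qualifiers) - QUALIFIER_FLAGS
        if unknown:
            raise ProfileError(f"unknown qualifier flags {sorted(unknown)}")


@dataclass
class FilterHit:
    compound_id: str
    ingredient_name: str
    entries: list[EffectEntry] = dc_field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "ingredient_name": self.ingredient_name,
            "entries": [
                {
                    "parameter": e.parameter,
                    "direction": e.direction,
                    "qualifiers": sorted(e.qualifiers),
                    "source": e.source,
                }
                for e in self.entries
            ],
        }


def _matches(entry: EffectEntry, q: FilterQuery, canonical_param: str | None) -> bool:
    if entry.qualifiers & q.exclude_qualifiers:
        return False
    if canonical_param is not None and entry.parameter != canonical_param:
        return False
    return entry.direction in _DIRECTION_MATCH[q.direction]


def query(dataset, q: FilterQuery, lexicon: ParameterLexicon | None = None) -> list[FilterHit]:
    """Distinct compounds with at least one matching effect entry.

    Hits are ordered deterministically by ingredient name (case-insensitive,
    compound id as tie-break); each hit lists every matched entry.
    """
    lexicon = lexicon or default_lexicon()
    canonical = None
    if q.parameter is not None:
        canonical = lexicon.normalize_parameter(q.parameter)
        if canonical is None:
            return []
    names = {c.compound_id: c.ingredient_name for c in dataset.compounds}
    hits: dict[str, FilterHit] = {}
    for entry in dataset.effects:
        if _matches(entry, q, canonical):
            hit = hits.setdefault(
                entry.compound_id,
                FilterHit(entry.compound_id, names.get(entry.compound_id, entry.compound_id)),
            )
            hit.entries.append(entry)
    return sorted(hits.values(), key=lambda h: (h.ingredient_name.lower(), h.compound_id))


def group_by_shared_effect(
    dataset,
    parameter: str,
    direction: str = "any",
    exclude_qualifiers: frozenset[str] = frozenset(),
    lexicon: ParameterLexicon | None = None,
) -> list[FilterHit]:
    """Compounds sharing one (parameter, direction) effect — the grouping
    used to seed structure-activity comparisons.  Membership equals the
    corresponding query hit set by construction."""
    return query(
        dataset,
        FilterQuery(parameter=parameter, direction=direction,
                    exclude_qualifiers=frozenset(exclude_qualifiers)),
        lexicon,
    )
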