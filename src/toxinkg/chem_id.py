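"""Chemical identity services.

Canonical SMILES give each ingredient a unique structure key (delegated to
RDKit's canonicalization behind a small contract); Morgan-fragment feature
sets feed a set-based Dice similarity, 2|A∩B|/(|A|+|B|), whose 0.5
threshold assigns preliminary structural-alert categories for repeated-dose
liver toxicity; and a punctuation-tolerant name index supports the
proportional ("show everything containing 'yellow'") and hard-threshold
search modes needed to cope with naming variants like "HC Blue No. 15" /
"HC Blue No.15".
"""

from __future__ import annotations

import difflib
import math
import re
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import (
    SmilesParseError,
    UndefinedSimilarityError,
    UnsupportedStructureError,
)
from .study_model import cas_checksum_ok  # noqa: F401  (re-exported identity check)

RDLogger.DisableLog("rdApp.*")

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def canonicalize(smiles: str, is_polymer: bool = False) -> str:
    """Return the canonical SMILES for *smiles*.

    Idempotent; two SMILES of the same molecule map to the same string.
    Polymer-flagged structures are rejected (no meaningful small-molecule
    canonical form).
    """
    if is_polymer:
        raise UnsupportedStructureError(
            "polymer ingredients have no canonical SMILES representation"
        )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol, canonical=True)


@dataclass(frozen=True)
class FingerprintSet:
    """A set of discrete structural feature keys (hashed fragments)."""

    features: frozenset[int]

    @classmethod
    def from_smiles(cls, smiles: str) -> "FingerprintSet":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(smiles)
        fp = _MORGAN.GetSparseCountFingerprint(mol)
        return cls(frozenset(fp.GetNonzeroElements()))

    @classmethod
    def of(cls, features) -> "FingerprintSet":
        return cls(frozenset(features))

    def __len__(self) -> int:
        return len(self.features)


def dice(a: FingerprintSet, b: FingerprintSet) -> float:
    """Set-based Dice similarity 2|A∩B|/(|A|+|B|); symmetric, in [0, 1]."""
    if not a.features and not b.features:
        raise UndefinedSimilarityError("Dice similarity undefined for two empty sets")
    return 2 * len(a.features & b.features) / (len(a.features) + len(b.features))


@dataclass(frozen=True)
class AlertAssignment:
    alert: str
    similarity: float
    note: str = "preliminary indicator"

    def to_json_dict(self) -> dict:
        return {"alert": self.alert, "similarity": round(self.similarity, 4),
                "note": self.note}


ALERT_THRESHOLD = 0.5


def assign_alert(
    target: FingerprintSet,
    alert_profiles: dict[str, FingerprintSet],
    threshold: float = ALERT_THRESHOLD,
) -> list[AlertAssignment]:
    """Alerts whose profile reaches *threshold* Dice similarity (inclusive).

    Sorted by descending similarity, alert name as tie-break, so the output
    is stable under any insertion order of *alert_profiles*.  Assignments
    are preliminary indicators, not toxicological conclusions.
    """
    hits = []
    for name in sorted(alert_profiles):
        similarity = dice(target, alert_profiles[name])
        if similarity >= threshold:
            hits.append(AlertAssignment(name, similarity))
    return sorted(hits, key=lambda h: (-h.similarity, h.alert))


class QSARToolboxAdapter:
    """Interface stub for a live structure-profiler service.

    A conforming adapter maps a canonical SMILES to named alert fingerprint
    profiles (``profiles(smiles) -> dict[str, FingerprintSet]``).  The
    shipped implementation is offline: callers supply profile fixtures
    directly (see :func:`alert_profiles_from_smiles`).
    """

    def profiles(self, smiles: str) -> dict[str, FingerprintSet]:
        raise NotImplementedError(
            "no live profiler service is wired in; supply alert profiles "
            "via alert_profiles_from_smiles() or a custom adapter"
        )


def alert_profiles_from_smiles(profiles: dict[str, list[str]]) -> dict[str, FingerprintSet]:
    """Build alert fingerprint profiles from exemplar SMILES lists
    (union of each exemplar's feature set)."""
    out: dict[str, FingerprintSet] = {}
    for alert, smileses in profiles.items():
        features: set[int] = set()
        for s in smileses:
            features |= FingerprintSet.from_smiles(s).features
        out[alert] = FingerprintSet.of(features)
    return out


# -- name search ---------------------------------------------------------

_PUNCT = re.compile(r"[.,;:'’()\[\]\-_/]+")
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Lowercase, fold punctuation variants ("No." / "No" / "No.15"),
    collapse whitespace.  Idempotent."""
    text = _PUNCT.sub(" ", str(name).lower())
    tokens = [t for t in _WS.split(text) if t and t != "no"]
    return " ".join(tokens)


@dataclass
class NameIndex:
    """Normalized ingredient-name -> compound-id index."""

    entries: dict[str, str] = field(default_factory=dict)
    display: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "NameIndex":
        index = cls()
        for name, compound_id in pairs:
            index.add(name, compound_id)
        return index

    @classmethod
    def from_dataset(cls, dataset) -> "NameIndex":
        index = cls()
        for compound in dataset.compounds:
            index.add(compound.ingredient_name, compound.compound_id)
            if compound.inci_name:
                index.add(compound.inci_name, compound.compound_id)
        return index

    def add(self, name: str, compound_id: str) -> None:
        key = normalize_name(name)
        self.entries[key] = compound_id
        self.display.setdefault(key, name)


@dataclass(frozen=True)
class NameMatch:
    compound_id: str
    name: str
    score: float

    def to_json_dict(self) -> dict:
        return {"compound_id": self.compound_id, "name": self.name,
                "score": round(self.score, 4)}


def search_names(
    index: NameIndex,
    query: str,
    mode: str = "proportional",
    threshold: float = 0.25,
) -> list[NameMatch]:
    """Rank indexed names against *query*.

    ``proportional`` mode retains the best-scoring fraction *threshold* of
    the index — plus every substring match, so a query like "yellow"
    surfaces each ingredient with "yellow" in its name.  ``hard`` mode
    retains entries whose similarity reaches *threshold* (e.g. 0.95).
    Invariant to case and to "No."-style punctuation variants.
    """
    q = normalize_name(query)
    scored: list[NameMatch] = []
    for key, compound_id in index.entries.items():
        ratio = difflib.SequenceMatcher(None, q, key).ratio()
        substring = bool(q) and q in key
        score = 1.0 if key == q else (max(ratio, 0.5 + ratio / 2) if substring else ratio)
        scored.append(NameMatch(compound_id, index.display[key], score))
    scored.sort(key=lambda m: (-m.score, m.name.lower()))

    if mode == "hard":
        return [m for m in scored if m.score >= threshold]
    if mode == "proportional":
        keep = math.ceil(threshold * len(scored))
        top = scored[:keep]
        substr = [
            m for m in scored
            if q and q in normalize_name(m.name) and m not in top
        ]
        return top + substr
    raise ValueError(f"unknown search mode {mode!r}")
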