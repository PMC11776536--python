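"""Guideline-profiled domain model for curated toxicity studies.

An OECD test guideline is decomposed ("guideline profiling") into a tree of
*concepts* — structural nodes written with a leading capital, at most three
levels deep — whose leaves carry *value properties*: typed, lowercase data
fields with optional units (e.g. ``dose-volume ml/kg bw``).  Curated study
records address fields by slash-delimited concept paths; a literal ``/``
inside a property name (units such as ``ml/kg bw``) is escaped as ``\\/`` in
the serialized form.

Profiles ship as YAML data files, one per guideline, so adding an endpoint
(toxicokinetics, skin absorption, ...) never requires code changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Union

import yaml

from .errors import PathResolutionError, ProfileError

VALUE_TYPES = {"boolean", "numeric", "text", "enum"}
BOOLEAN_VALUES = ["YES", "NO"]

_SPLIT_RE = re.compile(r"(?<!\\)/")


def split_path(path: str) -> list[str]:
    """Split a slash-delimited path, honouring ``\\/`` escapes."""
    return [seg.replace("\\/", "/") for seg in _SPLIT_RE.split(path)]


def join_path(segments: list[str]) -> str:
    """Inverse of :func:`split_path` (escapes literal slashes)."""
    return "/".join(seg.replace("/", "\\/") for seg in segments)


@dataclass(frozen=True)
class ValueProperty:
    """A typed data field attached to a concept node."""

    name: str
    value_type: str = "text"
    unit: str = ""
    allowed_values: tuple[str, ...] = ()

    def __post_init__(self):
        if self.name != self.name.lower():
            raise ProfileError(f"value property names are lowercase: {self.name!r}")
        if self.value_type not in VALUE_TYPES:
            raise ProfileError(f"unknown value type {self.value_type!r} for {self.name!r}")
        if self.value_type == "boolean":
            object.__setattr__(self, "allowed_values", tuple(BOOLEAN_VALUES))
        if self.value_type == "enum" and not self.allowed_values:
            raise ProfileError(f"enum property {self.name!r} declares no allowed values")

    def check_value(self, value) -> str | None:
        """Return a violation message for *value*, or None if it conforms."""
        if self.value_type == "numeric":
            try:
                float(value)
            except (TypeError, ValueError):
                return f"expected a numeric value, got {value!r}"
        elif self.value_type in ("boolean", "enum"):
            if str(value) not in self.allowed_values:
                allowed = "/".join(self.allowed_values)
                return f"value {value!r} not in {{{allowed}}}"
        return None


@dataclass
class ConceptNode:
    """A structural node in the profile tree (no data value of its own)."""

    name: str
    level: int = 1
    children: list["ConceptNode"] = field(default_factory=list)
    value_properties: list[ValueProperty] = field(default_factory=list)

    def __post_init__(self):
        if not self.name or not self.name[0].isupper():
            raise ProfileError(f"concept names start with a capital letter: {self.name!r}")
        if not 1 <= self.level <= 3:
            raise ProfileError(f"concept {self.name!r}: level {self.level} outside 1..3")
        seen: set[str] = set()
        for child in self.children:
            key = child.name.lower()
            if key in seen:
                raise ProfileError(f"concept {self.name!r} has duplicate child {child.name!r}")
            seen.add(key)


Node = Union[ConceptNode, ValueProperty]


@dataclass
class GuidelineProfile:
    """The concept/value-property tree for one OECD test guideline."""

    guideline_id: str
    endpoint: str
    study_kind: str = "repeated_dose"  # or "acute"
    root_concepts: list[ConceptNode] = field(default_factory=list)
    defaults: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for path in self.defaults:
            node = self.resolve(path)
            if not isinstance(node, ValueProperty):
                raise ProfileError(f"default path {path!r} is not a value property")

    # -- resolution ------------------------------------------------------

    def resolve(self, path: str) -> Node:
        """Resolve a slash-delimited path to its declared node.

        Matching is case-insensitive on input; the stored canonical names
        (capitalized concepts, lowercase properties) are authoritative.
        """
        segments = split_path(path)
        level: list[Node] = list(self.root_concepts)
        node: Node | None = None
        for seg in segments:
            match = next((n for n in level if n.name.lower() == seg.lower()), None)
            if match is None:
                raise PathResolutionError(path, seg, [n.name for n in level])
            node = match
            if isinstance(node, ConceptNode):
                level = list(node.children) + list(node.value_properties)
            else:
                level = []
        assert node is not None
        return node

    def canonical_path(self, path: str) -> str:
        """Return *path* rewritten with the declared canonical segment names."""
        segments = split_path(path)
        out: list[str] = []
        level: list[Node] = list(self.root_concepts)
        for seg in segments:
            match = next((n for n in level if n.name.lower() == seg.lower()), None)
            if match is None:
                raise PathResolutionError(path, seg, [n.name for n in level])
            out.append(match.name)
            level = (
                list(match.children) + list(match.value_properties)
                if isinstance(match, ConceptNode)
                else []
            )
        return join_path(out)

    def iter_properties(self) -> Iterator[tuple[str, ValueProperty]]:
        """Yield (canonical path, property) for every value property."""

        def walk(node: ConceptNode, prefix: list[str]):
            here = prefix + [node.name]
            for vp in node.value_properties:
                yield join_path(here + [vp.name]), vp
            for child in node.children:
                yield from walk(child, here)

        for root in self.root_concepts:
            yield from walk(root, [])

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "GuidelineProfile":
        def build(node: dict, level: int) -> ConceptNode:
            props = [
                ValueProperty(
                    name=p["name"],
                    value_type=p.get("type", "text"),
                    unit=p.get("unit", ""),
                    allowed_values=tuple(p.get("allowed_values", ())),
                )
                for p in node.get("properties", ())
            ]
            children = [build(c, level + 1) for c in node.get("concepts", ())]
            return ConceptNode(node["name"], level, children, props)

        return cls(
            guideline_id=data["guideline_id"],
            endpoint=data.get("endpoint", ""),
            study_kind=data.get("study_kind", "repeated_dose"),
            root_concepts=[build(c, 1) for c in data.get("concepts", ())],
            defaults=dict(data.get("defaults", {})),
        )

    def to_dict(self) -> dict:
        def dump(node: ConceptNode) -> dict:
            out: dict = {"name": node.name}
            if node.value_properties:
                out["properties"] = []
                for vp in node.value_properties:
                    p: dict = {"name": vp.name}
                    if vp.value_type != "text":
                        p["type"] = vp.value_type
                    if vp.unit:
                        p["unit"] = vp.unit
                    if vp.value_type == "enum":
                        p["allowed_values"] = list(vp.allowed_values)
                    out["properties"].append(p)
            if node.children:
                out["concepts"] = [dump(c) for c in node.children]
            return out

        return {
            "guideline_id": self.guideline_id,
            "endpoint": self.endpoint,
            "study_kind": self.study_kind,
            "concepts": [dump(c) for c in self.root_concepts],
            "defaults": dict(self.defaults),
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GuidelineProfile":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)


def resolve_path(profile: GuidelineProfile, path: str) -> Node:
    """Module-level convenience wrapper around :meth:`GuidelineProfile.resolve`."""
    return profile.resolve(path)


# -- study & compound records -------------------------------------------


@dataclass
class ReliabilityBlock:
    """Study-credibility fields kept outside the guideline tree.

    ``own_comments`` records curator observations and never participates in
    scoring (provenance only).
    """

    sccs_comments: str = ""
    study_year: int | None = None
    glp_status: bool | None = None
    ref_in_dossier: str = ""
    additional_information: str = ""
    own_comments: str = ""
    control_recovery_group: str | None = None


NON_OECD = "non-OECD"
PROVENANCE_KINDS = {"paper", "default", "expert"}


@dataclass
class StudyRecord:
    """One toxicity study: a path->value field map plus provenance."""

    study_id: str
    compound_id: str
    guideline_id: str = NON_OECD
    fields: dict[str, object] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    reliability: ReliabilityBlock = field(default_factory=ReliabilityBlock)
    conflicts: list[str] = field(default_factory=list)

    @property
    def is_oecd(self) -> bool:
        return self.guideline_id != NON_OECD

    def get(self, path: str, default=None):
        """Case-insensitive field lookup by canonical-or-lax path."""
        if path in self.fields:
            return self.fields[path]
        low = path.lower()
        for key, value in self.fields.items():
            if key.lower() == low:
                return value
        return default


CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def cas_checksum_ok(cas: str) -> bool:
    """Validate a CAS registry number against its check digit."""
    m = CAS_RE.match(cas.strip())
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    total = sum((i + 1) * int(d) for i, d in enumerate(digits))
    return total % 10 == int(m.group(3))


USE_CATEGORIES = {
    "hair dye",
    "preservative/disinfectant",
    "UV filter",
    "fragrance",
    "solvent",
    "multiple",
    "other",
}


@dataclass
class CompoundRecord:
    """Identity record for one cosmetic ingredient."""

    compound_id: str
    ingredient_name: str
    inci_name: str = ""
    cas_number: str = ""
    ec_number: str = ""
    smiles: str = ""
    canonical_smiles: str = ""
    use_category: str = "other"
    function: str = ""
    is_polymer: bool = False
    is_placeholder: bool = False

    def __post_init__(self):
        if self.use_category not in USE_CATEGORIES:
            raise ProfileError(
                f"{self.compound_id}: unknown use category {self.use_category!r}"
            )
        if self.is_polymer and self.canonical_smiles:
            raise ProfileError(
                f"{self.compound_id}: polymers cannot carry a canonical SMILES"
            )


# -- validation ----------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One rule violation found while validating a record (reported, not raised)."""

    study_id: str
    path: str
    kind: str  # unknown-path | type | enum | reference | uniqueness | conflict | parameter
    message: str

    def to_json_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "path": self.path,
            "kind": self.kind,
            "message": self.message,
        }


class ProfileRegistry:
    """Registry of guideline profiles keyed by guideline id."""

    def __init__(self, profiles: list[GuidelineProfile] = ()):
        self._profiles: dict[str, GuidelineProfile] = {}
        for profile in profiles:
            self.register(profile)

    def register(self, profile: GuidelineProfile) -> None:
        self._profiles[profile.guideline_id] = profile

    def get(self, guideline_id: str) -> GuidelineProfile | None:
        return self._profiles.get(guideline_id)

    def __contains__(self, guideline_id: str) -> bool:
        return guideline_id in self._profiles

    def ids(self) -> list[str]:
        return sorted(self._profiles)

    @classmethod
    def builtin(cls) -> "ProfileRegistry":
        """Registry of the shipped profiles (90-day oral RDT and acute oral)."""
        reg = cls()
        pkg = resources.files("toxinkg") / "data" / "profiles"
        for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
            if entry.name.endswith((".yaml", ".yml")):
                reg.register(GuidelineProfile.from_dict(yaml.safe_load(entry.read_text())))
        return reg


def validate_record(
    record: StudyRecord, profile: GuidelineProfile | ProfileRegistry | None
) -> list[Violation]:
    """Check a study record against its guideline profile.

    Returns an empty list iff every field path resolves and every value
    matches its declared type.  Records without an OECD guideline are checked
    only for coherence of the generic reliability block.  Idempotent and
    side-effect free.
    """
    violations: list[Violation] = []
    rel = record.reliability
    if rel.study_year is not None and not isinstance(rel.study_year, int):
        violations.append(
            Violation(record.study_id, "reliability/study year", "type",
                      f"study year must be an integer, got {rel.study_year!r}")
        )
    if rel.glp_status is not None and not isinstance(rel.glp_status, bool):
        violations.append(
            Violation(record.study_id, "reliability/glp status", "type",
                      f"GLP status must be boolean, got {rel.glp_status!r}")
        )

    if not record.is_oecd:
        return violations

    if isinstance(profile, ProfileRegistry):
        profile = profile.get(record.guideline_id)
    if profile is None:
        violations.append(
            Violation(record.study_id, "", "reference",
                      f"guideline {record.guideline_id!r} is not registered")
        )
        return violations

    for path, value in record.fields.items():
        try:
            node = profile.resolve(path)
        except PathResolutionError as err:
            violations.append(Violation(record.study_id, path, "unknown-path", str(err)))
            continue
        if not isinstance(node, ValueProperty):
            violations.append(
                Violation(record.study_id, path, "unknown-path",
                          "path names a concept, not a value property")
            )
            continue
        values = value if isinstance(value, (list, tuple)) else [value]
        for v in values:
            msg = node.check_value(v)
            if msg:
                kind = "enum" if node.value_type in ("enum", "boolean") else "type"
                violations.append(Violation(record.study_id, path, kind, msg))
    return violations
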