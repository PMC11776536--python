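"""RDF knowledge-graph construction, linking and rule-based inference.

The curated dataset is mapped to RDF quads by declarative, R2RML-inspired
rules (data, not code).  Provenance is kept by named-graph separation:

* ``internal``        — quads derived from the curated dataset only
* ``ontology``        — the loaded ontology fixture
* ``external_links``  — ``owl:sameAs`` links from normalized-label matches
* ``inferred``        — "is affected by" links derived by reasoning

"sameAs" asserts linguistic identity (case-insensitive, whitespace-collapsed
label equality).  "is affected by" is inferred by counting effects shared
between a test subject's observations and a disease/toxic-process effect
profile, where subtypes inherit their ancestors' effects through the is_a
hierarchy; the shared count is kept on the link as likelihood evidence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from rdflib import Dataset as RDFDataset
from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import MappingError
from .ingest import Dataset

TOX = Namespace("https://toxinkg.example.org/")
TOXV = Namespace("https://toxinkg.example.org/vocab/")
ONT = Namespace("https://toxinkg.example.org/ontology/vocab/")

GRAPH_NAMES = ("internal", "ontology", "external_links", "inferred")

_PREFIXES = {
    "tox": TOX,
    "toxv": TOXV,
    "ont": ONT,
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
}


def _slug(text: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", str(text).lower()).strip("-")


def _norm_label(text: str) -> str:
    return re.sub(r"\s+", " ", str(text)).strip().lower()


class KGraph:
    """A quad store with fixed named graphs and deterministic IRI minting."""

    def __init__(self):
        self.store = RDFDataset(default_union=True)
        for prefix, ns in _PREFIXES.items():
            self.store.bind(prefix, ns)
        self._graphs = {
            name: self.store.graph(TOX[f"graph/{name}"]) for name in GRAPH_NAMES
        }

    def graph(self, name: str) -> Graph:
        return self._graphs[name]

    def add(self, s, p, o, graph: str = "internal") -> None:
        self._graphs[graph].add((s, p, o))

    def quads(self) -> set:
        return {
            (s, p, o, getattr(g, "identifier", g))
            for s, p, o, g in self.store.quads((None, None, None, None))
        }

    def __len__(self) -> int:
        return len(self.quads())

    # -- serialization ---------------------------------------------------

    def serialize(self, fmt: str = "trig") -> str:
        """TriG or N-Quads text; N-Quads lines are sorted for diffability."""
        if fmt == "nquads":
            text = self.store.serialize(format="nquads")
            lines = sorted(line for line in text.splitlines() if line.strip())
            return "\n".join(lines) + "\n"
        return self.store.serialize(format=fmt)

    @classmethod
    def parse(cls, text: str, fmt: str = "trig") -> "KGraph":
        kg = cls()
        kg.store.parse(data=text, format=fmt)
        # re-register any named graphs present in the parsed data
        for name in GRAPH_NAMES:
            kg._graphs[name] = kg.store.graph(TOX[f"graph/{name}"])
        return kg

    # -- invariants ------------------------------------------------------

    def check_graph_separation(self) -> None:
        """No link/inference predicate may appear in the internal graph."""
        internal = self.graph("internal")
        for predicate in (OWL.sameAs, TOXV.isAffectedBy):
            if next(internal.triples((None, predicate, None)), None) is not None:
                raise MappingError(
                    f"link predicate {predicate} leaked into the internal graph"
                )


# -- IRI minting ---------------------------------------------------------


def compound_iri(compound) -> URIRef:
    """Compounds are keyed by CAS when present, else the slugged name."""
    if getattr(compound, "cas_number", ""):
        return TOX[f"compound/cas-{compound.cas_number}"]
    key = getattr(compound, "compound_id", None) or _slug(compound.ingredient_name)
    return TOX[f"compound/{key}"]


# -- mapping rules -------------------------------------------------------


@dataclass(frozen=True)
class MappingRule:
    """One declarative row -> quad rule."""

    source: str
    subject_template: str
    predicate: str
    object_spec: dict
    datatype: str = "string"


def _expand_curie(curie: str, namespaces: dict[str, str]) -> URIRef:
    if ":" in curie:
        prefix, local = curie.split(":", 1)
        if prefix in namespaces and not local.startswith("//"):
            return URIRef(namespaces[prefix] + local)
    return URIRef(curie)


def load_mapping_rules(path: str | Path | None = None) -> tuple[list[MappingRule], dict]:
    if path is None:
        text = (resources.files("toxinkg") / "data" / "kg_mapping.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    namespaces = dict(data.get("namespaces", {}))
    rules = [
        MappingRule(
            source=r["source"],
            subject_template=r["subject"],
            predicate=r["predicate"],
            object_spec=dict(r["object"]),
            datatype=r.get("object", {}).get("datatype", "string"),
        )
        for r in data["rules"]
    ]
    return rules, namespaces


def load_effect_alignment(path: str | Path | None = None) -> dict[tuple[str, str], dict]:
    if path is None:
        text = (resources.files("toxinkg") / "data" / "effect_alignment.yaml").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return {
        (a["parameter"], a["direction"]): {"token": a["token"], "label": a["label"]}
        for a in data["alignments"]
    }


def effect_token(parameter: str, direction: str, alignment=None) -> tuple[str, str]:
    """(token, label) for a finding; unaligned combinations get generated ones."""
    alignment = alignment if alignment is not None else load_effect_alignment()
    hit = alignment.get((parameter, direction))
    if hit:
        return hit["token"], hit["label"]
    return f"{direction}-{_slug(parameter)}", f"{direction} {parameter}"


def _source_rows(dataset: Dataset, alignment) -> dict[str, list[dict]]:
    ds = dataset.sorted_copy()
    rows: dict[str, list[dict]] = {
        "compounds": [], "opinions": [], "opinion_links": [],
        "studies": [], "effects": [],
    }
    for c in ds.compounds:
        rows["compounds"].append({
            "compound_id": c.compound_id, "ingredient_name": c.ingredient_name,
            "cas_number": c.cas_number, "use_category": c.use_category,
            "canonical_smiles": c.canonical_smiles,
        })
    for o in ds.opinions:
        rows["opinions"].append({"sccs_number": o.sccs_number, "year": str(o.year)})
        for cid in o.compound_ids:
            rows["opinion_links"].append({"sccs_number": o.sccs_number, "compound_id": cid})
    for s in ds.studies:
        rows["studies"].append({
            "study_id": s.study_id, "compound_id": s.compound_id,
            "guideline_id": s.guideline_id,
        })
    for e in ds.effects:
        token, label = effect_token(e.parameter, e.direction, alignment)
        rows["effects"].append({
            "compound_id": e.compound_id, "parameter": e.parameter,
            "parameter_slug": _slug(e.parameter), "direction": e.direction,
            "effect_token": token, "effect_label": label,
            "qualifier_list": ";".join(sorted(e.qualifiers)),
        })
    return rows


_TEMPLATE_VAR = re.compile(r"\{([^}]+)\}")


def _render(template: str, row: dict, rule: MappingRule) -> str:
    def sub(m):
        key = m.group(1)
        if key not in row:
            raise MappingError(
                f"rule ({rule.source} -> {rule.predicate}): template references "
                f"unknown column {key!r}"
            )
        return str(row[key])

    return _TEMPLATE_VAR.sub(sub, template)


def build(dataset: Dataset, rules: list[MappingRule] | None = None) -> KGraph:
    """Apply the mapping rules to the dataset; all quads land in `internal`.

    Deterministic: the same dataset always yields the same quad set.
    """
    if rules is None:
        rules, namespaces = load_mapping_rules()
    else:
        _, namespaces = load_mapping_rules()
    alignment = load_effect_alignment()
    rows_by_source = _source_rows(dataset, alignment)
    kg = KGraph()
    for rule in rules:
        if rule.source not in rows_by_source:
            raise MappingError(f"rule references unknown source {rule.source!r}")
        predicate = _expand_curie(rule.predicate, namespaces)
        for row in rows_by_source[rule.source]:
            subject = TOX[_render(rule.subject_template, row, rule)]
            spec = rule.object_spec
            if "const_iri" in spec:
                obj = _expand_curie(spec["const_iri"], namespaces)
            elif "iri_template" in spec:
                obj = TOX[_render(spec["iri_template"], row, rule)]
            elif "column" in spec:
                key = spec["column"]
                if key not in row:
                    raise MappingError(
                        f"rule ({rule.source} -> {rule.predicate}): unknown "
                        f"column {key!r}"
                    )
                value = row[key]
                if value is None or str(value) == "":
                    continue
                if spec.get("datatype") == "integer":
                    obj = Literal(int(value), datatype=XSD.integer)
                else:
                    obj = Literal(str(value))
            else:
                raise MappingError(
                    f"rule ({rule.source} -> {rule.predicate}): object spec "
                    f"needs column, const_iri or iri_template"
                )
            kg.add(subject, predicate, obj, "internal")
    return kg


# -- ontology loading and label linking ----------------------------------


def load_ontology(path: str | Path | None = None) -> Graph:
    graph = Graph()
    if path is None:
        text = (resources.files("toxinkg") / "data" / "mini_ontology.ttl").read_text()
        graph.parse(data=text, format="turtle")
    else:
        graph.parse(str(path), format="turtle")
    return graph


def link_same_as(kg: KGraph, ontology: Graph) -> KGraph:
    """Emit one owl:sameAs quad per internal/ontology label match.

    Labels are compared case-insensitively with collapsed whitespace.  All
    ambiguous multi-matches are emitted, with a warning (linking errors are
    treated as noncritical).  Ontology quads are loaded into the `ontology`
    named graph so downstream queries can traverse them.
    """
    onto_graph = kg.graph("ontology")
    for triple in ontology:
        onto_graph.add(triple)

    by_label: dict[str, list[URIRef]] = {}
    for s, o in ontology.subject_objects(RDFS.label):
        by_label.setdefault(_norm_label(o), []).append(s)

    internal = kg.graph("internal")
    for s, o in sorted(internal.subject_objects(RDFS.label)):
        matches = by_label.get(_norm_label(o), [])
        if len(matches) > 1:
            warnings.warn(
                f"label {str(o)!r} matches {len(matches)} ontology entities; "
                "emitting all links",
                stacklevel=2,
            )
        for target in sorted(matches):
            kg.add(s, OWL.sameAs, target, "external_links")
    return kg


# -- effect profiles and inference ---------------------------------------


@dataclass(frozen=True)
class EffectProfile:
    """A disease/toxic process with its is_a-closed adverse-effect tokens."""

    entity: URIRef
    label: str
    effects: frozenset[str]
    own_effects: frozenset[str] = frozenset()


def effect_profiles(ontology: Graph) -> list[EffectProfile]:
    """Extract one profile per toxic process, closing effects over the
    subclass hierarchy (a subtype inherits its ancestors' effects)."""
    own: dict[URIRef, set[str]] = {}
    processes = sorted(ontology.subjects(RDF.type, ONT.ToxicProcess))
    for process in processes:
        own[process] = set()
    for effect, context in ontology.subject_objects(ONT.has_context):
        token = ontology.value(effect, ONT.canonical_token)
        if token is not None and context in own:
            own[context].add(str(token))

    def ancestors(node: URIRef) -> set[URIRef]:
        out, frontier = set(), [node]
        while frontier:
            current = frontier.pop()
            for parent in ontology.objects(current, RDFS.subClassOf):
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out

    profiles = []
    for process in processes:
        closed = set(own[process])
        for ancestor in ancestors(process):
            closed |= own.get(ancestor, set())
        label = ontology.value(process, RDFS.label)
        profiles.append(
            EffectProfile(
                entity=process,
                label=str(label) if label else str(process),
                effects=frozenset(closed),
                own_effects=frozenset(own[process]),
            )
        )
    return profiles


@dataclass(frozen=True)
class InferredLink:
    subject: URIRef
    entity: URIRef
    shared_count: int

    def to_json_dict(self) -> dict:
        return {"subject": str(self.subject), "entity": str(self.entity),
                "shared_count": self.shared_count}


def subject_effect_tokens(kg: KGraph) -> dict[URIRef, set[str]]:
    """Observation effect tokens per test subject (compound) in `internal`."""
    internal = kg.graph("internal")
    tokens: dict[URIRef, set[str]] = {}
    for observation in internal.subjects(RDF.type, TOXV.Observation):
        subject = internal.value(observation, TOXV.subject)
        token = internal.value(observation, TOXV.effectToken)
        if subject is not None and token is not None:
            tokens.setdefault(subject, set()).add(str(token))
    return tokens


def infer_affected_by(
    kg: KGraph,
    profiles: list[EffectProfile] | None = None,
    min_shared: int = 2,
) -> list[InferredLink]:
    """Count effects shared between each test subject and each profile; emit
    an "is affected by" link (with the count as likelihood evidence) into
    the `inferred` graph whenever shared_count >= min_shared."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if profiles is None:
        profiles = effect_profiles(kg.graph("ontology"))
    links: list[InferredLink] = []
    for subject, tokens in sorted(subject_effect_tokens(kg).items()):
        for profile in profiles:
            shared = len(tokens & profile.effects)
            if shared >= min_shared:
                links.append(InferredLink(subject, profile.entity, shared))
                kg.add(subject, TOXV.isAffectedBy, profile.entity, "inferred")
                link_node = TOX[
                    f"inferred/{_slug(str(subject).rsplit('/', 1)[-1])}"
                    f"--{_slug(str(profile.entity).rsplit('/', 1)[-1])}"
                ]
                kg.add(link_node, RDF.type, TOXV.InferredLink, "inferred")
                kg.add(link_node, TOXV.subject, subject, "inferred")
                kg.add(link_node, TOXV.target, profile.entity, "inferred")
                kg.add(
                    link_node, TOXV.sharedEffectCount,
                    Literal(shared, datatype=XSD.integer), "inferred",
                )
    return sorted(links, key=lambda l: (str(l.subject), str(l.entity)))


# -- competency queries --------------------------------------------------

QUERY_KINDS = (
    "q1_effects_to_processes",
    "q2_disease_to_pathways",
    "q3_process_to_gene_products",
)


def _query_text(kind: str) -> str:
    return (resources.files("toxinkg") / "data" / "queries" / f"{kind}.rq").read_text()


def resolve_entity(ontology: Graph, ref: str) -> URIRef | None:
    """Resolve an IRI string or a (case-insensitive) label/altLabel."""
    if ref.startswith("http"):
        iri = URIRef(ref)
        return iri if next(ontology.predicate_objects(iri), None) else None
    wanted = _norm_label(ref)
    SKOS_ALT = URIRef("http://www.w3.org/2004/02/skos/core#altLabel")
    for predicate in (RDFS.label, SKOS_ALT):
        for s, o in ontology.subject_objects(predicate):
            if _norm_label(o) == wanted:
                return s
    return None


def competency_query(kg: KGraph, kind: str, params: dict) -> list[dict]:
    """Run one of the three shipped competency queries.

    * ``q1_effects_to_processes``: params {"effects": [tokens]} -> toxic
      processes ranked by shared-effect count.
    * ``q2_disease_to_pathways``: params {"disease": IRI or label} ->
      processes/pathways/models the disease impacts.
    * ``q3_process_to_gene_products``: params {"process": IRI or label} ->
      gene products attached to the process's pathways.
    """
    if kind not in QUERY_KINDS:
        raise ValueError(f"unknown competency query {kind!r}")
    ontology = kg.graph("ontology")
    text = _query_text(kind)
    if kind == "q1_effects_to_processes":
        tokens = params.get("effects", [])
        if not tokens:
            return []
        values = " ".join(f'"{t}"' for t in tokens)
        result = ontology.query(text.replace("%TOKENS%", values))
        rows = [
            {"entity": str(r.process), "label": str(r.label),
             "shared_count": int(r.shared)}
            for r in result
        ]
        rows.sort(key=lambda r: (-r["shared_count"], r["label"].lower(), r["entity"]))
        return rows

    key, placeholder = (
        ("disease", "%DISEASE%") if kind == "q2_disease_to_pathways"
        else ("process", "%PROCESS%")
    )
    entity = resolve_entity(ontology, str(params.get(key, "")))
    if entity is None:
        warnings.warn(f"unknown entity {params.get(key)!r}; empty result", stacklevel=2)
        return []
    result = ontology.query(text.replace(placeholder, f"<{entity}>"))
    return [{"entity": str(r[0]), "label": str(r[1])} for r in result]
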