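"""Knowledge-graph construction, label linking, inference, queries."""

import pytest
from rdflib import URIRef
from rdflib.namespace import OWL, RDFS

from toxinkg.errors import MappingError
from toxinkg.ingest import Dataset
from toxinkg.kg_builder import (
    KGraph,
    MappingRule,
    TOX,
    build,
    competency_query,
    effect_profiles,
    effect_token,
    infer_affected_by,
    link_same_as,
    load_mapping_rules,
    load_ontology,
    subject_effect_tokens,
)
from toxinkg.liver_filter import EffectEntry
from toxinkg.study_model import CompoundRecord, StudyRecord

ENT = "https://toxinkg.example.org/ontology/entity/"


@pytest.fixture(scope="module")
def ontology():
    return load_ontology()


@pytest.fixture()
def tiny_dataset():
    return Dataset(
        compounds=[CompoundRecord(compound_id="c1", ingredient_name="Thing",
                                  use_category="hair dye")],
        studies=[StudyRecord(study_id="s1", compound_id="c1",
                             guideline_id="OECD_408")],
        effects=[EffectEntry("c1", "ALT", "increase")],
    )


@pytest.fixture(scope="module")
def linked_kg(kg_dataset, ontology):
    kg = build(kg_dataset)
    link_same_as(kg, ontology)
    infer_affected_by(kg, min_shared=2)
    return kg


class TestBuild:
    def test_hand_counted_quads_for_three_row_input(self, tiny_dataset):
        """Applying the shipped rules by hand: compound -> type+label+category
        (CAS and SMILES empty, skipped) = 3; study -> type+subject+guideline
        = 3; effect -> type+subject+parameter+direction+label+token
        (qualifiers empty, skipped) = 6."""
        kg = build(tiny_dataset)
        assert len(kg.graph("internal")) == 12

    def test_empty_dataset_builds_empty_internal_graph(self):
        assert len(build(Dataset()).graph("internal")) == 0

    def test_determinism(self, tiny_dataset):
        assert build(tiny_dataset).quads() == build(tiny_dataset).quads()

    def test_all_built_quads_live_in_internal(self, tiny_dataset):
        kg = build(tiny_dataset)
        internal = TOX["graph/internal"]
        assert {g for _, _, _, g in kg.quads()} == {internal}

    def test_rule_with_unknown_column_names_the_rule(self, tiny_dataset):
        bad = MappingRule(
            source="compounds", subject_template="compound/{compound_id}",
            predicate="toxv:broken", object_spec={"column": "no_such_column"},
        )
        with pytest.raises(MappingError, match="no_such_column"):
            build(tiny_dataset, [bad])

    def test_mapping_rules_load_from_data(self):
        rules, namespaces = load_mapping_rules()
        assert {"tox", "toxv", "rdf", "rdfs"} <= set(namespaces)
        assert all(isinstance(r, MappingRule) for r in rules)


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["trig", "nquads"])
    def test_round_trip_preserves_quads(self, linked_kg, fmt):
        text = linked_kg.serialize(fmt)
        again = KGraph.parse(text, fmt)
        assert again.quads() == linked_kg.quads()

    def test_nquads_output_is_sorted(self, linked_kg):
        lines = linked_kg.serialize("nquads").splitlines()
        assert lines == sorted(lines)


class TestLinking:
    def test_label_match_emits_same_as(self, ontology):
        ds = Dataset(
            compounds=[CompoundRecord(compound_id="c1", ingredient_name="X",
                                      use_category="other")],
            effects=[EffectEntry("c1", "hepatic necrosis", "increase")],
        )
        kg = build(ds)
        link_same_as(kg, ontology)
        links = list(kg.graph("external_links").triples((None, OWL.sameAs, None)))
        targets = {o for _, _, o in links}
        assert URIRef(ENT + "necrosis") in targets

    def test_no_shared_labels_no_links(self, ontology):
        ds = Dataset(compounds=[CompoundRecord(
            compound_id="c1", ingredient_name="Totally unrelated name",
            use_category="other")])
        kg = build(ds)
        link_same_as(kg, ontology)
        assert len(kg.graph("external_links")) == 0

    def test_ambiguous_match_emits_all_links_and_warns(self, ontology):
        import rdflib

        duplicated = rdflib.Graph()
        for triple in ontology:
            duplicated.add(triple)
        clone = URIRef(ENT + "necrosis-clone")
        duplicated.add((clone, RDFS.label, rdflib.Literal("necrosis")))
        ds = Dataset(
            compounds=[CompoundRecord(compound_id="c1", ingredient_name="X",
                                      use_category="other")],
            effects=[EffectEntry("c1", "hepatic necrosis", "increase")],
        )
        kg = build(ds)
        with pytest.warns(UserWarning, match="matches 2"):
            link_same_as(kg, duplicated)
        targets = {
            o for _, _, o in kg.graph("external_links").triples((None, OWL.sameAs, None))
        }
        assert {URIRef(ENT + "necrosis"), clone} <= targets

    def test_graph_separation_invariant(self, linked_kg):
        linked_kg.check_graph_separation()
        internal = linked_kg.graph("internal")
        assert next(internal.triples((None, OWL.sameAs, None)), None) is None


class TestEffectProfiles:
    def test_subtype_inherits_ancestor_effects(self, ontology):
        by_label = {p.label: p for p in effect_profiles(ontology)}
        nafld = by_label["NAFLD"]
        assert nafld.own_effects == {"increased-hepatic-fat",
                                     "increased-triglycerides"}
        # two own + two inherited from the parent process
        assert nafld.effects == nafld.own_effects | {
            "increased-cholesterol", "hepatocellular-hypertrophy"
        }

    def test_subject_matching_only_inherited_effects(self, ontology):
        ds = Dataset(
            compounds=[CompoundRecord(compound_id="c1", ingredient_name="X",
                                      use_category="other")],
            effects=[EffectEntry("c1", "cholesterol", "increase"),
                     EffectEntry("c1", "hepatocellular hypertrophy", "increase")],
        )
        kg = build(ds)
        link_same_as(kg, ontology)
        links = infer_affected_by(kg, min_shared=2)
        by_entity = {str(l.entity).rsplit("/", 1)[-1]: l.shared_count for l in links}
        assert by_entity.get("nafld") == 2  # inherited-only overlap
        assert by_entity.get("lipidosis") == 2


class TestInference:
    def test_case_study_link_recovered_with_three_shared_effects(self, linked_kg):
        tokens = subject_effect_tokens(linked_kg)
        br51 = tokens[TOX["compound/basic-red-51"]]
        assert {"increased-ALP", "GGT-presence", "necrosis"} <= br51
        links = infer_affected_by(build_fresh(linked_kg), min_shared=2)
        cholestasis = [
            l for l in links
            if str(l.subject).endswith("basic-red-51")
            and str(l.entity).endswith("cholestasis")
        ]
        assert len(cholestasis) == 1 and cholestasis[0].shared_count == 3

    def test_shared_counts_equal_set_intersection_oracle(self, linked_kg, ontology):
        profiles = effect_profiles(ontology)
        links = infer_affected_by(build_fresh(linked_kg), profiles, min_shared=1)
        by_pair = {(l.subject, l.entity): l.shared_count for l in links}
        tokens = subject_effect_tokens(linked_kg)
        for subject, subject_tokens in tokens.items():
            for profile in profiles:
                expected = len(subject_tokens & set(profile.effects))
                got = by_pair.get((subject, profile.entity), 0)
                assert got == expected or (expected == 0 and got == 0)

    def test_disjoint_sets_never_link(self, ontology):
        ds = Dataset(
            compounds=[CompoundRecord(compound_id="c1", ingredient_name="X",
                                      use_category="other")],
            effects=[EffectEntry("c1", "albumin", "decrease")],
        )
        kg = build(ds)
        link_same_as(kg, ontology)
        assert infer_affected_by(kg, min_shared=1) == []

    def test_min_shared_monotonicity(self, linked_kg, ontology):
        profiles = effect_profiles(ontology)
        previous = None
        for threshold in (1, 2, 3, 4):
            links = {
                (l.subject, l.entity)
                for l in infer_affected_by(build_fresh(linked_kg), profiles,
                                           min_shared=threshold)
            }
            if previous is not None:
                assert links <= previous
            previous = links

    def test_inferred_quads_stay_out_of_internal(self, kg_dataset, ontology):
        kg = build(kg_dataset)
        link_same_as(kg, ontology)
        before = set(kg.graph("internal"))
        infer_affected_by(kg, min_shared=1)
        assert set(kg.graph("internal")) == before
        kg.check_graph_separation()


def build_fresh(linked_kg):
    """Copy of a linked KG without its inferred graph (so inference tests
    start clean)."""
    fresh = KGraph()
    for name in ("internal", "ontology", "external_links"):
        for triple in linked_kg.graph(name):
            fresh.graph(name).add(triple)
    return fresh


class TestCompetencyQueries:
    def test_effects_to_processes_ranks_cholestasis_first(self, linked_kg):
        rows = competency_query(
            linked_kg, "q1_effects_to_processes",
            {"effects": ["increased-ALP", "GGT-presence", "necrosis"]},
        )
        assert rows and rows[0]["label"] == "cholestasis"
        assert rows[0]["shared_count"] == 3

    def test_q1_ranking_is_total_and_deterministic(self, linked_kg):
        params = {"effects": ["increased-cholesterol", "increased-ALP",
                              "increased-triglycerides"]}
        first = competency_query(linked_kg, "q1_effects_to_processes", params)
        second = competency_query(linked_kg, "q1_effects_to_processes", params)
        assert first == second
        counts = [r["shared_count"] for r in first]
        assert counts == sorted(counts, reverse=True)

    def test_disease_to_pathways_includes_fatty_acid_biosynthesis(self, linked_kg):
        rows = competency_query(linked_kg, "q2_disease_to_pathways",
                                {"disease": "NAFLD"})
        assert "fatty acid biosynthetic process" in {r["label"] for r in rows}

    def test_process_to_gene_products_includes_acc1(self, linked_kg):
        rows = competency_query(
            linked_kg, "q3_process_to_gene_products",
            {"process": "hyperfunction of lipid biosynthesis"},
        )
        assert "acetyl-CoA carboxylase 1" in {r["label"] for r in rows}

    def test_unknown_entity_warns_and_returns_empty(self, linked_kg):
        with pytest.warns(UserWarning, match="unknown entity"):
            rows = competency_query(linked_kg, "q2_disease_to_pathways",
                                    {"disease": "no such disease"})
        assert rows == []


class TestEffectTokens:
    @pytest.mark.parametrize(
        "parameter,direction,token",
        [("ALP", "increase", "increased-ALP"),
         ("GGT", "increase", "GGT-presence"),
         ("hepatic necrosis", "increase", "necrosis")],
    )
    def test_aligned_tokens(self, parameter, direction, token):
        assert effect_token(parameter, direction)[0] == token

    def test_unaligned_combination_gets_generated_token(self):
        token, label = effect_token("albumin", "decrease")
        assert token == "decrease-albumin"
        assert label == "decrease albumin"
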