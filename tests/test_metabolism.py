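"""Activity-flow triad conversion, pathway definitions, layer merging."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmet import (ConversionConfig, FormatError, MetabolicReaction,
                       PathwayDefinition, load_pathway_definitions,
                       merge_metabolic_layer, reaction_to_af_edges,
                       read_reactions_tsv)
from causalmet.network import CausalNetwork


def rxn(substrates, products, enzymes, rid="R1", pathway="Glycolysis"):
    return MetabolicReaction(reaction_id=rid, pathway=pathway,
                             substrates=tuple(substrates),
                             products=tuple(products),
                             enzymes=tuple(enzymes))


def edge_set(edges):
    return {(e.source, e.target, e.sign) for e in edges}


class TestTriadConversion:
    def test_single_reaction_gives_triad(self):
        edges = reaction_to_af_edges(rxn(["S"], ["P"], ["E"]))
        assert edge_set(edges) == {("S", "P", 1), ("E", "P", 1), ("E", "S", -1)}

    def test_two_substrates_give_five_edges(self):
        edges = reaction_to_af_edges(rxn(["S1", "S2"], ["P"], ["E"]))
        assert edge_set(edges) == {
            ("S1", "P", 1), ("S2", "P", 1), ("E", "P", 1),
            ("E", "S1", -1), ("E", "S2", -1)}

    def test_enzyme_free_reaction_is_spontaneous_conversion(self):
        edges = reaction_to_af_edges(rxn(["S"], ["P"], []))
        assert edge_set(edges) == {("S", "P", 1)}

    def test_currency_metabolites_generate_no_edges(self):
        edges = reaction_to_af_edges(rxn(["G6P", "ATP"], ["F16BP"], ["PFKL"]))
        assert all("ATP" not in (e.source, e.target) for e in edges)
        assert edge_set(edges) == {("G6P", "F16BP", 1), ("PFKL", "F16BP", 1),
                                   ("PFKL", "G6P", -1)}

    def test_all_products_excluded_skips_reaction(self, caplog):
        assert reaction_to_af_edges(rxn(["S"], ["ATP"], ["E"])) == []
        assert any("skipped" in m for m in caplog.messages)

    def test_generated_scores_follow_config(self):
        edges = reaction_to_af_edges(rxn(["S"], ["P"], ["E"]),
                                     ConversionConfig(default_score=0.9))
        assert {e.score for e in edges} == {0.9}

    def test_substrate_product_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            rxn(["X"], ["X"], ["E"])

    @given(ns=st.integers(1, 3), np_=st.integers(1, 3), ne=st.integers(0, 3))
    @settings(max_examples=40, deadline=None)
    def test_edge_count_formula_and_sign_placement(self, ns, np_, ne):
        reaction = rxn([f"S{i}" for i in range(ns)],
                       [f"P{i}" for i in range(np_)],
                       [f"E{i}" for i in range(ne)])
        edges = reaction_to_af_edges(reaction)
        assert len(edges) == ns * np_ + ne * np_ + ne * ns
        for e in edges:
            if e.source.startswith("E") and e.target.startswith("S"):
                assert e.sign == -1
            else:
                assert e.sign == 1

    def test_conversion_deterministic(self):
        reaction = rxn(["S1", "S2"], ["P1", "P2"], ["E1", "E2"])
        assert reaction_to_af_edges(reaction) == reaction_to_af_edges(reaction)


NINE_CURATED = [
    "Glycolysis and Gluconeogenesis", "Citric acid cycle", "Glycogenesis",
    "Glycogenolysis", "Aspartate and asparagine metabolism",
    "Fatty acid synthesis", "Glutamine metabolism",
    "Nucleotide biosynthesis", "Pentose phosphate",
]


def pathway_yaml(with_demerge=True):
    blocks = "\n".join(
        f"  - name: {name}\n    enzymes: [E{i}a, E{i}b]\n"
        f"    rate_limiting: [E{i}a]"
        for i, name in enumerate(NINE_CURATED))
    demerge = """
demerge:
  Glycolysis and Gluconeogenesis:
    - {name: Glycolysis, enzymes: [E0a], rate_limiting: [E0a]}
    - {name: Gluconeogenesis, enzymes: [E0b], rate_limiting: [E0b]}
""" if with_demerge else ""
    return io.StringIO(f"pathways:\n{blocks}\n{demerge}")


class TestPathwayDefinitions:
    def test_demerge_turns_nine_into_ten(self):
        defs = load_pathway_definitions(pathway_yaml())
        assert len(defs) == 10
        names = {d.name for d in defs}
        assert {"Glycolysis", "Gluconeogenesis"} <= names
        assert "Glycolysis and Gluconeogenesis" not in names
        sub = next(d for d in defs if d.name == "Glycolysis")
        assert sub.parent == "Glycolysis and Gluconeogenesis"

    def test_without_demerge_nine_stay_nine(self):
        defs = load_pathway_definitions(pathway_yaml(), apply_demerge=False)
        assert len(defs) == 9

    def test_rle_subset_read_directly(self):
        defs = load_pathway_definitions(io.StringIO(
            "pathways:\n  - name: TCA\n    enzymes: [A, B, C, D, E, F, G, H]\n"
            "    rate_limiting: [A, B]\n"))
        assert defs[0].rate_limiting == frozenset({"A", "B"})

    def test_rle_outside_members_is_load_error(self):
        with pytest.raises(FormatError, match="rate-limiting"):
            load_pathway_definitions(io.StringIO(
                "pathways:\n  - name: X\n    enzymes: [A]\n"
                "    rate_limiting: [B]\n"))

    def test_duplicate_pathway_name_is_error(self):
        with pytest.raises(FormatError, match="duplicate"):
            load_pathway_definitions(io.StringIO(
                "pathways:\n"
                "  - {name: X, enzymes: [A], rate_limiting: [A]}\n"
                "  - {name: X, enzymes: [B], rate_limiting: [B]}\n"))

    def test_zero_rle_pathway_warns_at_load(self, caplog):
        load_pathway_definitions(io.StringIO(
            "pathways:\n  - {name: X, enzymes: [A], rate_limiting: []}\n"))
        assert any("no rate-limiting" in m for m in caplog.messages)


class TestReactionFile:
    def test_reversible_reaction_expands_to_two(self):
        frame = io.StringIO(
            "reaction_id\tpathway\tsubstrates\tproducts\tenzymes\treversible\n"
            "R1\tTCA\tmalate\toxaloacetate\tMDH2\t1\n")
        reactions = read_reactions_tsv(frame)
        assert [r.reaction_id for r in reactions] == ["R1_fwd", "R1_rev"]
        assert reactions[1].substrates == ("oxaloacetate",)

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError, match="enzymes"):
            read_reactions_tsv(io.StringIO(
                "reaction_id\tpathway\tsubstrates\tproducts\treversible\n"))


class TestMerge:
    def test_merging_one_triad_into_empty_network(self):
        net = merge_metabolic_layer(CausalNetwork(), [rxn(["S"], ["P"], ["E"])])
        assert net.n_entities == 3 and net.n_edges == 3

    def test_merge_is_idempotent(self):
        reactions = [rxn(["S"], ["P"], ["E"]),
                     rxn(["P"], ["Q"], ["E2"], rid="R2")]
        once = merge_metabolic_layer(CausalNetwork(), reactions)
        twice = merge_metabolic_layer(once, reactions)
        assert once == twice

    def test_shared_metabolite_connects_pathways(self):
        # two pathways sharing metabolite P must form one weak component;
        # oracle: plain reachability over undirected adjacency
        reactions = [rxn(["S"], ["P"], ["E1"], rid="R1", pathway="A"),
                     rxn(["P"], ["Q"], ["E2"], rid="R2", pathway="B")]
        net = merge_metabolic_layer(CausalNetwork(), reactions)
        adjacency = {}
        for e in net.edges():
            adjacency.setdefault(e.source, set()).add(e.target)
            adjacency.setdefault(e.target, set()).add(e.source)
        seen, stack = set(), ["S"]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adjacency.get(node, ()))
        assert seen == {"S", "P", "Q", "E1", "E2"}

    def test_class_collision_names_identifier(self):
        base = CausalNetwork()
        from causalmet import Entity, EntityClass
        base.add_entity(Entity("P", "P", EntityClass.PROTEIN))
        with pytest.raises(Exception, match="P"):
            merge_metabolic_layer(base, [rxn(["S"], ["P"], ["E"])])
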