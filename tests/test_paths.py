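"""Bounded signed path enumeration, distances, parity signs, Z machinery."""

import math

import numpy as np
import pytest

from causalmet import (CausalPath, DegenerateDistributionError, PathSign,
                       best_path, classify_gene_effect,
                       compute_pathway_zscores, enumerate_paths,
                       gene_pathway_distance, path_distance, path_sign)
from causalmet.metabolism import PathwayDefinition
from causalmet.paths import score_network
from conftest import make_network, random_edge_list
from _oracles import brute_force_distance, brute_force_paths, brute_force_sign


def path(signs, scores, nodes=None):
    nodes = nodes or tuple(f"n{i}" for i in range(len(signs) + 1))
    return CausalPath(tuple(nodes), tuple(signs), tuple(scores))


class TestEnumeration:
    def test_chain_longer_than_cutoff_is_invisible(self):
        chain = [(a, b, 1, 0.9) for a, b in
                 zip("ABCDE", "BCDEF")]
        net = make_network(chain)
        assert enumerate_paths(net, "A", {"F"}, cutoff=4) == []
        assert len(enumerate_paths(net, "A", {"F"}, cutoff=5)) == 1

    def test_diamond_has_two_paths_of_length_two(self):
        net = make_network([("A", "B", 1, 0.9), ("B", "D", 1, 0.8),
                            ("A", "C", -1, 0.7), ("C", "D", 1, 0.6)])
        paths = enumerate_paths(net, "A", {"D"})
        assert [p.nodes for p in paths] == [("A", "B", "D"), ("A", "C", "D")]
        assert [p.sign for p in paths] == [PathSign.ACTIVATING,
                                           PathSign.INHIBITING]

    def test_antiparallel_signed_edges_give_distinct_paths(self):
        net = make_network([("A", "B", 1, 0.9), ("A", "B", -1, 0.5)])
        paths = enumerate_paths(net, "A", {"B"})
        assert {(p.signs, p.scores) for p in paths} == {
            ((1,), (0.9,)), ((-1,), (0.5,))}

    def test_target_terminates_paths(self):
        # A -> T1 -> T2: with both as targets, no path may cross T1
        net = make_network([("A", "T1", 1, 0.9), ("T1", "T2", 1, 0.9)])
        paths = enumerate_paths(net, "A", {"T1", "T2"})
        assert [p.nodes for p in paths] == [("A", "T1")]

    def test_unsigned_edges_excluded_by_default(self):
        net = make_network([("A", "B", 0, 0.9), ("B", "C", 1, 0.9),
                            ("A", "C", 1, 0.4)])
        default = enumerate_paths(net, "A", {"C"})
        assert [p.nodes for p in default] == [("A", "C")]
        admitted = enumerate_paths(net, "A", {"C"}, include_unsigned=True)
        assert {p.sign for p in admitted} == {PathSign.ACTIVATING,
                                              PathSign.INDETERMINATE}

    def test_unknown_source_or_target_raises(self):
        net = make_network([("A", "B", 1, 0.9)])
        with pytest.raises(KeyError):
            enumerate_paths(net, "Z", {"B"})
        with pytest.raises(KeyError):
            enumerate_paths(net, "A", {"Z"})

    def test_empty_target_set_warns_and_returns_empty(self, caplog):
        net = make_network([("A", "B", 1, 0.9)])
        assert enumerate_paths(net, "A", set()) == []
        assert any("empty target set" in m for m in caplog.messages)

    def test_matches_brute_force_oracle_on_random_networks(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            edges = random_edge_list(rng, n_nodes=10, n_edges=25)
            net = make_network(edges)
            nodes = sorted({n for u, v, *_ in edges for n in (u, v)})
            source, targets = nodes[0], set(nodes[-3:]) - {nodes[0]}
            got = {(p.nodes, p.signs, p.scores)
                   for p in enumerate_paths(net, source, targets)}
            assert got == brute_force_paths(edges, source, targets, cutoff=4)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(11)
        edges = random_edge_list(rng, n_nodes=9, n_edges=22)
        net = make_network(edges)
        nodes = sorted({n for u, v, *_ in edges for n in (u, v)})
        for k in (1, 2, 3):
            smaller = {p.nodes for p in
                       enumerate_paths(net, nodes[0], {nodes[-1]}, cutoff=k)}
            larger = {p.nodes for p in
                      enumerate_paths(net, nodes[0], {nodes[-1]}, cutoff=k + 1)}
            assert smaller <= larger

    def test_adding_edge_never_increases_min_distance(self):
        rng = np.random.default_rng(3)
        edges = random_edge_list(rng, n_nodes=8, n_edges=18)
        nodes = sorted({n for u, v, *_ in edges for n in (u, v)})
        source, target = nodes[0], nodes[-1]

        def min_dist(edge_list):
            found = enumerate_paths(make_network(edge_list), source, {target})
            return min((p.distance for p in found), default=math.inf)

        base = min_dist(edges)
        existing = {(u, v) for u, v, *_ in edges}
        extra = next((a, b) for a in nodes for b in nodes
                     if a != b and (a, b) not in existing)
        assert min_dist(edges + [(*extra, 1, 0.95)]) <= base + 1e-12


class TestDistanceAndSign:
    @pytest.mark.parametrize("scores,expected", [
        ((1.0,), 0.0),
        ((0.8, 0.8), 0.4),
        ((0.9, 0.5, 0.7), 0.9),   # 0.1 + 0.5 + 0.3
    ])
    def test_distance_is_sum_of_edge_distances(self, scores, expected):
        p = path((1,) * len(scores), scores)
        assert path_distance(p) == pytest.approx(expected)

    @pytest.mark.parametrize("signs,expected", [
        ((1, 1, 1), PathSign.ACTIVATING),       # zero inhibitory steps
        ((-1, 1, 1), PathSign.INHIBITING),      # odd
        ((-1, -1), PathSign.ACTIVATING),        # even
        ((0, 1), PathSign.INDETERMINATE),       # unsigned step admitted
    ])
    def test_parity_rule(self, signs, expected):
        assert path_sign(path(signs, (0.9,) * len(signs))) is expected

    def test_sign_equals_product_of_edge_signs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            signs = tuple(rng.choice([-1, 1], size=rng.integers(1, 5)))
            p = path(signs, (0.5,) * len(signs))
            assert p.sign.value == brute_force_sign(signs)
            assert p.distance == pytest.approx(brute_force_distance(p.scores))

    def test_zero_length_self_path_is_activating_distance_zero(self):
        p = CausalPath(("RLE",), (), ())
        assert p.length == 0 and p.distance == 0.0
        assert p.sign is PathSign.ACTIVATING


class TestGeneDistance:
    def test_minimum_over_paths(self):
        paths = [path((1, 1), (0.8, 0.8)), path((1,), (0.1,))]
        assert gene_pathway_distance(paths) == (pytest.approx(0.4), False)

    def test_imputation_when_unreachable(self):
        assert gene_pathway_distance([], imputation_value=1.7) == (1.7, True)

    def test_imputation_before_distribution_is_sequencing_error(self):
        with pytest.raises(ValueError, match="imputation"):
            gene_pathway_distance([])


class TestZScores:
    def test_hand_computed_distribution(self):
        distances = {"g1": 0.0, "g2": 1.0, "g3": 1.0, "g4": 1.0, "g5": 1.0}
        scores = {s.gene: s for s in compute_pathway_zscores(distances)}
        assert scores["g1"].z == pytest.approx(-2.0)
        assert scores["g1"].significant
        assert all(not scores[g].significant for g in ("g2", "g3", "g4", "g5"))

    def test_threshold_is_strict(self):
        # {0, 1} puts the low gene at exactly z = -1; at threshold -1 the
        # strict inequality must leave it non-significant
        scores = compute_pathway_zscores({"a": 0.0, "b": 1.0}, threshold=-1.0)
        a = next(s for s in scores if s.gene == "a")
        assert a.z == -1.0
        assert not a.significant

    def test_z_normalisation(self):
        rng = np.random.default_rng(2)
        distances = {f"g{i}": float(v)
                     for i, v in enumerate(rng.uniform(0, 3, size=200))}
        zs = np.array([s.z for s in compute_pathway_zscores(distances)])
        assert abs(zs.mean()) < 1e-9
        assert abs(zs.std(ddof=0) - 1) < 1e-9

    def test_degenerate_distribution_raises(self):
        with pytest.raises(DegenerateDistributionError):
            compute_pathway_zscores({"a": 1.0, "b": 1.0})
        with pytest.raises(DegenerateDistributionError):
            compute_pathway_zscores({"a": 1.0})


class TestClassification:
    def test_pure_activator(self):
        paths = [path((1, 1), (0.9, 0.9))] * 3
        assert classify_gene_effect(paths) == (3, 0, "activator")

    def test_tie_is_mixed(self):
        paths = [path((1,), (0.9,)), path((-1,), (0.9,))]
        assert classify_gene_effect(paths) == (1, 1, "mixed")

    def test_double_inhibition_counts_as_activating(self):
        paths = [path((-1, -1), (0.9, 0.9))]
        assert classify_gene_effect(paths) == (1, 0, "activator")

    def test_best_path_tie_break(self):
        a = path((1,), (0.8,), nodes=("A", "Z"))
        b = path((1, 1), (0.9, 0.9), nodes=("A", "B", "Z"))
        c = path((1,), (0.8,), nodes=("A", "Y"))
        assert best_path([a, b, c]) is c  # same distance/length, lexicographic


class TestScoreNetwork:
    def test_planted_truth_recovered(self, mini, mini_scoring):
        for name, planted in mini.planted.items():
            plist = mini_scoring.paths[(name, planted.pathway)]
            match = [p for p in plist if p.nodes == planted.node_chain]
            assert len(match) == 1
            assert match[0].distance == pytest.approx(planted.expected_distance)
            assert match[0].sign.value == planted.expected_sign

    def test_activator_and_inhibitor_calls(self, mini, mini_scoring):
        pw1 = mini.pathway_defs[0].name
        act = mini_scoring.score("QACT", pw1)
        inh = mini_scoring.score("QINH", pw1)
        assert act.significant and act.n_activating >= 1
        assert inh.significant and inh.n_inhibiting >= 1
        assert classify_gene_effect(
            mini_scoring.paths[("QACT", pw1)])[2] == "activator"

    def test_unreachable_gene_imputed_at_max_finite(self, mini, mini_scoring):
        pw2 = mini.pathway_defs[-1].name
        far = mini_scoring.score("QFAR", pw2)
        assert far.imputed and not far.significant and far.n_paths == 0
        finite = [s.distance for s in mini_scoring.scores[pw2].values()
                  if not s.imputed]
        assert far.distance == pytest.approx(max(finite))

    def test_rle_gene_scores_distance_zero_self_path(self, mini, mini_scoring):
        pdef = mini.pathway_defs[0]
        rle = sorted(pdef.rate_limiting)[0]
        score = mini_scoring.score(rle, pdef.name)
        assert score.distance == 0.0 and not score.imputed
        assert score.n_paths == 1 and score.n_activating == 0

    def test_missing_rle_target_is_analysis_error(self, mini):
        ghost = PathwayDefinition(name="Ghost",
                                  member_enzymes=frozenset({"NOPE"}),
                                  rate_limiting=frozenset({"NOPE"}))
        with pytest.raises(ValueError, match="Ghost"):
            score_network(mini.network, [ghost])
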