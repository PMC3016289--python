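import itertools
import random

import networkx as nx
import numpy as np
import pytest

from mthaplo.network import (Constraint, PositionWeights, UNIT_WEIGHTS,
                             branching_order_tree, build_mj_network,
                             condense_haplotypes, extract_parsimony_tree,
                             hypercube_network, median_closure, tree_length)
from mthaplo.tree import MutationTree
from mthaplo.variants import SequenceProfile, VariantCall


def profiles_from_tokens(spec):
    """{'sample': {'100', '200C'}} -> SequenceProfiles."""
    from mthaplo.variants import parse_mutation
    out = []
    for sid, toks in spec.items():
        out.append(SequenceProfile(
            sid, frozenset(parse_mutation(t) for t in toks)))
    return out


def exhaustive_parsimony_minimum(haplotypes, root, weights):
    """Oracle: minimum weighted length over all unrooted binary topologies
    (weighted two-state Fitch per token)."""
    labels = [f"x{i}" for i in range(len(haplotypes))] + ["ROOT"]
    hapmap = {f"x{i}": h for i, h in enumerate(haplotypes)}
    hapmap["ROOT"] = frozenset(root)
    tokens = sorted({t for h in haplotypes for t in h} | set(root))

    def topologies(tips):
        def rec(lab):
            if len(lab) == 3:
                yield [("i0", l) for l in lab], 1
                return
            for edges, ni in rec(lab[:-1]):
                for k in range(len(edges)):
                    a, b = edges[k]
                    nn = f"i{ni}"
                    yield (edges[:k] + edges[k + 1:]
                           + [(a, nn), (nn, b), (nn, lab[-1])], ni + 1)
        if len(tips) <= 3:
            yield [("i0", l) for l in tips]
        else:
            for e, _ in rec(list(tips)):
                yield e

    best = float("inf")
    for edges in topologies(labels):
        g = nx.Graph(edges)
        start = next(iter(g.nodes))
        parent = {start: None}
        children = {n: [] for n in g.nodes}
        for n in nx.dfs_preorder_nodes(g, start):
            for m in g.neighbors(n):
                if m not in parent:
                    parent[m] = n
                    children[n].append(m)
        order = list(nx.dfs_postorder_nodes(g, start))
        total = 0.0
        for tok in tokens:
            w = weights.of_token(tok)
            INF = float("inf")
            cost = {}
            for n in order:
                if not children[n]:
                    has = tok in hapmap[n]
                    cost[n] = [INF if has else 0.0, 0.0 if has else INF]
                else:
                    cost[n] = [
                        sum(min(cost[c][0], cost[c][1] + w)
                            for c in children[n]),
                        sum(min(cost[c][1], cost[c][0] + w)
                            for c in children[n]),
                    ]
            total += min(cost[start])
        best = min(best, total)
    return best


class TestCondense:
    def test_identical_profiles_collapse(self):
        profs = profiles_from_tokens({f"s{i}": {"100"} for i in range(5)})
        haps = condense_haplotypes(profs)
        assert len(haps) == 1
        assert haps[0][1] == 5

    def test_distinct_profiles_stay_distinct(self):
        profs = profiles_from_tokens({"a": {"100"}, "b": {"200"},
                                      "c": set()})
        haps = condense_haplotypes(profs)
        assert len(haps) == 3
        assert sum(m for _, m, _ in haps) == 3

    def test_multiplicity_total_conserved(self):
        profs = profiles_from_tokens(
            {"a": {"100"}, "b": {"100"}, "c": {"200"}, "d": set(),
             "e": set(), "f": set()})
        haps = condense_haplotypes(profs)
        assert sum(m for _, m, _ in haps) == 6


class TestMedianJoining:
    def test_three_singleton_haplotypes_make_a_star(self):
        common = frozenset({"50"})
        haps = [common | {"100"}, common | {"200"}, common | {"300C"}]
        net = build_mj_network(haps)
        # the common profile is inferred as the single median hub
        assert common in net.graph.nodes
        assert net.graph.degree[common] == 3
        assert net.graph.number_of_nodes() == 4

    def test_two_haplotypes_connect_by_a_k_edge_path(self):
        a = frozenset()
        b = frozenset({"100", "200", "300"})
        net = build_mj_network([a, b])
        assert net.graph.number_of_edges() == 3
        assert nx.shortest_path_length(net.graph, a, b) == 3
        for u, v in net.graph.edges:
            assert len(u ^ v) == 1  # every edge is a single mutation

    def test_every_edge_single_mutation_and_observed_present(self):
        rng = random.Random(4)
        toks = [str(100 * i) for i in range(1, 6)]
        haps = {frozenset(t for t in toks if rng.random() < 0.5)
                for _ in range(6)}
        net = build_mj_network(sorted(haps, key=sorted))
        for u, v in net.graph.edges:
            assert len(u ^ v) == 1
        for h in haps:
            assert h in net.graph.nodes
        assert nx.is_connected(net.graph)


class TestTreeLength:
    def test_star_counts_mutations(self):
        from mthaplo import star_tree
        assert tree_length(star_tree([1, 2, 1, 0])) == 4.0

    def test_downweighted_position_reduces_length(self):
        from mthaplo.tree import Node
        root = Node("root")
        root.add(Node("a", mutations=[VariantCall(16189, "C", "T")]))
        root.add(Node("b", mutations=[VariantCall(16189, "T", "C"),
                                      VariantCall(5, "A", "G")]))
        tree = MutationTree(root)
        half = PositionWeights(default=1.0, hotspots=[16189],
                               hotspot_weight=0.5)
        assert tree_length(tree) == 3.0
        assert tree_length(tree, half) == 2.0

    def test_equals_manual_branch_recount(self):
        rng = np.random.default_rng(2)
        from conftest import random_mutation_tree
        tree = random_mutation_tree(rng, 9)
        manual = sum(len(n.mutations) for n in tree.preorder())
        assert tree_length(tree) == manual


class TestExtraction:
    def test_star_network_gives_star_tree(self):
        haps = [(frozenset({"100"}), 1, ["a"]),
                (frozenset({"200"}), 1, ["b"]),
                (frozenset({"300"}), 1, ["c"])]
        net = hypercube_network(haps, include=[frozenset()])
        tree = extract_parsimony_tree(net, frozenset())
        assert tree_length(tree) == 3.0
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_matches_exhaustive_minimum(self):
        rng = random.Random(17)
        for trial in range(15):
            npos = rng.randint(3, 6)
            toks = [str(100 * (i + 1)) for i in range(npos)]
            k = rng.randint(3, 6)
            hapset = set()
            while len(hapset) < k:
                hapset.add(frozenset(t for t in toks if rng.random() < 0.5))
            haps = [(h, 1, [f"s{i}"])
                    for i, h in enumerate(sorted(hapset, key=sorted))]
            w = UNIT_WEIGHTS if trial % 2 else PositionWeights(
                1.0, [100], 0.5)
            net = hypercube_network(haps, w, include=[frozenset()])
            tree = extract_parsimony_tree(net, frozenset())
            assert tree_length(tree, w) == pytest.approx(
                exhaustive_parsimony_minimum(sorted(hapset, key=sorted),
                                             frozenset(), w))

    def test_tree_is_embeddable_in_network(self):
        """Every branch mutation corresponds to a unit network edge along
        the path between the branch's endpoint haplotypes."""
        haps = [(frozenset({"100"}), 1, ["a"]),
                (frozenset({"100", "200"}), 1, ["b"]),
                (frozenset({"300"}), 1, ["c"])]
        net = hypercube_network(haps, include=[frozenset()])
        tree = extract_parsimony_tree(net, frozenset())
        edge_tokens = {d["token"] for _, _, d in net.graph.edges(data=True)}
        for node in tree.preorder():
            for v in node.mutations:
                assert str(v) in edge_tokens

    def test_constraint_enforced_at_cost(self):
        haps = [(frozenset({"100"}), 1, ["a"]),
                (frozenset({"100", "200"}), 1, ["b"]),
                (frozenset({"200", "300"}), 1, ["c"])]
        net = hypercube_network(haps, include=[frozenset()])
        free = extract_parsimony_tree(net, frozenset())
        forced = extract_parsimony_tree(
            net, frozenset(), constraints=[Constraint("X",
                                                      frozenset({"a", "c"}))])
        tips = {frozenset(t.name for t in MutationTree(n).tips())
                for n in forced.preorder()}
        assert frozenset({"a", "c"}) in tips
        assert tree_length(forced) >= tree_length(free)

    def test_unsatisfiable_constraint_raises_with_name(self):
        haps = [(frozenset({"100"}), 2, ["a", "b"]),
                (frozenset({"200"}), 1, ["c"])]
        net = hypercube_network(haps, include=[frozenset()])
        with pytest.raises(ValueError, match="Y"):
            extract_parsimony_tree(
                net, frozenset(),
                constraints=[Constraint("Y", frozenset({"a", "c"}))])

    def test_nested_constraints_and_mrca_naming(self):
        haps = [(frozenset({"100"}), 1, ["a"]),
                (frozenset({"100", "200"}), 1, ["b"]),
                (frozenset({"100", "200", "300"}), 1, ["c"]),
                (frozenset({"400"}), 1, ["d"])]
        net = hypercube_network(haps, include=[frozenset()])
        tree = extract_parsimony_tree(net, frozenset(), constraints=[
            Constraint("inner", frozenset({"b", "c"})),
            Constraint("outer", frozenset({"a", "b", "c"}))])
        inner = tree.find("inner")
        assert {t.name for t in MutationTree(inner).tips()} == {"b", "c"}
        outer = tree.find("outer")
        assert {t.name for t in MutationTree(outer).tips()} == {"a", "b",
                                                                "c"}

    def test_recurrent_hotspot_placed_twice_in_tree(self):
        """A homoplasic fast site is used on two branches when its weight
        makes that the cheapest explanation."""
        w = PositionWeights(default=10.0, hotspots=[16189],
                            hotspot_weight=5.0)
        haps = [(frozenset({"100", "16189"}), 1, ["a"]),
                (frozenset({"100", "200"}), 1, ["b"]),
                (frozenset({"300", "16189"}), 1, ["c"]),
                (frozenset({"300", "400"}), 1, ["d"])]
        net = hypercube_network(haps, w, include=[frozenset()])
        tree = extract_parsimony_tree(net, frozenset())
        uses = sum(1 for n in tree.preorder()
                   for v in n.mutations if v.position == 16189)
        assert uses == 2


class TestManualOverride:
    def test_branching_order_honoured_exactly(self):
        haps = {"a": frozenset({"100"}),
                "b": frozenset({"100", "200"}),
                "c": frozenset({"300"})}
        tree = branching_order_tree([["a", "b"], "c"], haps, frozenset())
        top = {tuple(sorted(t.name for t in MutationTree(c).tips()))
               for c in tree.root.children}
        assert top == {("a", "b"), ("c",)}
        # path property: tokens along root->tip reproduce the haplotype
        for tip in tree.tips():
            toks = {str(v) for v in tree.path_mutations(tip)}
            assert toks == set(haps[tip.name])
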