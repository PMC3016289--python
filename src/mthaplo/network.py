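"""Median networks and most-parsimonious tree extraction.

Reconstruction proceeds in the classical two steps used for mtDNA
haplogroups: first a median-joining network summarises the haplotypes
(minimum-spanning network plus inferred median haplotypes), then a rooted
most-parsimonious tree embeddable in the network is extracted. The hand
"branching order" step of traditional analyses is replaced by an exact
minimum Steiner-tree search (Dreyfus-Wagner dynamic programme) over the
network, with optional hard monophyly constraints and a manual-override
hook that honours a user-supplied nested branching order exactly.

Haplotypes are frozensets of mutation tokens ("16189", "16183C", ...);
positions can be down-weighted (mutational hotspots such as 16189 and 16311)
so that recurrent changes at fast sites are preferred when explaining
reticulations.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx

from .tree import MutationTree, Node
from .variants import SequenceProfile, parse_mutation

log = logging.getLogger("mthaplo")

Haplotype = frozenset  # of mutation tokens (str)

_POS_RE = re.compile(r"^(\d+)")


def _token_position(token: str) -> int:
    m = _POS_RE.match(token)
    if not m:
        raise ValueError(f"bad mutation token {token!r}")
    return int(m.group(1))


def _sort_key(h: Haplotype) -> tuple:
    return tuple(sorted((_token_position(t), t) for t in h))


class PositionWeights:
    """Per-position weights; hotspots are down-weighted.

    The default scheme follows common practice for control-region data:
    weight 10 per position, 5 for listed hotspots (exposed as floats so a
    unit/half scheme works equally).
    """

    def __init__(self, default: float = 10.0,
                 hotspots: Optional[dict[int, float] | Iterable[int]] = None,
                 hotspot_weight: float = 5.0):
        self.default = float(default)
        if hotspots is None:
            self.table: dict[int, float] = {}
        elif isinstance(hotspots, dict):
            self.table = {int(k): float(v) for k, v in hotspots.items()}
        else:
            self.table = {int(p): float(hotspot_weight) for p in hotspots}

    def of_token(self, token: str) -> float:
        return self.table.get(_token_position(token), self.default)

    def distance(self, a: Haplotype, b: Haplotype) -> float:
        return sum(self.of_token(t) for t in a ^ b)


UNIT_WEIGHTS = PositionWeights(default=1.0)


def condense_haplotypes(profiles: Sequence[SequenceProfile],
                        include_indels: bool = False
                        ) -> list[tuple[Haplotype, int, list[str]]]:
    """Collapse profiles to unique haplotypes with multiplicities.

    Returns (haplotype tokens, multiplicity, sample ids), deterministically
    ordered. Indels are excluded from the haplotype by default (they are
    excluded from dating; including them is an option for display).
    """
    groups: dict[Haplotype, list[str]] = {}
    for p in profiles:
        variants = p.variants if include_indels else p.substitutions
        h = frozenset(str(v) for v in variants)
        groups.setdefault(h, []).append(p.sample_id)
    out = [(h, len(ids), sorted(ids)) for h, ids in groups.items()]
    out.sort(key=lambda item: _sort_key(item[0]))
    return out


@dataclass
class HaplotypeNetwork:
    """Unit-edge haplotype graph: every edge changes exactly one position."""

    graph: nx.Graph                      # nodes are Haplotype frozensets
    observed: dict[Haplotype, list[str]]  # haplotype -> sample ids
    weights: PositionWeights
    epsilon: float = 0.0

    def edge_weight(self, u: Haplotype, v: Haplotype) -> float:
        return self.graph.edges[u, v]["weight"]

    def to_graphml(self, path) -> None:
        g = nx.relabel_nodes(
            self.graph, {h: " ".join(sorted(h, key=_token_position)) or "ref"
                         for h in self.graph})
        for _, _, d in g.edges(data=True):
            d.pop("token", None) if not isinstance(d.get("token"), str) else None
        nx.write_graphml(g, path)


def _add_unit_path(g: nx.Graph, u: Haplotype, v: Haplotype,
                   weights: PositionWeights) -> None:
    """Connect u and v through intermediate nodes, one mutation per edge.

    Tokens are toggled in deterministic (position, token) order so repeated
    runs produce identical intermediate haplotypes.
    """
    diff = sorted(u ^ v, key=lambda t: (_token_position(t), t))
    cur = u
    for i, tok in enumerate(diff):
        nxt = v if i == len(diff) - 1 else (cur ^ {tok})
        g.add_node(cur)
        g.add_node(nxt)
        g.add_edge(cur, nxt, weight=weights.of_token(tok), token=tok)
        cur = nxt


def _msn_links(nodes: list[Haplotype], weights: PositionWeights,
               epsilon: float) -> list[tuple[Haplotype, Haplotype]]:
    """Minimum-spanning-network links with tolerance epsilon (Kruskal sweep).

    A pair is linked if its distance does not exceed (by more than epsilon)
    the smallest distance at which its two components become connectable.
    """
    pairs = []
    for a, b in itertools.combinations(nodes, 2):
        pairs.append((weights.distance(a, b), a, b))
    pairs.sort(key=lambda x: (x[0], _sort_key(x[1]), _sort_key(x[2])))
    parent = list(range(len(nodes)))
    idx = {n: i for i, n in enumerate(nodes)}

    def root(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    links = []
    # group distances; a link is kept if components were separate at d - epsilon
    joined_at: dict[tuple[int, int], float] = {}
    for d, a, b in pairs:
        ra, rb = root(idx[a]), root(idx[b])
        if ra != rb:
            links.append((a, b))
            parent[ra] = rb
        else:
            # already connected: keep if within epsilon of the distance at
            # which the components first joined
            if epsilon > 0 and d <= _join_distance(a, b, links, weights) + epsilon:
                links.append((a, b))
    return links


def _join_distance(a, b, links, weights) -> float:
    """Largest link weight on the current network path between a and b."""
    g = nx.Graph()
    for u, v in links:
        g.add_edge(u, v, weight=weights.distance(u, v))
    try:
        path = nx.shortest_path(g, a, b, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return float("inf")
    return max(weights.distance(u, v) for u, v in zip(path, path[1:]))


def _majority_median(a: Haplotype, b: Haplotype, c: Haplotype) -> Haplotype:
    tally: dict[str, int] = {}
    for h in (a, b, c):
        for t in h:
            tally[t] = tally.get(t, 0) + 1
    return frozenset(t for t, k in tally.items() if k >= 2)


def build_mj_network(haplotypes: Sequence[Haplotype] | Sequence[tuple],
                     epsilon: float = 0.0,
                     weights: Optional[PositionWeights] = None,
                     max_median_rounds: int = 50) -> HaplotypeNetwork:
    """Median-joining network over the given haplotypes.

    Accepts raw haplotype frozensets or the (haplotype, multiplicity, ids)
    triples produced by :func:`condense_haplotypes`. Iteratively augments the
    minimum spanning network with majority medians of linked triplets until
    no median shortens the network, then emits a unit-edge graph (multi-step
    links are subdivided through deterministic intermediate haplotypes).
    """
    weights = weights or UNIT_WEIGHTS
    observed: dict[Haplotype, list[str]] = {}
    for item in haplotypes:
        if isinstance(item, tuple):
            h, _, ids = item
            observed[h] = list(ids)
        else:
            observed.setdefault(frozenset(item), [])
    if len(observed) < 2:
        raise ValueError("need at least 2 distinct haplotypes")

    nodes = sorted(observed, key=_sort_key)
    for _ in range(max_median_rounds):
        links = _msn_links(nodes, weights, epsilon)
        linked = nx.Graph(links)
        # candidate medians of triplets that share at least two MSN links,
        # scored by their connection cost; only lambda-minimal candidates
        # (within epsilon) are admitted per round, as in median joining
        candidates: dict[Haplotype, float] = {}
        for u, v in links:
            for w in nodes:
                if w is u or w is v:
                    continue
                if not (linked.has_edge(u, w) or linked.has_edge(v, w)):
                    continue
                m = _majority_median(u, v, w)
                if m in observed or m in nodes:
                    continue
                lam = (weights.distance(m, u) + weights.distance(m, v)
                       + weights.distance(m, w))
                if m not in candidates or lam < candidates[m]:
                    candidates[m] = lam
        if not candidates:
            break
        lam_min = min(candidates.values())
        new_medians = {m for m, lam in candidates.items()
                       if lam <= lam_min + epsilon}
        nodes = sorted(set(nodes) | new_medians, key=_sort_key)
        # prune obsolete medians: unobserved nodes not on any MSN link
        links = _msn_links(nodes, weights, epsilon)
        used = {n for l in links for n in l}
        nodes = sorted((set(nodes) & used) | set(observed), key=_sort_key)

    links = _msn_links(nodes, weights, epsilon)
    g = nx.Graph()
    for n in nodes:
        g.add_node(n)
    for u, v in links:
        _add_unit_path(g, u, v, weights)
    net = HaplotypeNetwork(g, observed, weights, epsilon)
    for h, ids in observed.items():
        net.graph.add_node(h)
        net.graph.nodes[h]["observed"] = True
    return net


def median_closure(haplotypes: Sequence[Haplotype] | Sequence[tuple],
                   weights: Optional[PositionWeights] = None,
                   max_nodes: int = 4096,
                   include: Iterable[Haplotype] = ()) -> HaplotypeNetwork:
    """Full median network: close the haplotype set under majority medians.

    For (effectively binary) mtDNA variant data the median network contains
    every most-parsimonious tree, so it is the safest substrate for exact
    tree extraction; it can grow exponentially with the number of
    incompatible sites, hence the node cap. Pass the intended root/outgroup
    haplotype through ``include`` so the closure is computed over it too —
    attaching it afterwards can exclude globally optimal trees.
    """
    weights = weights or UNIT_WEIGHTS
    observed: dict[Haplotype, list[str]] = {}
    for item in haplotypes:
        if isinstance(item, tuple):
            h, _, ids = item
            observed[h] = list(ids)
        else:
            observed.setdefault(frozenset(item), [])
    closed = set(observed) | {frozenset(h) for h in include}
    frontier = True
    while frontier:
        frontier = False
        for a, b, c in itertools.combinations(sorted(closed, key=_sort_key), 3):
            m = _majority_median(a, b, c)
            if m not in closed:
                closed.add(m)
                frontier = True
                if len(closed) > max_nodes:
                    raise RuntimeError("median closure exceeded the node cap")
    g = nx.Graph()
    nodes = sorted(closed, key=_sort_key)
    for n in nodes:
        g.add_node(n)
    for a, b in itertools.combinations(nodes, 2):
        if len(a ^ b) == 1:
            tok = next(iter(a ^ b))
            g.add_edge(a, b, weight=weights.of_token(tok), token=tok)
    # characters with identical splits leave multi-mutation gaps: bridge the
    # remaining components along minimum-spanning links, one mutation per edge
    for u, v in _msn_links(nodes, weights, 0.0):
        if not nx.has_path(g, u, v):
            _add_unit_path(g, u, v, weights)
    net = HaplotypeNetwork(g, observed, weights, epsilon=float("inf"))
    for h in observed:
        net.graph.nodes[h]["observed"] = True
    return net


def hypercube_network(haplotypes: Sequence[Haplotype] | Sequence[tuple],
                      weights: Optional[PositionWeights] = None,
                      include: Iterable[Haplotype] = (),
                      max_sites: int = 8) -> HaplotypeNetwork:
    """The full unit hypercube over the segregating mutation tokens.

    Tree extraction restricted to a median(-joining) network minimises length
    among trees embeddable in THAT network, which can exceed the
    unconstrained most-parsimonious length (median hulls do not always
    contain a globally optimal Steiner tree). The hypercube over all
    segregating tokens contains every possible ancestral haplotype, so
    extraction over it is globally exact; its size is 2^sites, hence the
    site cap — intended for small instances and oracle-grade analyses.
    """
    weights = weights or UNIT_WEIGHTS
    observed: dict[Haplotype, list[str]] = {}
    for item in haplotypes:
        if isinstance(item, tuple):
            h, _, ids = item
            observed[h] = list(ids)
        else:
            observed.setdefault(frozenset(item), [])
    base = frozenset.intersection(*observed.keys(), *[frozenset(h) for h in include]) \
        if include else frozenset.intersection(*observed.keys())
    tokens = sorted({t for h in observed for t in h - base}
                    | {t for h in include for t in frozenset(h) - base},
                    key=lambda t: (_token_position(t), t))
    if len(tokens) > max_sites:
        raise ValueError(
            f"{len(tokens)} segregating tokens exceed the hypercube cap "
            f"({max_sites}); use a median network instead")
    g = nx.Graph()
    for r in range(len(tokens) + 1):
        for combo in itertools.combinations(tokens, r):
            g.add_node(base | frozenset(combo))
    for node in list(g.nodes):
        for tok in tokens:
            other = node ^ {tok}
            if not g.has_edge(node, other):
                g.add_edge(node, other, weight=weights.of_token(tok), token=tok)
    net = HaplotypeNetwork(g, observed, weights, epsilon=float("inf"))
    for h in observed:
        net.graph.nodes[h]["observed"] = True
    return net


# ---------------------------------------------------------------------------
# exact Steiner-tree extraction (Dreyfus-Wagner) with monophyly constraints
# ---------------------------------------------------------------------------

def _all_pairs(g: nx.Graph):
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    paths = dict(nx.all_pairs_dijkstra_path(g, weight="weight"))
    return dist, paths


def _dreyfus_wagner(g: nx.Graph, terminal_costs: list[dict],
                    dist, paths) -> tuple[dict, dict]:
    """DP[(mask, v)] = min cost of a tree spanning terminal set `mask` + v.

    Each terminal is a cost dict {node: attachment cost} (a real terminal t
    is {v: dist[t][v]}); this uniformly supports "virtual" terminals that
    stand for pre-solved constrained subtrees. Returns the DP table and
    backpointers for reconstruction.
    """
    nodes = sorted(g.nodes, key=_sort_key)
    k = len(terminal_costs)
    DP: dict[tuple[int, Haplotype], float] = {}
    back: dict[tuple[int, Haplotype], tuple] = {}
    for i, costs in enumerate(terminal_costs):
        for v in nodes:
            DP[(1 << i, v)] = costs[v]
            back[(1 << i, v)] = ("leaf", i)
    for mask in range(1, 1 << k):
        if mask & (mask - 1) == 0:
            continue
        # merge two sub-forests at v
        for v in nodes:
            best, bb = float("inf"), None
            sub = (mask - 1) & mask
            while sub:
                if sub < (mask ^ sub):  # enumerate each split once
                    c = DP[(sub, v)] + DP[(mask ^ sub, v)]
                    if c < best:
                        best, bb = c, ("split", sub)
                sub = (sub - 1) & mask
            DP[(mask, v)] = best
            back[(mask, v)] = bb
        # grow along shortest paths (single Dijkstra-like relaxation suffices
        # because dist is a metric closure)
        for v in nodes:
            for u in nodes:
                c = DP[(mask, u)] + dist[u].get(v, float("inf"))
                if c < DP[(mask, v)] - 1e-12:
                    DP[(mask, v)] = c
                    back[(mask, v)] = ("move", u)
    return DP, back


def _collect_edges(back, paths, mask, v, leaf_handlers, ns, edges, glues):
    kind = back[(mask, v)]
    if kind[0] == "leaf":
        leaf_handlers[kind[1]](v, edges, glues)
        return
    if kind[0] == "split":
        sub = kind[1]
        _collect_edges(back, paths, sub, v, leaf_handlers, ns, edges, glues)
        _collect_edges(back, paths, mask ^ sub, v, leaf_handlers, ns, edges, glues)
        return
    if kind[0] == "move":
        u = kind[1]
        p = paths[u][v]
        for a, b in zip(p, p[1:]):
            edges.add((ns, frozenset((a, b))))
        _collect_edges(back, paths, mask, u, leaf_handlers, ns, edges, glues)


@dataclass
class Constraint:
    """A named clade whose samples must form a monophyletic group."""

    name: str
    sample_ids: frozenset[str]


def _validate_nesting(constraints: Sequence[Constraint]) -> list[Constraint]:
    for a, b in itertools.combinations(constraints, 2):
        inter = a.sample_ids & b.sample_ids
        if inter and not (a.sample_ids <= b.sample_ids
                          or b.sample_ids <= a.sample_ids):
            raise ValueError(
                f"constraints {a.name!r} and {b.name!r} overlap without nesting"
            )
    # innermost first
    return sorted(constraints, key=lambda c: len(c.sample_ids))


def extract_parsimony_tree(network: HaplotypeNetwork,
                           root_profile: Haplotype | Iterable[str],
                           constraints: Sequence[Constraint] = (),
                           name: str = "mp-tree",
                           exact_max_terminals: int = 9,
                           exact_max_nodes: int = 400) -> MutationTree:
    """Extract a minimum-weight rooted tree embeddable in the network.

    The tree connects every observed haplotype and the root haplotype using
    network edges only, with total edge weight minimised exactly
    (Dreyfus-Wagner over the unit-edge graph) while the problem is small
    (at most ``exact_max_terminals`` haplotype groups over at most
    ``exact_max_nodes`` network nodes); beyond that a Steiner-tree
    approximation (Mehlhorn) is used, which remains embeddable and
    constraint-respecting but is no longer guaranteed minimal. Monophyly constraints are
    honoured by solving each constrained clade as a nested Steiner problem
    over its own copy of the latent network (excluding haplotypes observed
    outside the clade) that attaches to the rest of the tree at a single
    haplotype; an unsatisfiable constraint raises with the clade name. Ties
    are broken deterministically (nodes processed in sorted token order).

    Samples hang from their haplotype node as zero-mutation tips, so the
    returned :class:`MutationTree` is directly usable for rho dating.
    """
    g = network.graph
    INF = float("inf")
    root = frozenset(root_profile)
    if root not in g:
        # attach the outgroup/root haplotype to its nearest network node
        nearest = min(g.nodes, key=lambda n: (network.weights.distance(root, n),
                                              _sort_key(n)))
        _add_unit_path(g, root, nearest, network.weights)
    if not nx.is_connected(g):
        raise ValueError("network is not connected")

    sample_to_hap = {}
    for h, ids in network.observed.items():
        for sid in ids:
            sample_to_hap[sid] = h

    ordered = _validate_nesting(list(constraints))
    for con in ordered:
        missing = con.sample_ids - set(sample_to_hap)
        if missing:
            raise ValueError(
                f"constraint {con.name!r}: unknown samples {sorted(missing)}")
        for sid in con.sample_ids:
            outside = set(network.observed[sample_to_hap[sid]]) - con.sample_ids
            if outside:
                raise ValueError(
                    f"constraint {con.name!r} unsatisfiable: haplotype shared "
                    f"with samples {sorted(outside)}")
    all_constrained = {sid for con in ordered for sid in con.sample_ids}
    if set(network.observed.get(root, ())) & all_constrained:
        raise ValueError("the root haplotype cannot sit inside a constraint")

    def solve_group(gsub: nx.Graph, ns: str, haps: list[Haplotype],
                    virtuals: list[tuple[str, dict, object]]):
        """Solve one Steiner group; returns (cost-per-node, builder).

        ``builder(v, edges, glues)`` reconstructs the group's edges in
        namespace ``ns`` with the tree glued to the outside world at v.
        Small groups are solved exactly (Dreyfus-Wagner); larger ones fall
        back to the Mehlhorn Steiner approximation with local attachment.
        """
        k = len(haps) + len(virtuals)
        if k <= exact_max_terminals and gsub.number_of_nodes() <= exact_max_nodes:
            return _solve_exact(gsub, ns, haps, virtuals)
        return _solve_approx(gsub, ns, haps, virtuals)

    def _solve_exact(gsub, ns, haps, virtuals):
        dist = dict(nx.all_pairs_dijkstra_path_length(gsub, weight="weight"))
        paths = dict(nx.all_pairs_dijkstra_path(gsub, weight="weight"))
        terminal_costs, handlers = [], []
        for t in haps:
            terminal_costs.append({v: dist[t].get(v, INF) for v in gsub.nodes})

            def handler(v, edges, glues, t=t):
                p = paths[t][v]
                for a, b in zip(p, p[1:]):
                    edges.add((ns, frozenset((a, b))))
            handlers.append(handler)
        for vns, vcost, vbuild in virtuals:
            terminal_costs.append({v: vcost.get(v, INF) for v in gsub.nodes})

            def handler(v, edges, glues, vns=vns, vbuild=vbuild):
                glues.append((vns, v, ns))
                vbuild(v, edges, glues)
            handlers.append(handler)
        DP, back = _dreyfus_wagner(gsub, terminal_costs, dist, paths)
        full = (1 << len(terminal_costs)) - 1
        costd = {v: DP[(full, v)] for v in gsub.nodes}

        def builder(v, edges, glues):
            _collect_edges(back, paths, full, v, handlers, ns, edges, glues)
        return costd, builder

    def _solve_approx(gsub, ns, haps, virtuals):
        from networkx.algorithms.approximation import steiner_tree

        # realise each virtual terminal at its cheapest attachment node
        realized = []
        for vns, vcost, vbuild in virtuals:
            vbest = min(sorted(gsub.nodes, key=_sort_key),
                        key=lambda v: vcost.get(v, INF))
            realized.append((vns, vbest, vcost[vbest], vbuild))
        term_nodes = list(dict.fromkeys(
            list(haps) + [r[1] for r in realized]))
        if len(term_nodes) == 1:
            T_edges, T_nodes = [], set(term_nodes)
            t_cost = 0.0
        else:
            T = steiner_tree(gsub, term_nodes, weight="weight",
                             method="mehlhorn")
            T_edges = list(T.edges)
            T_nodes = set(T.nodes)
            t_cost = T.size(weight="weight")
        base = t_cost + sum(r[2] for r in realized)
        dist_to_T, path_from_T = nx.multi_source_dijkstra(
            gsub, T_nodes, weight="weight")
        costd = {v: base + dist_to_T.get(v, INF) for v in gsub.nodes}

        def builder(v, edges, glues):
            for a, b in T_edges:
                edges.add((ns, frozenset((a, b))))
            p = path_from_T.get(v, [v])
            for a, b in zip(p, p[1:]):
                edges.add((ns, frozenset((a, b))))
            for vns, vbest, _, vbuild in realized:
                glues.append((vns, vbest, ns))
                vbuild(vbest, edges, glues)
        return costd, builder

    # innermost first; each entry: (constraint, costd, builder)
    solved: list[tuple[Constraint, dict, object]] = []
    for con in ordered:
        inner = [s for s in solved if s[0].sample_ids < con.sample_ids]
        own = con.sample_ids - {sid for s in inner for sid in s[0].sample_ids}
        haps = sorted({sample_to_hap[sid] for sid in own}, key=_sort_key)
        # the clade solves over the full graph: its edges live in the
        # clade's own namespace, so routing through a haplotype observed
        # elsewhere creates a distinct latent copy and cannot break
        # monophyly
        costd, builder = solve_group(g, con.name, haps,
                                     [(s[0].name, s[1], s[2]) for s in inner])
        solved = [s for s in solved if not (s[0].sample_ids < con.sample_ids)]
        solved.append((con, costd, builder))

    free_haps = sorted({h for h, ids in network.observed.items()
                        if set(ids) - all_constrained}, key=_sort_key)
    if root not in free_haps:
        free_haps = [root] + free_haps
    costd, builder = solve_group(g, "", free_haps,
                                 [(s[0].name, s[1], s[2]) for s in solved])
    best_v = min(sorted(g.nodes, key=_sort_key), key=lambda v: costd[v])
    if costd[best_v] == INF:
        names = ", ".join(c.name for c in ordered)
        raise ValueError(f"constraints [{names}] not satisfiable in the network")
    edges: set[tuple] = set()
    glues: list[tuple] = []
    builder(best_v, edges, glues)

    # ---- assemble the rooted MutationTree from the namespaced edges ------
    # each glue becomes an explicit zero-mutation stem edge, so a constrained
    # clade keeps its own ancestral node even when its Steiner junction
    # coincides with the attachment vertex
    tg = nx.Graph()
    tg.add_node(("", root))
    for ns, e in edges:
        a, b = tuple(e)
        tg.add_edge((ns, a), (ns, b), token=g.edges[a, b]["token"])
    for child_ns, v, parent_ns in glues:
        tg.add_edge((parent_ns, v), (child_ns, v), token=None, stem=child_ns)

    tree_root = Node("root")
    node_of = {("", root): tree_root}
    for a, b in nx.dfs_edges(tg, source=("", root)):
        data = tg.edges[a, b]
        if data["token"] is None:
            child = Node(mutations=[])  # constraint stem; named at its MRCA below
        else:
            child = Node(mutations=[parse_mutation(data["token"])])
        node_of[a].add(child)
        node_of[b] = child

    # hang samples off their haplotype node, in the innermost namespace
    # whose constraint contains them
    for h, ids in sorted(network.observed.items(), key=lambda kv: _sort_key(kv[0])):
        for sid in sorted(ids):
            ns = ""
            for con in ordered:  # ordered is innermost-first
                if sid in con.sample_ids:
                    ns = con.name
                    break
            key = (ns, h)
            if key not in node_of:  # pragma: no cover - terminals are spanned
                raise RuntimeError(f"haplotype of sample {sid!r} missing from tree")
            node_of[key].add(Node(sid))

    tree = MutationTree(tree_root, frozenset(), name)
    _prune_empty(tree)
    _verify_monophyly(tree, ordered)
    _name_constrained_clades(tree, ordered)
    return tree


def _prune_empty(tree: MutationTree) -> None:
    """Remove childless unnamed internal nodes and splice degree-1 chains.

    Latent haplotype nodes that ended up with a single child are merged into
    that child's branch (their mutations concatenate), keeping the tree tidy
    without changing any root-to-tip path.
    """
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node is tree.root:
                continue
            if node.is_tip and node.name is None:
                node.parent.children.remove(node)
                changed = True
            elif len(node.children) == 1 and node.name is None:
                child = node.children[0]
                child.mutations = node.mutations + child.mutations
                child.parent = node.parent
                node.parent.children[node.parent.children.index(node)] = child
                changed = True
        # root with single child: fold into the child
        while len(tree.root.children) == 1 and tree.root.name in (None, "root"):
            child = tree.root.children[0]
            if child.is_tip:
                break
            child.mutations = tree.root.mutations + child.mutations
            child.parent = None
            child.name = child.name or tree.root.name
            tree.root = child


def _verify_monophyly(tree: MutationTree, constraints: Sequence[Constraint]
                      ) -> None:
    tip_sets = {}
    for node in tree.preorder():
        tip_sets[id(node)] = frozenset(t.name for t in MutationTree(node).tips())
    for con in constraints:
        if not any(s == con.sample_ids for s in tip_sets.values()):
            raise ValueError(
                f"constraint {con.name!r} is not satisfiable in the network")


def _name_constrained_clades(tree: MutationTree,
                             constraints: Sequence[Constraint]) -> None:
    """Label each constraint's MRCA (the lowest node spanning exactly it)."""
    for con in constraints:
        mrca = None
        for node in tree.preorder():
            tips = frozenset(t.name for t in MutationTree(node).tips())
            if tips == con.sample_ids:
                mrca = node  # keep the deepest match
        if mrca is not None and mrca.name is None:
            mrca.name = con.name


def tree_length(tree: MutationTree,
                weights: Optional[PositionWeights] = None) -> float:
    """Weighted mutation count over all branches (unit weights -> count)."""
    weights = weights or UNIT_WEIGHTS
    total = 0.0
    for node in tree.preorder():
        for v in node.mutations:
            total += weights.table.get(v.position, weights.default)
    return total


def branching_order_tree(order_spec, haplotypes_by_sample: dict[str, Haplotype],
                         root_profile: Haplotype,
                         weights: Optional[PositionWeights] = None,
                         name: str = "manual-tree") -> MutationTree:
    """Honour a user-supplied nested branching order exactly.

    ``order_spec`` is a nested list structure of sample ids, e.g.
    ``["root", ["a", ["b", "c"]]]`` mirrors a hand-constructed tree. Branch
    mutation lists are filled with the token differences between each node's
    haplotype and its parent's inferred haplotype (parent haplotype =
    intersection-style consensus along the nesting).
    """
    weights = weights or UNIT_WEIGHTS

    def consensus(spec) -> Haplotype:
        if isinstance(spec, str):
            return haplotypes_by_sample[spec]
        subs = [consensus(s) for s in spec]
        out = set(subs[0])
        for s in subs[1:]:
            out &= set(s)
        return frozenset(out)

    def build(spec, parent_hap: Haplotype) -> Node:
        hap = consensus(spec)
        diff = sorted(hap ^ parent_hap, key=lambda t: (_token_position(t), t))
        node = Node(spec if isinstance(spec, str) else None,
                    mutations=[parse_mutation(t) for t in diff])
        if not isinstance(spec, str):
            for s in spec:
                node.add(build(s, hap))
        return node

    root = Node("root")
    for spec in order_spec:
        root.add(build(spec, root_profile))
    return MutationTree(root, frozenset(), name)
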