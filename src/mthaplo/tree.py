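"""Rooted trees whose branches carry explicit mutation lists.

A :class:`MutationTree` is the shared substrate for rho dating, maximum
likelihood branch fitting and Bayesian dating: a rooted tree in which every
branch (the edge above a node) records the mutations inferred on it, internal
nodes may be named after clades (haplogroup labels such as "U6a"), and tips
map to sample ids. Node times, when present, are in years before present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Optional

from .variants import VariantCall


class Node:
    """A tree node; ``mutations`` sit on the branch above the node."""

    __slots__ = ("name", "children", "parent", "mutations", "time", "length")

    def __init__(self, name: Optional[str] = None,
                 mutations: Optional[list[VariantCall]] = None,
                 time: Optional[float] = None,
                 length: Optional[float] = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.mutations: list[VariantCall] = list(mutations or [])
        self.time = time
        self.length = length

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"Node({self.name!r}, n_children={len(self.children)})"


@dataclass
class MutationTree:
    """Rooted clade tree with per-branch mutation lists.

    Invariant: concatenating branch mutations along the root-to-tip path, a
    position toggled an odd number of times differs from the root haplotype.
    The root haplotype itself is explicit (``root_profile``).
    """

    root: Node
    root_profile: frozenset[VariantCall] = frozenset()
    name: str = "tree"

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def find(self, name: str) -> Node:
        for node in self.preorder():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r} in tree {self.name!r}")

    def clade_tips(self, clade: str | Node) -> list[Node]:
        node = clade if isinstance(clade, Node) else self.find(clade)
        sub = MutationTree(node)
        return sub.tips()

    # -- path algebra ------------------------------------------------------
    def path_mutations(self, node: Node, ancestor: Optional[Node] = None
                       ) -> list[VariantCall]:
        """Mutations on the path from ``ancestor`` (default root) down to ``node``."""
        top = ancestor if ancestor is not None else self.root
        branches: list[list[VariantCall]] = []
        cur = node
        while cur is not top:
            if cur is None:
                raise ValueError("node is not a descendant of the given ancestor")
            branches.append(cur.mutations)
            cur = cur.parent
        out: list[VariantCall] = []
        for muts in reversed(branches):
            out.extend(muts)
        return out

    def tip_profile(self, tip: Node) -> frozenset[VariantCall]:
        """Variant profile of a tip: root profile plus path mutations replayed.

        Substitutions are replayed as base-state changes so that back
        mutations cancel and multi-hit chains (A>G then G>T) resolve to the
        final state; indels toggle presence. Positions hit an odd number of
        times by two-state toggling therefore differ from the root state.
        """
        from .variants import substitution_class

        # position -> (original/reference base, current base)
        subs: dict[int, tuple[str, str]] = {}
        indels: dict[tuple, VariantCall] = {}
        for v in self.root_profile:
            if v.is_substitution:
                subs[v.position] = (v.ref_base, v.alt_base)
            else:
                indels[(v.position, v.mclass)] = v
        for v in self.path_mutations(tip):
            if v.is_substitution:
                orig, _ = subs.get(v.position, (v.ref_base, v.ref_base))
                subs[v.position] = (orig, v.alt_base)
            else:
                key = (v.position, v.mclass)
                if key in indels:
                    del indels[key]
                else:
                    indels[key] = v
        out = set(indels.values())
        for pos, (orig, cur) in subs.items():
            if cur != orig:
                out.add(VariantCall(pos, orig, cur, substitution_class(orig, cur)))
        return frozenset(out)

    # -- editing / utilities ----------------------------------------------
    def copy(self) -> "MutationTree":
        def _copy(node: Node) -> Node:
            new = Node(node.name, list(node.mutations), node.time, node.length)
            for c in node.children:
                new.add(_copy(c))
            return new
        return MutationTree(_copy(self.root), self.root_profile, self.name)

    def n_tips(self) -> int:
        return len(self.tips())

    def total_mutations(self, predicate: Optional[Callable[[VariantCall], bool]] = None
                        ) -> int:
        pred = predicate or (lambda v: True)
        return sum(1 for n in self.preorder() for v in n.mutations if pred(v))

    def set_times_from_lengths(self) -> None:
        """Fill node times (years BP) from branch lengths, tips at time 0."""
        depth: dict[int, float] = {id(self.root): 0.0}
        maxd = 0.0
        for node in self.preorder():
            if node is self.root:
                continue
            d = depth[id(node.parent)] + (node.length or 0.0)
            depth[id(node)] = d
            maxd = max(maxd, d)
        for node in self.preorder():
            node.time = maxd - depth[id(node)]

    def set_lengths_from_times(self) -> None:
        for node in self.preorder():
            if node.parent is not None:
                node.length = node.parent.time - node.time


def resolve_polytomies(tree: MutationTree, seed: int = 0) -> MutationTree:
    """Binary-resolve multifurcations with zero-mutation internal nodes.

    Children are combined pairwise in a deterministic order derived from the
    seed; the inserted nodes carry no mutations so path mutation counts are
    unchanged.
    """
    import numpy as np
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.preorder()):
        while len(node.children) > 2:
            order = rng.permutation(len(node.children))[:2]
            picked = sorted(order, reverse=True)
            merged = Node()
            for i in picked:
                child = node.children.pop(i)
                merged.add(child)
            node.add(merged)
    return out


def assign_initial_times(tree: MutationTree,
                         years_per_mutation: float,
                         min_gap: float = 1.0) -> MutationTree:
    """Rough node times from mutation counts (for initialising samplers).

    A node's age is the mean root-to-tip mutation count below it times the
    per-mutation clock, forced strictly older than its children by
    ``min_gap`` years. Tips sit at 0.
    """
    out = tree.copy()

    def depth(node: Node) -> float:
        if node.is_tip:
            node.time = 0.0
            return 0.0
        ages = []
        for c in node.children:
            d = depth(c)
            ages.append(d + len(c.mutations) * years_per_mutation)
        node.time = max(max(ages),
                        max(c.time for c in node.children) + min_gap)
        return node.time

    depth(out.root)
    out.set_lengths_from_times()
    return out


def star_tree(counts_or_profiles, root_profile: frozenset = frozenset(),
              name: str = "star") -> MutationTree:
    """Build a star tree from per-tip transition counts or mutation lists.

    Integer counts expand to that many distinct dummy transitions; lists of
    :class:`VariantCall` are attached verbatim. Convenient for worked
    examples and closed-form checks.
    """
    from .variants import VariantCall

    root = Node("root")
    pos = 1
    for i, item in enumerate(counts_or_profiles):
        if isinstance(item, int):
            muts = []
            for _ in range(item):
                muts.append(VariantCall(pos, "A", "G"))
                pos += 1
        else:
            muts = list(item)
        root.add(Node(f"tip{i + 1}", mutations=muts))
    return MutationTree(root, root_profile, name)
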