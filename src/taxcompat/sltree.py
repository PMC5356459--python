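"""Semi-labeled trees and the ancestral-compatibility calculus.

A semi-labeled tree is a rooted tree together with a labeling function
``phi`` mapping a label set onto the nodes.  Labels may sit on internal
nodes (higher-order taxa such as families or genera) as well as on leaves.
Every leaf, and every node with exactly one child (the root included),
must carry at least one label; nodes with two or more children may be
unlabeled.  Ordinary phylogenies and taxonomies are both special cases.

This module provides the data model plus the calculus used everywhere
else as a verification oracle: cluster sets, restriction, the ordered
descendant-pair set D and the unordered incomparable-pair set N, and the
"ancestrally displays" relation (D/N containment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

AUX_PREFIX = "__aux"


class TreeError(ValueError):
    """Raised on malformed semi-labeled trees or invalid operation inputs."""


@dataclass(frozen=True)
class SemiLabeledTree:
    """A rooted semi-labeled tree.

    Nodes are opaque integer identities.  ``children`` maps every node to
    its (ordered, semantically orderless) child tuple; ``labels_of`` maps
    every node to its (possibly empty) frozen label set.
    """

    root: int
    children: Mapping[int, tuple[int, ...]]
    labels_of: Mapping[int, frozenset[str]]

    # -- derived views -------------------------------------------------

    def nodes(self) -> list[int]:
        return list(self.children)

    @property
    def parent(self) -> dict[int, int | None]:
        try:
            return self._parent_cache  # type: ignore[attr-defined]
        except AttributeError:
            p: dict[int, int | None] = {self.root: None}
            for u, ch in self.children.items():
                for c in ch:
                    p[c] = u
            object.__setattr__(self, "_parent_cache", p)
            return p

    @property
    def node_of(self) -> dict[str, int]:
        """phi: label -> node.  Fails on duplicate labels within the tree."""
        try:
            return self._node_of_cache  # type: ignore[attr-defined]
        except AttributeError:
            m: dict[str, int] = {}
            for u, labs in self.labels_of.items():
                for lab in labs:
                    if lab in m:
                        raise TreeError(f"label {lab!r} appears on two nodes")
                    m[lab] = u
            object.__setattr__(self, "_node_of_cache", m)
            return m

    @property
    def label_set(self) -> frozenset[str]:
        return frozenset(self.node_of)

    def n_nodes(self) -> int:
        return len(self.children)

    def n_edges(self) -> int:
        return len(self.children) - 1

    def postorder(self) -> Iterator[int]:
        """Iterative post-order traversal (safe on deep chains)."""
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            u, expanded = stack.pop()
            if expanded:
                yield u
            else:
                stack.append((u, True))
                for c in reversed(self.children[u]):
                    stack.append((c, False))

    def preorder(self) -> Iterator[int]:
        stack = [self.root]
        while stack:
            u = stack.pop()
            yield u
            for c in reversed(self.children[u]):
                stack.append(c)

    def depths(self) -> dict[int, int]:
        d = {self.root: 0}
        for u in self.preorder():
            for c in self.children[u]:
                d[c] = d[u] + 1
        return d


def build(spec) -> SemiLabeledTree:
    """Build a tree from a nested shorthand.

    ``spec`` is either a bare label (a leaf), or a pair
    ``(label_or_None, [child_specs])``.  Example::

        build(("1", [("3", [("a", ["b", "c"]), "d", "e"]), "f"]))
    """
    children: dict[int, tuple[int, ...]] = {}
    labels: dict[int, frozenset[str]] = {}
    counter = itertools.count()

    def walk(s) -> int:
        u = next(counter)
        if isinstance(s, str):
            labels[u] = frozenset([s])
            children[u] = ()
            return u
        lab, kids = s
        labels[u] = frozenset() if lab is None else frozenset([lab])
        children[u] = tuple(walk(k) for k in kids)
        return u

    root = walk(spec)
    return SemiLabeledTree(root=root, children=children, labels_of=labels)


@dataclass(frozen=True)
class Profile:
    """An ordered collection of semi-labeled trees over overlapping labels."""

    trees: tuple[SemiLabeledTree, ...]

    def __init__(self, trees: Iterable[SemiLabeledTree]):
        object.__setattr__(self, "trees", tuple(trees))

    @property
    def label_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= t.label_set
        return frozenset(out)

    @property
    def size_MP(self) -> int:
        """Total node count plus edge count across the profile."""
        return sum(t.n_nodes() + t.n_edges() for t in self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# The compatibility calculus
# ---------------------------------------------------------------------------

def clusters(tree: SemiLabeledTree) -> frozenset[frozenset[str]]:
    """The cluster set Cl(T): for each node u, the labels in u's subtree."""
    acc: dict[int, frozenset[str]] = {}
    out: set[frozenset[str]] = set()
    for u in tree.postorder():
        x = set(tree.labels_of[u])
        for c in tree.children[u]:
            x |= acc[c]
        acc[u] = frozenset(x)
        out.add(acc[u])
    return frozenset(out)


def restrict(tree: SemiLabeledTree, subset: Iterable[str]) -> SemiLabeledTree:
    """Restrict ``tree`` to a nonempty label subset.

    Takes the minimal rooted subtree connecting the nodes carrying labels
    in ``subset`` and suppresses every node of degree two that carries no
    retained label.  The result's cluster set equals
    ``{X & subset : X in Cl(tree), X & subset nonempty}``.
    """
    A = frozenset(subset)
    if not A:
        raise TreeError("restriction subset must be nonempty")
    missing = A - tree.label_set
    if missing:
        raise TreeError(f"labels not in tree: {sorted(missing)}")

    # Count retained labels below each node (bottom-up).
    cnt: dict[int, int] = {}
    for u in tree.postorder():
        cnt[u] = len(tree.labels_of[u] & A) + sum(cnt[c] for c in tree.children[u])

    # Descend to the root of the minimal subtree: the highest node that
    # either carries a retained label or branches over retained labels.
    r = tree.root
    while not (tree.labels_of[r] & A):
        live = [c for c in tree.children[r] if cnt[c] > 0]
        if len(live) != 1:
            break
        r = live[0]

    # Rebuild with suppression: a node survives if it carries a retained
    # label or keeps >= 2 live children (or is the new root).
    return _emit_iterative(tree, cnt, A, r)


def _emit_iterative(tree: SemiLabeledTree, cnt: dict[int, int],
                    A: frozenset[str], r: int) -> SemiLabeledTree:
    children: dict[int, tuple[int, ...]] = {}
    labels: dict[int, frozenset[str]] = {}
    counter = itertools.count()

    def resolve(u: int) -> int:
        # Skip unlabeled pass-through nodes (single live child, no label).
        while True:
            labs = tree.labels_of[u] & A
            live = [c for c in tree.children[u] if cnt[c] > 0]
            if labs or len(live) != 1:
                return u
            u = live[0]

    root_orig = resolve(r)
    id_of: dict[int, int] = {}
    stack = [root_orig]
    order: list[int] = []
    kids_of: dict[int, list[int]] = {}
    while stack:
        u = stack.pop()
        nid = next(counter)
        id_of[u] = nid
        order.append(u)
        kids = [resolve(c) for c in tree.children[u] if cnt[c] > 0]
        kids_of[u] = kids
        stack.extend(kids)
    for u in order:
        nid = id_of[u]
        labels[nid] = tree.labels_of[u] & A
        children[nid] = tuple(id_of[c] for c in kids_of[u])
    return SemiLabeledTree(root=id_of[root_orig], children=children,
                           labels_of=labels)


def desc_pairs(tree: SemiLabeledTree) -> frozenset[tuple[str, str]]:
    """D(T): ordered pairs (l, l') with phi(l') a proper descendant of phi(l).

    Co-located labels (same node) appear in no pair.
    """
    below: dict[int, frozenset[str]] = {}
    out: set[tuple[str, str]] = set()
    for u in tree.postorder():
        sub = set()
        for c in tree.children[u]:
            sub |= below[c]
        for lab in tree.labels_of[u]:
            for d in sub:
                out.add((lab, d))
        below[u] = frozenset(sub | tree.labels_of[u])
    return frozenset(out)


def incomp_pairs(tree: SemiLabeledTree) -> frozenset[frozenset[str]]:
    """N(T): unordered pairs of labels on incomparable nodes."""
    below: dict[int, frozenset[str]] = {}
    out: set[frozenset[str]] = set()
    for u in tree.postorder():
        ch_sets = [below[c] for c in tree.children[u]]
        for i in range(len(ch_sets)):
            for j in range(i + 1, len(ch_sets)):
                for a in ch_sets[i]:
                    for b in ch_sets[j]:
                        out.add(frozenset((a, b)))
        sub = set(tree.labels_of[u])
        for s in ch_sets:
            sub |= s
        below[u] = frozenset(sub)
    return frozenset(out)


def ancestrally_displays(big: SemiLabeledTree, small: SemiLabeledTree) -> bool:
    """True iff D(small) <= D(big) and N(small) <= N(big).

    This is the certificate check applied to every supertree the engines
    produce.  ``big`` may be multiply labeled (supertree output); labels
    sharing one node of ``big`` are mutually comparable-equal, so a pair
    of ``small`` that is strictly nested or incomparable must map to
    distinct, suitably related nodes of ``big``.
    """
    if not small.label_set <= big.label_set:
        raise TreeError("label set of the displayed tree must be contained "
                        "in the display candidate's")
    node_of = big.node_of
    tin: dict[int, int] = {}
    tout: dict[int, int] = {}
    t = 0
    stack: list[tuple[int, bool]] = [(big.root, False)]
    while stack:
        u, done = stack.pop()
        if done:
            tout[u] = t
            t += 1
            continue
        tin[u] = t
        t += 1
        stack.append((u, True))
        for c in big.children[u]:
            stack.append((c, False))

    def is_proper_anc(a: int, b: int) -> bool:
        return a != b and tin[a] <= tin[b] and tout[b] <= tout[a]

    for (l1, l2) in desc_pairs(small):
        a, b = node_of[l1], node_of[l2]
        if not is_proper_anc(a, b):
            return False
    for pair in incomp_pairs(small):
        l1, l2 = tuple(pair)
        a, b = node_of[l1], node_of[l2]
        if a == b or is_proper_anc(a, b) or is_proper_anc(b, a):
            return False
    return True


def isomorphic(t1: SemiLabeledTree, t2: SemiLabeledTree) -> bool:
    """Cluster-set equality: a semi-labeled tree is determined by Cl(T)."""
    return t1.label_set == t2.label_set and clusters(t1) == clusters(t2)


def add_distinct_labels(profile: Profile) -> tuple[Profile, frozenset[str]]:
    """Fully label a profile by tagging every unlabeled node with a fresh label.

    Fresh labels use a reserved ``__aux`` prefix with a collision scan over
    the existing universe, so they are deterministic and strippable on
    output.  Compatibility is unchanged by this transformation, and any
    supertree for the augmented profile displays the original one.
    """
    universe = profile.label_universe
    counter = itertools.count()

    def fresh() -> str:
        while True:
            cand = f"{AUX_PREFIX}{next(counter)}"
            if cand not in universe:
                return cand

    added: set[str] = set()
    new_trees = []
    for t in profile.trees:
        new_labels = dict(t.labels_of)
        changed = False
        for u in t.children:
            if not new_labels[u]:
                lab = fresh()
                added.add(lab)
                new_labels[u] = frozenset([lab])
                changed = True
        if changed:
            new_trees.append(SemiLabeledTree(root=t.root, children=t.children,
                                             labels_of=new_labels))
        else:
            new_trees.append(t)
    return Profile(new_trees), frozenset(added)


def is_aux(label: str) -> bool:
    return label.startswith(AUX_PREFIX)


def validate(tree: SemiLabeledTree, require_full: bool = False,
             require_singular: bool = False) -> list[str]:
    """Check the semi-labeled tree invariants; violations are data, not errors."""
    out: list[str] = []
    seen: dict[str, int] = {}
    reachable: set[int] = set()
    stack = [tree.root]
    while stack:
        u = stack.pop()
        if u in reachable:
            out.append(f"node {u}: reached twice (not a tree)")
            continue
        reachable.add(u)
        stack.extend(tree.children.get(u, ()))
    for u in tree.children:
        if u not in reachable:
            out.append(f"node {u}: unreachable from root")
    for u, ch in tree.children.items():
        labs = tree.labels_of.get(u, frozenset())
        if len(ch) == 0 and not labs:
            out.append(f"node {u}: unlabeled leaf")
        if len(ch) == 1 and not labs:
            out.append(f"node {u}: unlabeled single-child node")
        if require_full and not labs:
            out.append(f"node {u}: unlabeled (full labeling required)")
        if require_singular and len(labs) > 1:
            out.append(f"node {u}: {len(labs)} labels (singular labeling "
                       "required)")
        for lab in labs:
            if lab in seen:
                out.append(f"label {lab!r}: on nodes {seen[lab]} and {u}")
            else:
                seen[lab] = u
    return out
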