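"""Ancestral-compatibility engine for profiles of semi-labeled trees.

The algorithm walks all input trees top-down in lockstep.  Its unit of
progress is a *position*: for each input tree, a frontier set of sibling
labels.  A label ``l`` is *semi-universal* at a position when every tree
containing ``l`` has frontier exactly ``{l}``; the set S of semi-universal
labels becomes the label set of the next supertree node.  Advancing
replaces each such frontier by the label's children and removes ``l``
from the display graph; the connected components of what remains are
independent subproblems.  If a live component ever has no semi-universal
label, the profile is incompatible — and only then.

Two engines are provided:

* :func:`buildnt_iterative` — the production engine.  A FIFO queue of
  component records mirrors the connected components of the shrinking
  display graph (one record per component, at every loop head).  Records
  carry a per-tree frontier map, per-label singleton counts, the set of
  currently semi-universal ("exposed") labels, and a weight equal to the
  sum of label multiplicities, so S is read off in O(|S|).  Edge
  deletions go through the dynamic-connectivity structure; when a
  component splits, the node-count-smaller side is scanned to compute
  weights and the weight-smaller side is rebuilt into a fresh record,
  giving the logarithmic amortization of the frontier bookkeeping.

* :func:`buildnt_recursive_reference` — a deliberately naive
  re-implementation (explicit position vectors, semi-universality by
  counting from scratch, components by breadth-first search) used as the
  cross-check oracle in the test-suite.

Both expect a fully and singularly labeled profile whose display graph
is connected; :func:`build_supertree` is the user-facing driver that
adds auxiliary labels and splits disconnected inputs first.
"""

from __future__ import annotations

import sys
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from . import displaygraph as dgmod
from .dyncon import DynamicConnectivity
from .sltree import (Profile, SemiLabeledTree, TreeError, add_distinct_labels,
                     is_aux, validate)


class EngineError(RuntimeError):
    pass


@dataclass
class SupertreeNode:
    """A node of the output supertree, labeled by a set of input labels."""

    label_set: frozenset[str]
    parent: "SupertreeNode | None" = None
    children: list = field(default_factory=list)

    def iter_nodes(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)


def supertree_to_sltree(root: SupertreeNode) -> SemiLabeledTree:
    """Flatten a supertree into the semi-labeled tree data model."""
    nodes = list(root.iter_nodes())
    ids = {id(n): i for i, n in enumerate(nodes)}
    children = {ids[id(n)]: tuple(ids[id(c)] for c in n.children)
                for n in nodes}
    labels = {ids[id(n)]: frozenset(n.label_set) for n in nodes}
    return SemiLabeledTree(root=ids[id(root)], children=children,
                           labels_of=labels)


@dataclass
class EngineStats:
    """Work counters for the amortized-cost accounting."""

    deletions: int = 0          # dyncon edge deletions
    field_updates: int = 0      # frontier/count/exposed mutations
    weight_scans: int = 0       # labels scanned while computing side weights
    moves: int = 0              # labels moved to a fresh record on splits


class ComponentRecord:
    """Bookkeeping for one connected component of the live display graph."""

    __slots__ = ("rep", "frontier_map", "exposed", "weight")

    def __init__(self, rep: str, frontier_map: dict[int, set[str]],
                 exposed: set[str], weight: int):
        self.rep = rep                      # any live member label
        self.frontier_map = frontier_map    # tree index -> U(i) & component
        self.exposed = exposed              # labels with count == k_l here
        self.weight = weight                # sum of k_l over members

    def position(self, k: int) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(self.frontier_map.get(i, ()))
                     for i in range(k))


def semi_universal_labels(record: ComponentRecord) -> frozenset[str]:
    """The candidate label set S; empty S signals incompatibility."""
    return frozenset(record.exposed)


class _Engine:
    """Shared state for one run of the iterative algorithm."""

    def __init__(self, profile: Profile, stats: EngineStats | None = None,
                 check_invariants: bool = False):
        self.profile = profile
        self.k = len(profile.trees)
        self.last_successor_position: tuple[frozenset[str], ...] | None = None
        self.stats = stats if stats is not None else EngineStats()
        self.check_invariants = check_invariants

        self.graph = dgmod.build_display_graph(profile)
        self.k_of = self.graph.multiplicity
        # label -> list of (tree index, node); and child labels per tree
        self.occurrences: dict[str, list[tuple[int, int]]] = {}
        for i, t in enumerate(profile.trees):
            for lab, node in t.node_of.items():
                self.occurrences.setdefault(lab, []).append((i, node))

        self.dc = DynamicConnectivity(self.graph.vertices)
        self.adj: dict[str, set[str]] = {
            v: set(self.graph.graph[v]) for v in self.graph.vertices}
        for u, v in self.graph.graph.edges:
            self.dc.dc_insert_edge(u, v)

        self.count: dict[str, int] = {lab: 0 for lab in self.graph.vertices}
        self.record_of: dict[str, ComponentRecord] = {}

    def children_of(self, i: int, lab: str) -> list[str]:
        t = self.profile.trees[i]
        node = t.node_of[lab]
        out = []
        for c in t.children[node]:
            (cl,) = t.labels_of[c]
            out.append(cl)
        return out

    # -- initialization ------------------------------------------------

    def init_root_record(self) -> ComponentRecord:
        fm: dict[int, set[str]] = {}
        for i, t in enumerate(self.profile.trees):
            (rl,) = t.labels_of[t.root]
            fm[i] = {rl}
            self.count[rl] += 1
            self.stats.field_updates += 2
        exposed = {lab for i, cell in fm.items() for lab in cell
                   if self.count[lab] == self.k_of[lab]}
        weight = sum(self.k_of[lab] for lab in self.graph.vertices)
        rec = ComponentRecord(rep=min(self.graph.vertices), frontier_map=fm,
                              exposed=exposed, weight=weight)
        for lab in self.graph.vertices:
            self.record_of[lab] = rec
        return rec

    # -- the split protocol -------------------------------------------

    def split_update(self, u: str, v: str) -> None:
        """Delete edge {u,v}; on a split, rebuild the weight-smaller side."""
        rec = self.record_of[u]
        report = self.dc.dc_delete_edge(u, v)
        self.adj[u].discard(v)
        self.adj[v].discard(u)
        self.stats.deletions += 1
        if report is None:
            return
        a, b = report.side_a, report.side_b
        # Scan the node-count-smaller side to compute both weights.
        if a.size < b.size:
            small, big = a, b
        elif b.size < a.size:
            small, big = b, a
        else:  # tie: the side holding the lexicographically smallest label
            ma = min(self.dc.dc_component_members(a.representative))
            mb = min(self.dc.dc_component_members(b.representative))
            small, big = (a, b) if ma < mb else (b, a)
        small_members = list(self.dc.dc_component_members(small.representative))
        w_small = sum(self.k_of[x] for x in small_members)
        self.stats.weight_scans += len(small_members)
        w_big = rec.weight - w_small
        # Move the weight-smaller side out into a fresh record.
        if w_small < w_big:
            light_members = small_members
            light_w, heavy_w = w_small, w_big
            heavy_rep = big.representative
        elif w_big < w_small:
            light_members = list(self.dc.dc_component_members(big.representative))
            light_w, heavy_w = w_big, w_small
            heavy_rep = small.representative
        else:  # weight tie: reuse the node-smaller side (already scanned)
            light_members = small_members
            light_w, heavy_w = w_small, w_big
            heavy_rep = big.representative
        new_rec = ComponentRecord(rep=min(light_members), frontier_map={},
                                  exposed=set(), weight=light_w)
        rec.weight = heavy_w
        rec.rep = heavy_rep
        count = self.count
        k_of = self.k_of
        for beta in light_members:
            self.record_of[beta] = new_rec
            self.stats.moves += 1
            for i, _node in self.occurrences[beta]:
                cell = rec.frontier_map.get(i)
                if cell is None or beta not in cell:
                    continue
                # remove beta from the inherited record's cell
                cell.discard(beta)
                self.stats.field_updates += 1
                if not cell:
                    del rec.frontier_map[i]
                    count[beta] -= 1
                    rec.exposed.discard(beta)
                    self.stats.field_updates += 2
                elif len(cell) == 1:
                    (gamma,) = cell
                    count[gamma] += 1
                    self.stats.field_updates += 1
                    if count[gamma] == k_of[gamma]:
                        rec.exposed.add(gamma)
                        self.stats.field_updates += 1
                # add beta to the fresh record's cell
                c1 = new_rec.frontier_map.get(i)
                if c1 is None:
                    new_rec.frontier_map[i] = {beta}
                    count[beta] += 1
                    self.stats.field_updates += 2
                    if count[beta] == k_of[beta]:
                        new_rec.exposed.add(beta)
                        self.stats.field_updates += 1
                else:
                    if len(c1) == 1:
                        (delta,) = c1
                        count[delta] -= 1
                        new_rec.exposed.discard(delta)
                        self.stats.field_updates += 2
                    c1.add(beta)
                    self.stats.field_updates += 1

    # -- advancing a position -----------------------------------------

    def successor_apply(self, record: ComponentRecord,
                        S: frozenset[str]) -> list[ComponentRecord]:
        """Advance ``record`` past its semi-universal labels S.

        Replaces each S-frontier by the label's children, deletes the
        labels and their incident edges from the graph, and returns the
        component records of what survives.
        """
        if not S or S != frozenset(record.exposed):
            raise EngineError("successor_apply requires S to be exactly the "
                              "semi-universal label set of the record")
        # Clear the S cells, then install the child sets.
        for lab in sorted(S):
            for i, _node in self.occurrences[lab]:
                del record.frontier_map[i]
                self.count[lab] -= 1
                self.stats.field_updates += 2
            record.exposed.discard(lab)
            self.stats.field_updates += 1
        for lab in sorted(S):
            for i, _node in self.occurrences[lab]:
                ch = self.children_of(i, lab)
                if not ch:
                    continue
                record.frontier_map[i] = set(ch)
                self.stats.field_updates += 1
                if len(ch) == 1:
                    alpha = ch[0]
                    self.count[alpha] += 1
                    self.stats.field_updates += 1
                    if self.count[alpha] == self.k_of[alpha]:
                        record.exposed.add(alpha)
                        self.stats.field_updates += 1
        self.last_successor_position = record.position(self.k)
        # Delete each consumed label's incident edges, then the label.
        by_id: dict[int, ComponentRecord] = {id(record): record}
        for lab in sorted(S):
            for nb in sorted(self.adj[lab]):
                self.split_update(lab, nb)
                for x in (lab, nb):
                    r = self.record_of[x]
                    by_id.setdefault(id(r), r)
            # lab is isolated now; discard it and its singleton component
            final = self.record_of.pop(lab)
            by_id.pop(id(final), None)
        return list(by_id.values())


def _assert_connected(graph: dgmod.DisplayGraph) -> None:
    comps = dgmod.static_components(graph)
    if len(comps) > 1:
        raise EngineError(
            f"display graph has {len(comps)} components; split the profile "
            "into label-disjoint sub-profiles first (see build_supertree)")


def buildnt_iterative(profile: Profile, *, stats: EngineStats | None = None,
                      trace: list | None = None,
                      check_invariants: bool = False) -> SupertreeNode | None:
    """Iterative engine: returns the supertree root, or None if incompatible.

    ``profile`` must be fully and singularly labeled with a connected
    display graph.  When ``trace`` is a list, one entry per dequeued
    component is appended: a dict with the position vector, S, the
    successor position, the resulting component member-sets, and the
    breadth-first level.
    """
    eng = _Engine(profile, stats=stats, check_invariants=check_invariants)
    _assert_connected(eng.graph)
    root_rec = eng.init_root_record()
    k = eng.k

    queue: deque[tuple[ComponentRecord, SupertreeNode | None, int]] = deque()
    queue.append((root_rec, None, 0))
    root_node: SupertreeNode | None = None

    while queue:
        if check_invariants:
            _check_queue_invariant(eng, queue)
        record, pred, level = queue.popleft()
        S = semi_universal_labels(record)
        entry = None
        if trace is not None:
            entry = {"level": level, "position": record.position(k), "S": S}
            trace.append(entry)
        if not S:
            return None  # incompatible
        node = SupertreeNode(label_set=S, parent=pred)
        if pred is not None:
            pred.children.append(node)
        else:
            root_node = node
        if len(S) == 1:
            (only,) = tuple(S)
            if all(not eng.children_of(i, only)
                   for i, _ in eng.occurrences[only]):
                # leaf shortcut: the component is the single label `only`
                eng.record_of.pop(only, None)
                if entry is not None:
                    entry["successor"] = record.position(k)
                    entry["components"] = []
                continue
        parts = eng.successor_apply(record, S)
        if entry is not None:
            entry["successor"] = eng.last_successor_position
            entry["components"] = [
                (frozenset(eng.dc.dc_component_members(p.rep)),
                 p.position(k)) for p in parts]
        for part in parts:
            queue.append((part, node, level + 1))
    return root_node


def _check_queue_invariant(eng: _Engine, queue) -> None:
    """Debug check: queue records correspond 1-1 to live graph components."""
    seen: set[frozenset[str]] = set()
    for rec, _, _ in queue:
        comp = frozenset(eng.dc.dc_component_members(rec.rep))
        if comp in seen:
            raise EngineError("two queue records share one component")
        seen.add(comp)
    covered: set[str] = set().union(*seen) if seen else set()
    if covered != set(eng.record_of):
        raise EngineError("queue does not cover the live label set")


def buildnt_recursive_reference(profile: Profile) -> SupertreeNode | None:
    """Naive recursive engine; the independent cross-check for the iterative one.

    Positions are explicit vectors, semi-universality is recomputed from
    scratch, and components come from breadth-first search on an explicit
    subgraph.  Returns the supertree root, or None if incompatible.
    """
    graph = dgmod.build_display_graph(profile)
    _assert_connected(graph)
    k = len(profile.trees)
    k_of = graph.multiplicity
    trees_of: dict[str, list[int]] = {}
    for i, t in enumerate(profile.trees):
        for lab in t.node_of:
            trees_of.setdefault(lab, []).append(i)

    def children_of(i: int, lab: str) -> list[str]:
        t = profile.trees[i]
        return [next(iter(t.labels_of[c]))
                for c in t.children[t.node_of[lab]]]

    g = graph.graph.copy()

    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 3 * graph.n_vertices() + 1000))
    try:
        def solve(U: tuple[frozenset[str], ...],
                  members: frozenset[str]) -> SupertreeNode | None:
            in_U = set().union(*U) if U else set()
            S = frozenset(
                lab for lab in in_U
                if all(U[i] == frozenset((lab,)) for i in trees_of[lab]))
            if not S:
                return None
            node = SupertreeNode(label_set=S)
            if len(S) == 1:
                (only,) = tuple(S)
                if all(not children_of(i, only) for i in trees_of[only]):
                    return node
            succ = list(U)
            for lab in S:
                for i in trees_of[lab]:
                    succ[i] = frozenset(children_of(i, lab))
            rest = members - S
            sub = g.subgraph(rest)
            for W in nx.connected_components(sub):
                W = frozenset(W)
                UW = tuple(frozenset(s & W) for s in succ)
                child = solve(UW, W)
                if child is None:
                    return None
                child.parent = node
                node.children.append(child)
            return node

        roots = tuple(frozenset(t.labels_of[t.root]) for t in profile.trees)
        return solve(roots, frozenset(graph.vertices))
    finally:
        sys.setrecursionlimit(limit)


def build_supertree(profile: Profile, *, engine: str = "iterative",
                    join_root: bool = True,
                    stats: EngineStats | None = None
                    ) -> SupertreeNode | None:
    """User-facing driver: validate, fully label, split, solve, join.

    Auxiliary labels added to unlabeled nodes remain in the returned
    supertree (the writer can strip them).  A disconnected display graph
    decomposes the profile into label-disjoint groups of whole trees;
    their supertrees are joined under a fresh unlabeled root when
    ``join_root`` is true, else a synthetic root labeled by nothing is
    still returned but callers may treat its children as a forest.
    Returns None when any sub-profile is incompatible.
    """
    for idx, t in enumerate(profile.trees):
        problems = validate(t, require_singular=True)
        if problems:
            raise TreeError(f"tree {idx} invalid: " + "; ".join(problems))
    full, _added = add_distinct_labels(profile)
    graph = dgmod.build_display_graph(full)
    comps = dgmod.static_components(graph)
    solver = {"iterative": lambda p: buildnt_iterative(p, stats=stats),
              "recursive": buildnt_recursive_reference}[engine]
    if len(comps) == 1:
        return solver(full)
    sub_roots = []
    for comp in comps:
        sub = Profile([t for t in full.trees if t.label_set <= comp])
        r = solver(sub)
        if r is None:
            return None
        sub_roots.append(r)
    joint = SupertreeNode(label_set=frozenset())
    for r in sub_roots:
        r.parent = joint
        joint.children.append(r)
    return joint
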