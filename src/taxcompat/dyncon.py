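"""Decremental dynamic graph connectivity (Holm–de Lichtenberg–Thorup).

The compatibility engine deletes edges from the display graph and must
learn, after each deletion, whether the touched component split, how big
the two sides are, and which labels each side holds.  This module
maintains that information with the HDT hierarchy: every edge carries a
level, F_i is the spanning forest restricted to edges of level >= i, and
each forest is represented by Euler tours stored in balanced trees
(treaps) with parent pointers.

Augmentations carried by the tour nodes:

* ``size``      — number of vertex (loop) occurrences below, which gives
                  component cardinality at the tour root;
* ``sub_tree``  — whether the subtree holds an arc of a tree edge whose
                  level equals this forest's level (candidates to push
                  one level down when a tree edge dies);
* ``sub_nontree`` — whether the subtree holds a vertex with incident
                  non-tree edges at this level (replacement candidates).

Deleting a tree edge at level l cuts it out of forests 0..l, then
searches levels l, l-1, ..., 0 for a replacement: the smaller side's
level-i tree edges are pushed to level i+1, its level-i non-tree edges
are scanned, non-reconnecting ones are pushed to level i+1, and the
first reconnecting one is promoted to a tree edge.  If no level yields a
replacement the component has genuinely split.  Amortized cost per
deletion is O(log^2 N).

Vertices are labels (strings) mapped once to dense integer ids; the
usage pattern is insert-everything-then-only-delete, which is all the
engine ever needs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Iterator


class ConnectivityError(ValueError):
    pass


class _Node:
    __slots__ = ("prio", "left", "right", "par", "cnt", "size",
                 "is_loop", "vertex", "edge", "self_tree", "self_nontree",
                 "sub_tree", "sub_nontree")

    def __init__(self, prio: float, *, vertex: int | None = None,
                 edge: "_EdgeRec | None" = None):
        self.prio = prio
        self.left = None
        self.right = None
        self.par = None
        self.vertex = vertex
        self.edge = edge
        self.is_loop = vertex is not None
        self.self_tree = False
        self.self_nontree = False
        self.cnt = 1
        self.size = 1 if self.is_loop else 0
        self.sub_tree = False
        self.sub_nontree = False


def _upd(x: _Node) -> None:
    cnt = 1
    size = 1 if x.is_loop else 0
    st = x.self_tree
    sn = x.self_nontree
    l = x.left
    if l is not None:
        cnt += l.cnt
        size += l.size
        st = st or l.sub_tree
        sn = sn or l.sub_nontree
    r = x.right
    if r is not None:
        cnt += r.cnt
        size += r.size
        st = st or r.sub_tree
        sn = sn or r.sub_nontree
    x.cnt = cnt
    x.size = size
    x.sub_tree = st
    x.sub_nontree = sn


def _pull(x: _Node) -> None:
    while x is not None:
        _upd(x)
        x = x.par


def _root(x: _Node) -> _Node:
    while x.par is not None:
        x = x.par
    return x


def _merge(a: _Node | None, b: _Node | None) -> _Node | None:
    if a is None:
        return b
    if b is None:
        return a
    if a.prio > b.prio:
        m = _merge(a.right, b)
        a.right = m
        m.par = a
        _upd(a)
        return a
    m = _merge(a, b.left)
    b.left = m
    m.par = b
    _upd(b)
    return b


def _split_before(x: _Node) -> tuple[_Node | None, _Node]:
    """Split the tree containing x into (before-x, x-and-after)."""
    L = x.left
    if L is not None:
        L.par = None
        x.left = None
    _upd(x)
    R: _Node = x
    cur = x
    p = x.par
    x.par = None
    while p is not None:
        gp = p.par
        p.par = None
        if p.left is cur:
            p.left = None
            _upd(p)
            R = _merge(R, p)
        else:
            p.right = None
            _upd(p)
            L = _merge(p, L)
        cur = p
        p = gp
    return L, R


def _split_after(x: _Node) -> tuple[_Node, _Node | None]:
    """Split the tree containing x into (up-to-x, after-x)."""
    R = x.right
    if R is not None:
        R.par = None
        x.right = None
    _upd(x)
    L: _Node = x
    cur = x
    p = x.par
    x.par = None
    while p is not None:
        gp = p.par
        p.par = None
        if p.right is cur:
            p.right = None
            _upd(p)
            L = _merge(p, L)
        else:
            p.left = None
            _upd(p)
            R = _merge(R, p)
        cur = p
        p = gp
    return L, R


def _order_index(x: _Node) -> int:
    idx = x.left.cnt if x.left is not None else 0
    cur = x
    p = x.par
    while p is not None:
        if p.right is cur:
            idx += 1 + (p.left.cnt if p.left is not None else 0)
        cur = p
        p = p.par
    return idx


class _EdgeRec:
    __slots__ = ("u", "v", "level", "is_tree", "arcs")

    def __init__(self, u: int, v: int):
        self.u = u
        self.v = v
        self.level = 0
        self.is_tree = False
        # level -> (arc_uv, arc_vu) for the forests this tree edge lives in
        self.arcs: dict[int, tuple[_Node, _Node]] = {}


@dataclass(frozen=True)
class ComponentHandle:
    """Identifies a component by one of its members; sizes are a snapshot."""
    representative: str
    size: int


@dataclass(frozen=True)
class SplitReport:
    side_a: ComponentHandle
    side_b: ComponentHandle


class DynamicConnectivity:
    """HDT decremental connectivity over a vertex universe of labels."""

    def __init__(self, vertices: Iterable[str], *, seed: int = 0x5EED):
        labels = sorted(set(vertices))
        self._label_of = labels
        self._id_of = {lab: i for i, lab in enumerate(labels)}
        self._rng = random.Random(seed)
        n = len(labels)
        # per level: loop-node table and non-tree adjacency
        self._loops: list[list[_Node | None]] = []
        self._nontree: list[dict[int, set[int]]] = []
        self._ensure_level(0)
        loops0 = self._loops[0]
        for i in range(n):
            loops0[i] = _Node(self._rng.random(), vertex=i)
        self._edges: dict[tuple[int, int], _EdgeRec] = {}
        self.deletions = 0
        self.trace: list[tuple] | None = None  # optional op trace

    # -- plumbing ------------------------------------------------------

    def _ensure_level(self, i: int) -> None:
        while len(self._loops) <= i:
            self._loops.append([None] * len(self._label_of))
            self._nontree.append({})

    def _loop(self, level: int, v: int) -> _Node:
        self._ensure_level(level)
        node = self._loops[level][v]
        if node is None:
            node = _Node(self._rng.random(), vertex=v)
            self._loops[level][v] = node
        return node

    def _vid(self, label: str) -> int:
        try:
            return self._id_of[label]
        except KeyError:
            raise ConnectivityError(f"unknown vertex {label!r}") from None

    def _reroot(self, loop: _Node) -> _Node:
        L, R = _split_before(loop)
        return _merge(R, L)

    def _link_at_level(self, rec: _EdgeRec, level: int) -> None:
        lu = self._loop(level, rec.u)
        lv = self._loop(level, rec.v)
        tu = self._reroot(lu)
        tv = self._reroot(lv)
        a1 = _Node(self._rng.random(), edge=rec)
        a2 = _Node(self._rng.random(), edge=rec)
        a1.self_tree = rec.level == level
        _upd(a1)
        rec.arcs[level] = (a1, a2)
        _merge(_merge(_merge(tu, a1), tv), a2)

    def _cut_at_level(self, rec: _EdgeRec, level: int) -> None:
        a1, a2 = rec.arcs.pop(level)
        if _order_index(a1) > _order_index(a2):
            a1, a2 = a2, a1
        # Tour reads A | a1 | middle | a2 | C.  The middle is one of the
        # two components and A+C (a rotation of the other) is the rest;
        # which is which depends on where the tour was linearized, and
        # callers only ever locate components through loop nodes.
        A, _ = _split_before(a1)
        _, rest = _split_after(a1)
        _middle, _ = _split_before(a2)
        _, C = _split_after(a2)
        _merge(A, C)
        a1.edge = a2.edge = None

    def _nontree_add(self, level: int, x: int, y: int) -> None:
        self._ensure_level(level)
        for a, b in ((x, y), (y, x)):
            s = self._nontree[level].setdefault(a, set())
            s.add(b)
            la = self._loop(level, a)
            if not la.self_nontree:
                la.self_nontree = True
                _pull(la)

    def _nontree_remove(self, level: int, x: int, y: int) -> None:
        for a, b in ((x, y), (y, x)):
            s = self._nontree[level][a]
            s.discard(b)
            if not s:
                la = self._loops[level][a]
                if la is not None and la.self_nontree:
                    la.self_nontree = False
                    _pull(la)

    @staticmethod
    def _collect_flagged(root: _Node, attr: str) -> list[_Node]:
        sub = "sub_tree" if attr == "self_tree" else "sub_nontree"
        out: list[_Node] = []
        if not getattr(root, sub):
            return out
        stack = [root]
        while stack:
            n = stack.pop()
            if getattr(n, attr):
                out.append(n)
            for ch in (n.left, n.right):
                if ch is not None and getattr(ch, sub):
                    stack.append(ch)
        return out

    # -- public contract ----------------------------------------------

    def dc_insert_edge(self, u: str, v: str) -> None:
        a, b = self._vid(u), self._vid(v)
        if a == b:
            raise ConnectivityError("self-loops are not allowed")
        key = (a, b) if a < b else (b, a)
        if key in self._edges:
            return  # duplicate insert is a no-op
        rec = _EdgeRec(*key)
        ra = _root(self._loops[0][a])
        rb = _root(self._loops[0][b])
        if ra is not rb:
            rec.is_tree = True
            self._link_at_level(rec, 0)
        else:
            self._nontree_add(0, *key)
        self._edges[key] = rec
        if self.trace is not None:
            self.trace.append(("insert", u, v))

    def dc_connected(self, u: str, v: str) -> bool:
        a, b = self._vid(u), self._vid(v)
        return _root(self._loops[0][a]) is _root(self._loops[0][b])

    def dc_component_size(self, v: str) -> int:
        return _root(self._loops[0][self._vid(v)]).size

    def dc_component_members(self, v: str) -> Iterator[str]:
        root = _root(self._loops[0][self._vid(v)])
        stack = [root]
        labels = self._label_of
        while stack:
            n = stack.pop()
            if n.is_loop:
                yield labels[n.vertex]
            for ch in (n.left, n.right):
                if ch is not None and ch.size:
                    stack.append(ch)

    def has_edge(self, u: str, v: str) -> bool:
        a, b = self._vid(u), self._vid(v)
        key = (a, b) if a < b else (b, a)
        return key in self._edges

    def dc_delete_edge(self, u: str, v: str) -> SplitReport | None:
        a, b = self._vid(u), self._vid(v)
        key = (a, b) if a < b else (b, a)
        rec = self._edges.pop(key, None)
        if rec is None:
            raise ConnectivityError(f"edge {{{u!r}, {v!r}}} not present")
        self.deletions += 1
        if not rec.is_tree:
            self._nontree_remove(rec.level, rec.u, rec.v)
            if self.trace is not None:
                self.trace.append(("delete", u, v, False))
            return None
        lvl = rec.level
        for i in range(lvl, -1, -1):
            self._cut_at_level(rec, i)
        replaced = False
        for i in range(lvl, -1, -1):
            if self._replace(rec, i):
                replaced = True
                break
        if replaced:
            if self.trace is not None:
                self.trace.append(("delete", u, v, False))
            return None
        ra = _root(self._loops[0][rec.u])
        rb = _root(self._loops[0][rec.v])
        report = SplitReport(
            ComponentHandle(self._label_of[rec.u], ra.size),
            ComponentHandle(self._label_of[rec.v], rb.size),
        )
        if self.trace is not None:
            self.trace.append(("delete", u, v, True))
        return report

    # -- replacement search -------------------------------------------

    def _replace(self, rec: _EdgeRec, i: int) -> bool:
        """Try to reconnect rec's endpoints at level i; True on success."""
        lu = self._loop(i, rec.u)
        lv = self._loop(i, rec.v)
        ru = _root(lu)
        rv = _root(lv)
        small_root = ru if ru.size <= rv.size else rv
        # Push the smaller side's level-i tree edges one level down.
        for arc in self._collect_flagged(small_root, "self_tree"):
            e2 = arc.edge
            arc.self_tree = False
            _pull(arc)
            e2.level = i + 1
            self._link_at_level(e2, i + 1)
        small_root = _root(small_root)  # unchanged shape, defensive
        # Scan the smaller side's level-i non-tree edges.
        nontree = self._nontree[i]
        for lx in self._collect_flagged(small_root, "self_nontree"):
            x = lx.vertex
            for y in list(nontree.get(x, ())):
                ly = self._loops[i][y]
                if _root(ly) is small_root:
                    # both endpoints inside: push one level down
                    kxy = (x, y) if x < y else (y, x)
                    e2 = self._edges[kxy]
                    self._nontree_remove(i, x, y)
                    e2.level = i + 1
                    self._nontree_add(i + 1, x, y)
                else:
                    # reconnects the two sides: promote to tree edge
                    kxy = (x, y) if x < y else (y, x)
                    e2 = self._edges[kxy]
                    self._nontree_remove(i, x, y)
                    e2.is_tree = True
                    for j in range(i, -1, -1):
                        self._link_at_level(e2, j)
                    return True
        return False
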