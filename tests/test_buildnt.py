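"""The compatibility engine: worked-example trace, record bookkeeping,
engine equivalence, soundness of returned supertrees."""

import random

import pytest

from taxcompat import (GeneratorConfig, Profile, ancestrally_displays, build,
                       build_supertree, buildnt_iterative,
                       buildnt_recursive_reference, fig1_profile,
                       gen_compatible, gen_incompatible, isomorphic,
                       supertree_to_sltree)
from taxcompat.buildnt import EngineStats, _Engine, semi_universal_labels


def fs(*items):
    return frozenset(items)


def run_traced(profile):
    trace = []
    root = buildnt_iterative(profile, trace=trace, check_invariants=True)
    return root, trace


class TestRootState:
    def test_worked_example_root_position(self, fig1):
        eng = _Engine(fig1)
        rec = eng.init_root_record()
        assert rec.position(3) == (fs("1"), fs("2"), fs("g"))
        assert semi_universal_labels(rec) == fs("1", "2")
        assert rec.weight == sum(eng.k_of.values())

    def test_single_tree_single_node(self):
        p = Profile([build("x")])
        eng = _Engine(p)
        rec = eng.init_root_record()
        assert rec.position(1) == (fs("x"),)
        assert semi_universal_labels(rec) == fs("x")
        assert rec.weight == 1


class TestWorkedExampleTrace:
    """The engine reproduces the published step-by-step execution on
    the three-tree example."""

    def test_level_by_level_positions(self, fig1):
        root, trace = run_traced(fig1)
        assert root is not None
        by_level = {}
        for e in trace:
            by_level.setdefault(e["level"], []).append(e)
        # level 0: the root position and its two-component split
        (e0,) = by_level[0]
        assert e0["position"] == (fs("1"), fs("2"), fs("g"))
        assert e0["S"] == fs("1", "2")
        members = {m for m, _pos in e0["components"]}
        assert members == {fs("3", "4", "a", "b", "c", "d", "e", "g"),
                           fs("f", "h", "i")}
        positions = {pos for _m, pos in e0["components"]}
        assert positions == {(fs("3"), fs("e", "g"), fs("g")),
                             (fs("f"), fs("f"), fs())}
        # level 1
        l1 = {e["position"]: e for e in by_level[1]}
        e_u1 = l1[(fs("3"), fs("e", "g"), fs("g"))]
        assert e_u1["S"] == fs("3")
        assert {pos for _m, pos in e_u1["components"]} == {
            (fs("a", "d"), fs("g"), fs("g")), (fs("e"), fs("e"), fs())}
        e_u2 = l1[(fs("f"), fs("f"), fs())]
        assert e_u2["S"] == fs("f")
        assert {pos for _m, pos in e_u2["components"]} == {
            (fs(), fs("h"), fs()), (fs(), fs("i"), fs())}
        # level 2: U_11 splits; e, h, i are leaves
        l2 = {e["position"]: e for e in by_level[2]}
        e_u11 = l2[(fs("a", "d"), fs("g"), fs("g"))]
        assert e_u11["S"] == fs("g")
        assert {pos for _m, pos in e_u11["components"]} == {
            (fs("a"), fs("a"), fs("4")), (fs("d"), fs("d"), fs("d"))}
        for leaf_pos, leaf in [((fs("e"), fs("e"), fs()), "e"),
                               ((fs(), fs("h"), fs()), "h"),
                               ((fs(), fs("i"), fs()), "i")]:
            assert l2[leaf_pos]["S"] == fs(leaf)
            assert l2[leaf_pos]["components"] == []
        # level 3: U_111 -> {4, a}; d is a leaf
        l3 = {e["position"]: e for e in by_level[3]}
        e_u111 = l3[(fs("a"), fs("a"), fs("4"))]
        assert e_u111["S"] == fs("4", "a")
        assert {pos for _m, pos in e_u111["components"]} == {
            (fs("b"), fs(), fs("b")), (fs("c"), fs(), fs("c"))}
        assert l3[(fs("d"), fs("d"), fs("d"))]["S"] == fs("d")
        # level 4: b and c are leaves
        assert {tuple(sorted(e["S"])) for e in by_level[4]} == {("b",), ("c",)}

    def test_supertree_shape_and_verification(self, fig1):
        root, _ = run_traced(fig1)
        result = supertree_to_sltree(root)
        expected = build((None, [
            ("3", [("g", [(None, ["b", "c"]), "d"]), "e"]),
            ("f", ["h", "i"])]))
        lab = dict(expected.labels_of)
        lab[expected.root] = fs("1", "2")
        for u, labs in expected.labels_of.items():
            if not labs and u != expected.root:
                lab[u] = fs("4", "a")
        expected = type(expected)(root=expected.root,
                                  children=expected.children, labels_of=lab)
        assert isomorphic(result, expected)
        for t in fig1.trees:
            assert ancestrally_displays(result, t)

    def test_split_weight_bookkeeping(self, fig1):
        """After consuming the roots, the {f,h,i} side carries weight
        k_f + k_h + k_i = 4."""
        eng = _Engine(fig1)
        rec = eng.init_root_record()
        parts = eng.successor_apply(rec, semi_universal_labels(rec))
        weights = {frozenset(eng.dc.dc_component_members(p.rep)): p.weight
                   for p in parts}
        assert weights[fs("f", "h", "i")] == 4
        # sum of multiplicities over the printed member set
        expected = sum(eng.k_of[l]
                       for l in ("3", "4", "a", "b", "c", "d", "e", "g"))
        assert expected == 15
        assert weights[fs("3", "4", "a", "b", "c", "d", "e", "g")] == expected


class TestIncompatibility:
    @pytest.mark.parametrize("kind", ["ancestor-cycle", "triplet-conflict",
                                      "nesting-vs-separation"])
    @pytest.mark.parametrize("engine", ["iterative", "recursive"])
    def test_contradiction_fixtures_rejected(self, kind, engine):
        assert build_supertree(gen_incompatible(kind), engine=engine) is None

    def test_no_semi_universal_label_in_conflicting_triplets(self):
        """After consuming both triplet roots the single component's
        position ({2,c},{4,b}) exposes no label."""
        p = Profile([build(("1", [("2", ["a", "b"]), "c"])),
                     build(("3", [("4", ["a", "c"]), "b"]))])
        eng = _Engine(p)
        rec = eng.init_root_record()
        (only,) = eng.successor_apply(rec, semi_universal_labels(rec))
        assert only.position(2) == (fs("2", "c"), fs("4", "b"))
        assert semi_universal_labels(only) == frozenset()


class TestLeafShortcut:
    def test_two_tree_shared_leaf(self):
        p = Profile([build(("r", ["e", "x"])), build(("s", ["e", "y"]))])
        root = build_supertree(p)
        s = supertree_to_sltree(root)
        for t in p.trees:
            assert ancestrally_displays(s, t)

    def test_single_node_profile(self):
        root = buildnt_iterative(Profile([build("x")]))
        assert root.label_set == fs("x")
        assert root.children == []


class TestEngineEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_compatible_profiles_agree(self, seed):
        prof, _ = gen_compatible(GeneratorConfig(
            n_labels=random.Random(seed).randint(5, 80), k_trees=4,
            seed=seed))
        a = build_supertree(prof, engine="iterative")
        b = build_supertree(prof, engine="recursive")
        assert a is not None and b is not None
        assert isomorphic(supertree_to_sltree(a), supertree_to_sltree(b))

    @pytest.mark.parametrize("seed", range(8))
    def test_perturbed_profiles_agree_on_verdict(self, seed):
        """Swapping two labels inside one tree may or may not break
        compatibility; both engines must reach the same verdict and,
        when compatible, isomorphic supertrees."""
        prof = _perturbed(seed)
        a = build_supertree(prof, engine="iterative")
        b = build_supertree(prof, engine="recursive")
        assert (a is None) == (b is None)
        if a is not None:
            assert isomorphic(supertree_to_sltree(a), supertree_to_sltree(b))


def _perturbed(seed: int) -> Profile:
    rng = random.Random(seed)
    prof, _ = gen_compatible(GeneratorConfig(
        n_labels=rng.randint(8, 60), k_trees=4, seed=seed))
    trees = list(prof.trees)
    i = rng.randrange(len(trees))
    t = trees[i]
    labs = sorted(t.label_set)
    if len(labs) >= 2:
        a, b = rng.sample(labs, 2)
        swap = {a: b, b: a}
        new_labels = {u: frozenset(swap.get(l, l) for l in ls)
                      for u, ls in t.labels_of.items()}
        trees[i] = type(t)(root=t.root, children=t.children,
                           labels_of=new_labels)
    return Profile(trees)


class TestSoundness:
    @pytest.mark.parametrize("seed", range(6))
    def test_output_displays_every_input(self, seed):
        prof, _ = gen_compatible(GeneratorConfig(n_labels=70, k_trees=6,
                                                 seed=seed))
        stats = EngineStats()
        root = build_supertree(prof, stats=stats)
        assert root is not None
        s = supertree_to_sltree(root)
        for t in prof.trees:
            assert ancestrally_displays(s, t)

    def test_each_label_semi_universal_at_most_once(self, fig1):
        _, trace = run_traced(fig1)
        seen = []
        for e in trace:
            seen.extend(e["S"])
        assert len(seen) == len(set(seen))

    def test_deletion_budget(self, fig1):
        stats = EngineStats()
        buildnt_iterative(fig1, stats=stats)
        from taxcompat import build_display_graph
        g = build_display_graph(fig1)
        assert stats.deletions <= g.n_vertices() + g.n_edges()
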