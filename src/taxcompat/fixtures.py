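"""Deterministic profile generators for tests and demonstrations.

Compatible profiles are produced by sampling a hidden semi-labeled
supertree and emitting restrictions of it to random label subsets — any
restriction of a tree is ancestrally displayed by it, so such a profile
is compatible by construction and the hidden tree is a witness.
Incompatible profiles embed one of three small contradictions.  The
module also reconstructs the three-tree example profile used throughout
the documentation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .sltree import Profile, SemiLabeledTree, build, restrict

INCOMPATIBLE_KINDS = ("ancestor-cycle", "triplet-conflict",
                      "nesting-vs-separation")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the compatible-profile generator.

    ``n_labels`` sets the node count of the hidden supertree (leaves and
    single-child nodes are always labeled; other internal nodes are
    labeled with probability ``label_density``, so the realized label
    set is a little smaller than ``n_labels`` when density < 1).
    ``subset_fraction`` is the expected fraction of labels each input
    tree retains.  Identical seeds give identical output.
    """

    n_labels: int = 50
    k_trees: int = 5
    label_density: float = 0.5
    subset_fraction: float = 0.5
    seed: int = 0


def fig1_profile() -> Profile:
    """The running three-tree example: two phylogeny-like trees whose
    roots and some internal nodes carry added numeric labels, plus a
    taxonomy-like tree rooted at the higher-order taxon g."""
    t1 = build(("1", [("3", [("a", ["b", "c"]), "d", "e"]), "f"]))
    t2 = build(("2", ["e", ("f", ["h", "i"]), ("g", ["a", "d"])]))
    t3 = build(("g", [("4", ["b", "c"]), "d"]))
    return Profile([t1, t2, t3])


def _hidden_supertree(rng: random.Random, n_nodes: int,
                      label_density: float) -> SemiLabeledTree:
    """Sample a rooted tree by preferential attachment and label it.

    Attachment probability grows with a node's current child count,
    which yields the heavy-tailed degree distributions seen in
    taxonomies (a genus holding dozens of species) rather than the
    O(log n) maximum degree of uniform attachment.
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes in the hidden supertree")
    parents = [0] * n_nodes
    bag = [0]  # node j appears 1 + (#children of j) times
    for j in range(1, n_nodes):
        p = rng.choice(bag)
        parents[j] = p
        bag.append(p)
        bag.append(j)
    kids: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for j in range(1, n_nodes):
        kids[parents[j]].append(j)

    width = len(str(n_nodes))
    labels: dict[int, frozenset[str]] = {}
    counter = 0
    for u in range(n_nodes):
        mandatory = len(kids[u]) <= 1
        if mandatory or rng.random() < label_density:
            labels[u] = frozenset([f"t{counter:0{width}d}"])
            counter += 1
        else:
            labels[u] = frozenset()
    return SemiLabeledTree(root=0,
                           children={u: tuple(c) for u, c in kids.items()},
                           labels_of=labels)


def gen_compatible(config: GeneratorConfig) -> tuple[Profile, SemiLabeledTree]:
    """A compatible profile plus the hidden supertree witnessing it."""
    rng = random.Random(config.seed)
    witness = _hidden_supertree(rng, config.n_labels, config.label_density)
    universe = sorted(witness.label_set)
    trees = []
    for _ in range(config.k_trees):
        subset = [lab for lab in universe
                  if rng.random() < config.subset_fraction]
        if not subset:
            subset = [rng.choice(universe)]
        trees.append(restrict(witness, subset))
    return Profile(trees), witness


def gen_incompatible(kind: str, seed: int = 0) -> Profile:
    """A small profile embedding a named contradiction.

    * ``ancestor-cycle``: one tree makes a an ancestor of b, the other
      makes b an ancestor of a.
    * ``triplet-conflict``: the rooted triplets ab|c and ac|b with
      labeled internal nodes.
    * ``nesting-vs-separation``: one tree nests b strictly below a, the
      other places a and b as incomparable siblings.
    """
    rng = random.Random(seed)
    if kind == "ancestor-cycle":
        trees = [build(("a", ["b"])), build(("b", ["a"]))]
    elif kind == "triplet-conflict":
        trees = [build(("1", [("2", ["a", "b"]), "c"])),
                 build(("3", [("4", ["a", "c"]), "b"]))]
    elif kind == "nesting-vs-separation":
        trees = [build(("a", ["b"])), build(("p", ["a", "b"]))]
    else:
        raise ValueError(f"unknown incompatibility kind {kind!r}; "
                         f"expected one of {INCOMPATIBLE_KINDS}")
    rng.shuffle(trees)  # order never matters; exercise that
    return Profile(trees)
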