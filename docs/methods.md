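# Methods

## Model

A **semi-labeled tree** is a pair `T = (T, φ)` of a rooted tree and a
labeling map from a label set onto the nodes such that every leaf and
every node with a single child (the root included) is labeled; nodes
with two or more children may be unlabeled.  Ordinary phylogenies
(bijective leaf labeling) and taxonomies (every node labeled by a
taxon of some rank) are both instances.  Input trees must be
*singularly* labeled (at most one label per node); output supertrees
need not be, because several input labels can be forced onto one node.

A tree is determined by its **cluster set** `Cl(T)` (for each node, the
labels in its subtree).  Restriction `T|A` is the tree whose clusters
are `{X ∩ A ≠ ∅ : X ∈ Cl(T)}`, realized by the minimal rooted subtree
spanning `φ(A)` with unlabeled degree-two nodes suppressed; the
test-suite cross-checks the two constructions against each other on
random trees.  `T` *ancestrally displays* `T′` iff
`D(T′) ⊆ D(T)` and `N(T′) ⊆ N(T)`, where `D` collects ordered strict
ancestor/descendant label pairs and `N` unordered incomparable pairs;
labels sharing one node are mutually comparable-equal and belong to
neither set.  This containment test is the package's universal
verification oracle — every supertree the engines emit is checked
against it in the tests, independently of how it was built.

## Procedure

1. **Full labeling.**  Unlabeled nodes receive fresh `__aux<n>` labels
   (collision-scanned against the user's labels).  Compatibility is
   invariant under this transformation, and any supertree for the
   augmented profile displays the original; the writer strips the
   auxiliary labels again by default, suppressing nodes this leaves
   unlabeled with one child.
2. **Display graph.**  Trees are glued at shared labels; vertices are
   labels, edges are parent/child pairs in any tree, parallel edges
   merged.  Per label, `k_ℓ` counts the trees containing it.  A
   disconnected display graph splits the profile into label-disjoint
   groups of whole trees, solved independently; the driver joins the
   sub-supertrees under a fresh unlabeled root (legal, since it has ≥ 2
   children) or emits a forest on request.
3. **Engine.**  A FIFO queue holds one *component record* per connected
   component of the shrinking display graph.  A record stores: the
   frontier map `i → U(i) ∩ Y` for trees with nonempty intersection;
   per-label singleton counts (`count(ℓ)` = number of trees whose
   frontier cell is exactly `{ℓ}`); the *exposed* set
   `{ℓ : count(ℓ) = k_ℓ}` — precisely the semi-universal labels, read
   off in `O(|S|)`; and the component weight `Σ_{ℓ∈Y} k_ℓ`.  Empty `S`
   ⇒ incompatible.  Otherwise a supertree node labeled `S` is created,
   frontiers of consumed labels are replaced by their child sets, all
   edges incident to consumed labels are deleted (sorted order, for
   reproducible split sequences; correctness is order-independent and
   the equivalence suite exercises shuffled inputs), and the surviving
   components are enqueued.  A single childless semi-universal label
   short-circuits to a leaf.
4. **Splits.**  Each deletion queries the dynamic-connectivity
   structure.  On a split, the node-count-smaller side is scanned to
   compute both weights (each label is scanned `O(log M_P)` times over
   a run, since its component at least halves), then every label of the
   *weight*-smaller side is moved into a fresh record: its frontier
   cells are deleted from the inherited record and re-created in the
   new one, with `count`/`exposed` adjusted in `O(1)` per (label, tree)
   — a cell shrinking to a singleton increments the surviving label's
   count, a cell growing past one decrements it, with exposure updated
   at the `k_ℓ` threshold.

## Dynamic connectivity

Decremental connectivity uses the Holm–de Lichtenberg–Thorup
hierarchy: every edge carries a level, `F_i` is the spanning forest of
edges with level ≥ i, and each forest level is a set of Euler tours
stored in treaps with parent pointers.  Tour nodes aggregate subtree
size (component cardinality), the presence of tree edges at exactly
this level, and the presence of vertices with non-tree edges at this
level, so replacement searches visit only flagged subtrees.  Deleting
a tree edge at level l cuts forests 0…l and searches levels l…0: the
smaller side's level-i tree edges are pushed to level i+1, its level-i
non-tree edges are scanned — non-reconnecting ones pushed down, the
first reconnecting one promoted into forests i…0 — and if every level
fails, the component has split and the report carries a representative
and size for each side.  The structure is validated wholesale against
breadth-first recomputation (several thousand randomized deletions in
the test-suite and acceptance script).  The engine's usage pattern is
insert-everything-then-delete; interleaved later insertions are
outside the contract.

Vertices are mapped once to dense integer ids; treap priorities come
from a per-instance seeded generator, so runs are deterministic.

## Parameters

Generator defaults (`GeneratorConfig`): `n_labels=50` nodes in the
hidden supertree, `k_trees=5` input trees, `label_density=0.5`
(probability that a multi-child internal node carries a label — leaves
and single-child nodes are always labeled, so the realized label count
is somewhat below `n_labels` when density < 1), `subset_fraction=0.5`
(per-label inclusion probability per input tree, forced nonempty).
Identical seeds give byte-identical profiles.

The hidden supertree is sampled by *preferential* attachment (a new
node picks a parent with probability proportional to 1 + its child
count).  Uniform attachment was rejected deliberately: its maximum
degree grows only like `log₂ n`, whereas taxonomies are heavy-tailed —
a genus holding dozens of species — and degree-independence of the
run time is exactly the regime worth exercising.  The generated
profiles are restrictions of one true tree, so they are compatible by
construction (with the hidden tree as witness) and cover partial
labeling, shared internal taxa, and high-degree nodes.  They do *not*
emulate real-data pathologies such as label synonymy/misspelling,
rank inversions between conflicting taxonomies, or adversarially
near-incompatible profiles; passing tests therefore demonstrate
algorithmic correctness on the stated model, not robustness to dirty
taxon names.  Incompatible fixtures are three minimal contradictions
(ancestor cycle, conflicting rooted triplets, nesting vs. sibling
separation) rather than random perturbations, plus label-swap
perturbations in the equivalence suite whose verdict is deliberately
left open and only cross-checked between engines.

## Numerical and tie-break choices

- All structures are hash-based; the `O(log)` bounds quoted for
  balanced trees are worst-case devices, hashing gives the same
  amortized totals in expectation.
- Exposed sets store *labels* (with `count(ℓ) = k_ℓ`) rather than tree
  indices; the two encodings are interconvertible, and the label form
  yields `S` without a reverse index.
- Node-count ties on splits: the side containing the lexicographically
  smallest label counts as smaller.  Weight ties: the node-smaller
  side (already scanned, already deterministic) is rebuilt.  The
  halving arguments only need "at most half", so determinism is the
  only stake.
- Canonical output ordering sorts children by the smallest label in
  their subtree and renders multi-labels sorted and `+`-joined;
  isomorphism (cluster-set equality) is the real contract, canonical
  form only serves snapshot tests.
- Degenerate inputs: single-node trees, single-tree profiles, and
  fully-overlapping or disjoint label sets are all legal; empty input
  and duplicate labels within one tree are rejected at parse time.

## Problem sizes

The test-suite and acceptance script run the worked three-tree example
exactly; engine cross-validation on 100+ profiles up to 300 labels;
the connectivity oracle on ~1300 deletions over four 80-vertex graphs;
and work accounting on generated profiles of 10², 10³ and 10⁴ labels
(`M_P` up to ≈ 34 000), where deletions stay under the `|V|+|E|` budget
and bookkeeping updates stay near-linear in `M_P` (the measured ratio
`updates/M_P` drifts from ≈ 3.8 to ≈ 4.8 over two decades, far inside
the `log²` envelope).  The whole suite runs in well under a minute on
one core.

## Limitations

- Incompatible profiles are detected, not repaired; no MinCut-style
  resolution or greedy synthesis is attempted.
- Unrooted trees, branch lengths, and NEXUS/PhyloXML input are out of
  scope (branch lengths in Newick input are parsed and dropped with a
  warning).
- The recursive reference engine recomputes positions naively
  (quadratic-ish) and is intended for cross-checking at moderate
  sizes, not production use.
- The dynamic-connectivity structure is decremental-only by contract,
  matching the engine's needs; it is not a general fully-dynamic
  library.
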