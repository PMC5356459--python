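# taxcompat

Ancestral compatibility testing and supertree construction for rooted
**semi-labeled trees** — phylogenies whose internal nodes may carry
higher-order taxa, which includes taxonomies such as the NCBI taxonomy.

## The problem

Large phylogenetic syntheses combine source trees with only partially
overlapping taxon sets, and increasingly mix ordinary phylogenies with
taxonomies to gain coverage.  A taxonomy is a semi-labeled tree
`T = (T, φ)`: a rooted tree plus a map `φ` from a label set `L(T)` onto
its nodes, with internal labels denoting higher-order taxa (e.g.
*Fabaceae* above *Glycine max*).  Given a profile
`P = {T₁, …, T_k}` of such trees, the *ancestral compatibility* question
asks whether a single tree `T` on `L(P) = ⋃ᵢ L(Tᵢ)` exists that
preserves, for every input tree, both its strict ancestor/descendant
pairs `D(Tᵢ) = {(ℓ,ℓ′) : ℓ <_{Tᵢ} ℓ′}` and its incomparability pairs
`N(Tᵢ) = {{ℓ,ℓ′} : ℓ ∥_{Tᵢ} ℓ′}` — i.e. `D(Tᵢ) ⊆ D(T)` and
`N(Tᵢ) ⊆ N(T)` for all `i` (the tree then *ancestrally displays* the
profile).

`taxcompat` decides this and builds a witness supertree in
`O(M_P log² M_P)` time, where `M_P` is the total number of nodes plus
edges over the profile — crucially **independent of node degrees**,
which matters because taxonomies contain nodes with hundreds of
children.

## The algorithm

After fully labeling the profile (fresh auxiliary labels on unlabeled
nodes), the trees are glued at shared labels into the **display graph**
`H_P`.  The engine walks all trees top-down in lockstep, maintaining a
*position* `U = (U(1), …, U(k))` of frontier sibling-sets.  A label `ℓ`
is **semi-universal** when `U(i) = {ℓ}` for every tree containing `ℓ`;
the set `S` of such labels becomes the label set of the next supertree
node.  Advancing replaces those frontiers by child sets and deletes the
consumed labels from `H_P`; the connected components of the remainder
are independent subproblems, processed breadth-first from a FIFO queue.
The profile is incompatible exactly when some live component has no
semi-universal label.

Component splits are detected by a decremental dynamic-connectivity
structure in the Holm–de Lichtenberg–Thorup style (Euler-tour forests
with edge levels, `O(log² N)` amortized per deletion), and per-component
frontier bookkeeping is rebuilt only on the weight-smaller side of each
split, which bounds the total update work by `O(M_P log M_P)`.

## Worked example

`fixtures.fig1_profile()` is a three-tree profile (two phylogeny-style
trees plus a small taxonomy rooted at the higher-order taxon `g`) over
labels `a…i` with added numeric labels `1–4`:

```
(((b,c)a,d,e)3,f)1;
((a,d)g,e,(h,i)f)2;
((b,c)4,d)g;
```

From Python:

```python
>>> from taxcompat import fig1_profile, build_supertree
>>> from taxcompat.io_cli import write_tree
>>> root = build_supertree(fig1_profile())
>>> print(write_tree(root))
((((b,c)'4+a',d)g,e)3,(h,i)f)'1+2';
```

or from the shell:

```console
$ taxcompat check fig1.nwk
((((b,c)'4+a',d)g,e)3,(h,i)f)'1+2';
$ taxcompat verify supertree.nwk fig1.nwk
OK
```

The output is a semi-labeled supertree; `'1+2'` marks one node carrying
both labels 1 and 2 (output nodes may be multiply labeled even when all
inputs are singularly labeled).  `verify` re-checks the `D`/`N`
containments independently of the engine.  An incompatible input —
e.g. the two-tree profile `(b)a; (a)b;` in which each label claims to
be the other's ancestor — prints `INCOMPATIBLE` and exits with
status 1.

Synthetic data comes from `taxcompat gen`, which samples a hidden
supertree and emits restrictions of it (compatible by construction,
with the hidden tree as witness), or contradiction fixtures via
`--incompatible {ancestor-cycle,triplet-conflict,nesting-vs-separation}`.

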