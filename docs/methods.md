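# Methods

## Model

A **species tree** S is rooted, binary (required by the refinement
machinery; parsing accepts non-binary S and the cost layer works with it),
with unique leaf labels. A **gene tree** is leaf-labeled by species names,
with repeats allowed; it may be rooted or unrooted and may contain
polytomies, which are interpreted as *soft*: stand-ins for unresolved
binary structure. A **binary refinement** is any binary tree that contracts
back to the input; a **rooting** of an unrooted tree either subdivides an
edge with a new root (G_e) or promotes an internal vertex to the root
(G_v). Node rootings matter: when the instance has an all-single M6 star,
the optimum over refinements is reached through the star's center.

All costs are exact integers of the form ρ_K(T,S) = Σ_{g ∈ I(T)} ξ_K(g)
under the lca mapping; see the README for the three contribution
functions. The unrooted, non-binary score of G is
min { ρ_K(rooting of refinement of G) }, and the package returns a witness
tree attaining it.

## The reduction

Both directions of every edge of G are labeled with the lca of the species
images of the leaves on the tail side; ⊤ is the lca of all leaf images
(*not* necessarily the species root when L(G) ⊂ L(S)). For an internal
vertex with k edges, α counts incident subtree-side labels equal to ⊤ and
β counts remainder-side labels equal to ⊤. Because at most one subtree can
be indispensable for reaching ⊤, β ∈ {k−1, k}, giving exactly six types:
M1 (α=1, β=k−1), M2 (0, k−1), M3 (1, k), M4 (k, k), M5 (1<α<k, β=k),
M6 (0, k). A note on orientation: the star-type table is stated over
(subtree-side, remainder-side) counts in that order; with the opposite
reading the table is not exhaustive already on a 3-leaf star against a
3-leaf caterpillar, so this orientation is forced, and the property suite
(500 instances) pins it.

The locator starts at the internal endpoint of the canonically-first leaf
edge and repeatedly steps across an edge whose toward-label is ⊤ and
away-label is not (the M1 move; a property test checks every start vertex
works). It terminates at a vertex incident to an empty or double edge
(root there) or at the unique M6 center (root at the vertex). A visited
set guards the walk; revisiting a vertex or finishing anywhere else raises
an internal-consistency error rather than returning silently.

Correctness is enforced empirically rather than assumed: the acceptance
suite checks, on 300 seeded instances per cost, that the pipeline's cost
equals the exhaustive minimum over the full rooting × refinement space.

## Rooted refinement

For the **duplication** cost the objective decomposes per polytomy:
resolution does not change the images of pre-existing nodes, and the
contribution of the new nodes (and of the polytomy apex) depends only on
the children's images. Each polytomy is therefore resolved by exhaustive
local search over its (2k−3)!! shapes, scored on images alone; a dedicated
suite (300 rooted instances) confirms the decomposed optimum equals the
global exhaustive minimum. The local search is capped at 8 children
(135,135 shapes) and raises a cap error beyond.

For **deep coalescence** and **Robinson–Foulds** the rooted refinement
problem has no known polynomial algorithm, so the rooted step enumerates
all refinements under a global cap (default 100,000) and never substitutes
a heuristic: too-large inputs fail loudly with exit code 3.

**Robinson–Foulds scope.** ρ_RF itself is defined for any labeling, but
the optimal-rooting reduction provably does not extend to repeated labels:
on the instance G = (s1,s4,(s4,(s2,(s3,(s3,(s1,s1,s2)))))) against
S = (s4,(s3,(s1,s2))) the located double edge refines to RF cost 1 while a
single edge reaches 0. `refine_unrooted(cost="rf")` therefore rejects
repeated labels; with repeat-free labelings (including proper subsets of
the species set) the equivalence suites pass throughout. The classical RF
conversion |I(S)| + 2·ρ_RF − |I(T)| additionally requires full bijectivity
onto L(S) and is cross-checked against the direct cluster symmetric
difference.

**Deep coalescence convention.** The per-edge path-length form is used as
is, which makes identical binary 3-leaf trees score 4 rather than 0. The
classical extra-lineages convention (−1 per child edge) is available as
`dc_variant="minus_one_per_edge"`; the two differ by the fixed child-edge
count of a binary refinement, so optimal rootings and refinements
coincide (tested).

## Numerical and structural choices

- Child order is never meaningful; equality is label-preserving
  isomorphism via a recursive sorted canonical form, which also
  deduplicates refinements when repeated labels make distinct resolutions
  isomorphic (the closed-form count Π(2k−3)!! / Π(2d−5)!! counts
  resolutions over distinguishable subtrees and matches the enumeration
  exactly on repeat-free trees).
- Ties among equal-cost shapes/refinements are broken by canonical order;
  optimal-edge sets are reported sorted by edge split keys. All outputs
  are deterministic; `--reproducible` drops the one timestamp field.
- The per-edge rooting profile is computed by explicit re-rooting
  (quadratic overall); the locator itself needs only the linear labeling.
  Species-tree lca queries walk parent pointers over precomputed depths —
  appropriate for the tens-to-hundreds-of-leaves regime this tool targets.
- The brute-force oracle enumerates refinement-first (each unrooted binary
  refinement, rooted on every edge, with resolution edges tracked so
  "edge rootings only" can be requested); a test verifies it against a
  literal rooting-first product-space enumeration on small instances.

## Synthetic data

Generators draw random binary shapes by sequential attachment (uniform
over labeled histories, not topologies — a simplicity choice), reuse
labels with a configurable duplication rate, and contract internal edges
independently at a contraction rate to create soft polytomies. Defaults
(8 species, 9 gene leaves, duplication rate 0.2, contraction rate 0.3)
match the bounded oracle family used throughout the suites: at most 8
species, 9 gene leaves, and 3 polytomies of degree ≤ 5, obtained by
rejection sampling, which keeps every exhaustive cross-check to a few
thousand candidate trees per instance. These generators emulate the
combinatorial shape of gene-family data only: no birth–death or
coalescent process, no branch lengths, no inference noise model.
Consequently the passing suites certify the combinatorial guarantees of
the method (optimality, exhaustiveness, plateaus, identities) on
structurally diverse inputs; they say nothing about statistical behavior
on trees estimated from sequences.

## Limitations

- Deep coalescence / Robinson–Foulds refinement is exponential in
  polytomy size by design (the rooted problems are open); the duplication
  path is the scalable one.
- Species-tree-side polytomies are not resolved (the species tree must be
  binary for refinement), and losses, transfers, or non-lca
  reconciliations are out of scope.
- Newick handling is a strict subset: branch lengths parsed and ignored,
  internal node labels ignored, unary nodes suppressed.
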