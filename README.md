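# urefine

Rooting and binary refinement of unrooted, non-binary gene trees against a
rooted binary species tree, under the gene duplication, deep coalescence,
and Robinson–Foulds reconciliation costs.

## The problem

Gene trees inferred from real sequence data are usually **unrooted** and
often contain **polytomies** (multifurcations) that stand for unresolved
binary structure, not for true simultaneous splits. The classical
reconciliation costs, however, are defined for rooted binary gene trees:
given a gene tree *T* and species tree *S* with *L(T) ⊆ L(S)*, the lca
mapping *M* sends each gene node to the lca of its leaf labels' species,
and a cost is a sum of per-node contributions ξ over internal nodes of *T*:

- **duplication**: ξ_D(g) = 1 iff some child *c* has M(g) = M(c);
- **deep coalescence**: ξ_DC(g) = Σ_c ‖M(g), M(c)‖, the species-tree path
  lengths to the children's images;
- **Robinson–Foulds**: ξ_RF(g) = 1 iff the cluster of *g* is not the
  cluster of M(g); the classical rooted RF distance is recovered as
  |I(S)| + 2·ρ_RF(T,S) − |I(T)| for repeat-free labelings.

`urefine` extends these costs to unrooted, non-binary gene trees *G* by the
**binary refinement model**: the score of *G* is the minimum rooted cost
over all rootings of all binary refinements of *G* (refinements resolve
every polytomy; rootings place the root on an edge or at a vertex). It also
returns a witness: an optimally rooted, optimally resolved binary tree.

The key algorithmic idea is a linear-time reduction to the rooted problem.
Each edge of *G*, in each direction, is labeled with the lca of the species
images on its tail side; writing ⊤ for the lca of all leaf images, every
internal vertex's star falls into one of six types (M1–M6) determined by
how many incident edge directions carry ⊤. A single walk over the labeling
finds either an *empty* edge (neither direction ⊤), a *double* edge (both
directions ⊤), or the center of the unique all-single M6 star; rooting
there is optimal, and only the rooted refinement step remains. For the
duplication cost the rooted step decomposes per polytomy and is solved
exactly by local search; for deep coalescence and Robinson–Foulds no
polynomial rooted refinement algorithm is known, so the rooted step is an
explicit exhaustive minimization under a configurable cap.

## Worked example

A four-leaf star gene tree `(a,b,c,d);` against the species tree
`((a,b),(c,d));`:

```sh
urefine --reproducible refine gene.nwk species.nwk --oracle
```

prints (abridged):

```json
{
  "results": {
    "cost_name": "dup",
    "cost_value": 0,
    "n_polytomies_resolved": 1,
    "oracle_checked": true,
    "refined_newick": "((a,b),(c,d));",
    "refined_root_split": [["a", "b"], ["c", "d"]],
    "rooting": {"location": {"vertex": 0}, "type": "node"}
  }
}
```

Read: every edge of the star is *single* (its center is an M6 star, which
`urefine stars` reports as `alpha=0, beta=4, type=M6`), so the tree is
rooted **at the central vertex**, the single 4-way polytomy is resolved,
and the optimal refinement `((a,b),(c,d))` needs **0 duplications** — the
refined tree's root edge separates {a,b} from {c,d}, exactly the species
split. `--oracle` re-derives the minimum by exhaustive search over all
rootings × refinements and confirms it. Without refinement every rooting of
the star itself costs 1 (`urefine urcost` reports `min_cost: 1` with all
four edges optimal), illustrating why polytomies must be resolved, not
scored as hard multifurcations.

Other subcommands: `cost` (rooted ρ_K and classical RF), `urcost`
(per-edge rooting profile), `stars` (M1–M6 table, DOT export),
`enumerate` (refinement listing/counting), `simulate` (seeded synthetic
instances). All emit JSON on stdout; `--reproducible` makes runs
byte-identical.

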