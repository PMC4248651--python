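"""Binary refinement minimizing a reconciliation cost, and the reduction
from unrooted to rooted refinement.

The pipeline for an unrooted, possibly multifurcating gene tree G against a
rooted binary species tree S:

1. locate an optimal rooting of G from the edge labeling alone
   (``find_optimal_root``): an empty or double edge, or the center of the
   unique all-single M6 star;
2. refine the resulting rooted tree to a binary tree of minimum cost.

For the duplication cost the rooted refinement decomposes: the lca images
of pre-existing nodes are unchanged by resolution, so each polytomy can be
resolved independently by a local search over its (2k-3)!! binary shapes,
scored only on the children's images.  For the deep coalescence and
Robinson-Foulds costs no polynomial rooted refinement algorithm is known,
so the rooted step enumerates all refinements exhaustively under a cap
rather than substituting a heuristic.

``brute_force_best`` is the independent oracle: the exact minimum over the
whole rooting x refinement space by explicit enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .costs import lca_mapping, rho
from .errors import CapExceededError, InvalidInputError
from .trees import (DEFAULT_ENUMERATION_CAP, RNode, RootedGeneTree,
                    RootingChoice, SpeciesTree, UnrootedGeneTree, _canonical,
                    _expand_polytomy, count_binary_refinements,
                    double_factorial, iter_rooted_refinements,
                    iter_rooted_shapes, iter_unrooted_refinements)

#: Largest polytomy (child count) the local duplication search will resolve;
#: the search space per polytomy is (2k-3)!!.
DEFAULT_POLYTOMY_DEGREE_CAP = 8


@dataclass
class RefinementResult:
    """Outcome of a refinement run.

    ``rooting`` is None when the input was already rooted.  For results of
    the unrooted pipeline, ``optimal_edges`` lists every edge of the input
    attaining the minimum unrefined rooting cost (canonical order), and
    ``refined_root_split`` gives the leaf-label sides of the refined binary
    tree's root edge — the optimal edge of the refinement itself.
    """
    rooting: Optional[RootingChoice]
    refined_tree: RootedGeneTree
    cost_name: str
    cost_value: int
    n_polytomies_resolved: int
    optimal_edges: Optional[List[Tuple[int, int]]] = None
    refined_root_split: Optional[Tuple[Tuple[str, ...], Tuple[str, ...]]] = None


def _require_binary_species(species: SpeciesTree) -> None:
    if not species.is_binary():
        raise InvalidInputError("refinement needs a binary species tree")


# ---------------------------------------------------------------------------
# Local (per-polytomy) resolution under the duplication cost
# ---------------------------------------------------------------------------

def _shape_dup_cost(shape, slot_mappings: List[RNode], species: SpeciesTree
                    ) -> Tuple[RNode, int]:
    """(image, duplication count) of a resolution shape, counting the apex."""
    if isinstance(shape, int):
        return slot_mappings[shape], 0
    left, right = shape
    lm, lc = _shape_dup_cost(left, slot_mappings, species)
    rm, rc = _shape_dup_cost(right, slot_mappings, species)
    image = species.lca(lm, rm)
    dup = 1 if (image is lm or image is rm) else 0
    return image, lc + rc + dup


def _shape_canonical(shape, slot_keys):
    if isinstance(shape, int):
        return slot_keys[shape]
    left, right = shape
    return ("N",) + tuple(sorted((_shape_canonical(left, slot_keys),
                                  _shape_canonical(right, slot_keys))))


def resolve_polytomy_min_dup(child_mappings: List[RNode],
                             species: SpeciesTree,
                             slot_keys=None,
                             degree_cap: int = DEFAULT_POLYTOMY_DEGREE_CAP
                             ) -> Tuple[object, int]:
    """Minimum-duplication binary resolution of one polytomy.

    ``child_mappings`` are the species images of the polytomy's children.
    Returns the best shape (nested index pairs over the children) and its
    duplication count, including the apex node's contribution.  The search
    is exhaustive over all (2k-3)!! shapes; ties are broken by the canonical
    form of the resolved subtree (``slot_keys`` supplies the children's
    canonical keys; indices are used when absent).
    """
    k = len(child_mappings)
    if k < 2:
        raise InvalidInputError("a polytomy needs at least two children")
    if k > degree_cap:
        raise CapExceededError(
            f"polytomy with {k} children exceeds the local search cap of "
            f"{degree_cap} ({double_factorial(2 * k - 3)} shapes)")
    keys = slot_keys if slot_keys is not None else [("L", str(i)) for i in range(k)]
    best = None
    for shape in iter_rooted_shapes(k):
        _, cost = _shape_dup_cost(shape, child_mappings, species)
        candidate = (cost, _shape_canonical(shape, keys), shape)
        if best is None or candidate[:2] < best[:2]:
            best = candidate
    return best[2], best[0]


# ---------------------------------------------------------------------------
# Rooted refinement
# ---------------------------------------------------------------------------

def bin_refine_rooted(tree: RootedGeneTree, species: SpeciesTree,
                      cost: str = "dup",
                      dc_variant: str = "printed",
                      degree_cap: int = DEFAULT_POLYTOMY_DEGREE_CAP,
                      cap: int = DEFAULT_ENUMERATION_CAP
                      ) -> RefinementResult:
    """Minimum-cost binary refinement of a rooted gene tree.

    Duplication: per-polytomy local search (exact by decomposition).
    Deep coalescence / Robinson-Foulds: exhaustive enumeration under ``cap``.
    """
    _require_binary_species(species)
    missing = tree.label_set() - species.labels()
    if missing:
        raise InvalidInputError(
            f"gene-tree labels absent from the species tree: {sorted(missing)}")
    polytomies = [n for n in tree.root.postorder() if len(n.children) > 2]

    if cost == "dup":
        mapping = lca_mapping(tree, species)
        refined, nmap = tree.copy_with_map()
        for polytomy in polytomies:
            slots = polytomy.children
            shape, _ = resolve_polytomy_min_dup(
                [mapping[c] for c in slots], species,
                slot_keys=[_canonical(c) for c in slots],
                degree_cap=degree_cap)
            _expand_polytomy(nmap[polytomy], shape)
        value = rho(refined, species, "dup")
    elif cost in ("dc", "rf"):
        best = None
        for refined_candidate in iter_rooted_refinements(tree, cap=cap):
            value = rho(refined_candidate, species, cost, dc_variant=dc_variant)
            key = (value, refined_candidate.canonical())
            if best is None or key < best[0]:
                best = (key, refined_candidate)
        refined, value = best[1], best[0][0]
    else:
        raise InvalidInputError(f"unknown cost {cost!r}")

    return RefinementResult(
        rooting=None, refined_tree=refined, cost_name=cost, cost_value=value,
        n_polytomies_resolved=len(polytomies),
        refined_root_split=_root_split(refined))


def _root_split(tree: RootedGeneTree):
    if len(tree.root.children) != 2:
        return None
    sides = []
    for child in tree.root.children:
        labels = tuple(sorted(n.label for n in child.postorder() if n.is_leaf))
        sides.append(labels)
    return tuple(sorted(sides))


# ---------------------------------------------------------------------------
# Unrooted refinement (the full pipeline)
# ---------------------------------------------------------------------------

def refine_unrooted(tree: UnrootedGeneTree, species: SpeciesTree,
                    cost: str = "dup",
                    dc_variant: str = "printed",
                    degree_cap: int = DEFAULT_POLYTOMY_DEGREE_CAP,
                    cap: int = DEFAULT_ENUMERATION_CAP,
                    with_optimal_edges: bool = True) -> RefinementResult:
    """Optimal rooting + minimum-cost binary refinement of an unrooted gene
    tree: the cost of the result equals the minimum rooted cost over all
    rootings of all binary refinements of the input."""
    _require_binary_species(species)
    if cost == "rf":
        labels = tree.leaf_labels()
        if len(labels) != len(set(labels)):
            raise InvalidInputError(
                "Robinson-Foulds refinement needs repeat-free leaf labels: "
                "the optimal-rooting reduction does not extend to gene "
                "trees with duplicated labels")
    from .unrooted import find_optimal_root, unrooted_cost
    choice = find_optimal_root(tree, species)
    rooted = choice.apply(tree)
    inner = bin_refine_rooted(rooted, species, cost, dc_variant=dc_variant,
                              degree_cap=degree_cap, cap=cap)
    optimal_edges = None
    if with_optimal_edges:
        _, optimal_edges = unrooted_cost(tree, species, cost,
                                         dc_variant=dc_variant)
    return RefinementResult(
        rooting=choice, refined_tree=inner.refined_tree, cost_name=cost,
        cost_value=inner.cost_value,
        n_polytomies_resolved=inner.n_polytomies_resolved,
        optimal_edges=optimal_edges,
        refined_root_split=_root_split(inner.refined_tree))


# ---------------------------------------------------------------------------
# Exhaustive oracles
# ---------------------------------------------------------------------------

def brute_force_best_rooted(tree: RootedGeneTree, species: SpeciesTree,
                            cost: str = "dup", dc_variant: str = "printed",
                            cap: int = DEFAULT_ENUMERATION_CAP
                            ) -> Tuple[int, RootedGeneTree]:
    """Exact minimum cost over all binary refinements of a rooted tree, by
    global enumeration; the oracle the decomposed refinement is checked
    against."""
    best = None
    for refined in iter_rooted_refinements(tree, cap=cap):
        value = rho(refined, species, cost, dc_variant=dc_variant)
        key = (value, refined.canonical())
        if best is None or key < best[0]:
            best = (key, refined)
    return best[0][0], best[1]


def brute_force_best(tree: UnrootedGeneTree, species: SpeciesTree,
                     cost: str = "dup",
                     include_node_rootings: bool = True,
                     dc_variant: str = "printed",
                     cap: int = DEFAULT_ENUMERATION_CAP
                     ) -> Tuple[int, RootedGeneTree]:
    """Exact minimum of the rooted cost over the rooting x refinement space.

    Organized refinement-first: every unrooted binary refinement is
    enumerated with edge provenance, and each is rooted on every edge (all
    edges when node rootings are included — rootings on resolution edges
    are exactly the refinements of node rootings — or only on edges of the
    input otherwise).  Returns the minimum and a rooted witness.
    """
    _validate = tree.label_set() - species.labels()
    if _validate:
        raise InvalidInputError(
            f"gene-tree labels absent from the species tree: {sorted(_validate)}")
    n_edges = 2 * len(tree.leaves()) - 3
    space = count_binary_refinements(tree) * max(n_edges, 1)
    if space > cap:
        raise CapExceededError(
            f"brute-force space of {space} rootings x refinements exceeds "
            f"the cap of {cap}")
    best = None
    for refined in iter_unrooted_refinements(tree, cap=cap):
        for edge in refined.edges():
            if not include_node_rootings and frozenset(edge) in refined.new_edges:
                continue
            candidate = refined.root_at_edge(edge)
            value = rho(candidate, species, cost, dc_variant=dc_variant)
            if best is None or value < best[0]:
                best = (value, candidate)
    if best is None:
        raise InvalidInputError("empty search space")
    return best
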