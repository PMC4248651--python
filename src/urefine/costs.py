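"""Rooted comparison costs between a gene tree and a species tree.

Every cost in the family is a sum of per-node contributions over the
internal nodes of the gene tree, evaluated under the least-common-ancestor
(lca) mapping M:

* duplication (``dup``): a node contributes 1 when it shares its image with
  one of its children (a duplication node);
* deep coalescence (``dc``): a node contributes the species-tree path length
  ||M(g), M(c)|| summed over its children c;
* Robinson-Foulds (``rf``): a node contributes 1 when its cluster differs
  from the cluster of its image.

All costs are exact integers and are well-defined for multifurcating gene
trees, which the refinement machinery relies on.

The ``dc`` contribution is used exactly in the per-edge path-length form
above; the classical "extra lineages" convention, which subtracts one per
child edge, is available as ``dc_variant="minus_one_per_edge"``.  The two
differ by a constant offset per tree shape only, so optimal rootings and
refinement structure are unaffected; note the path-length form is strictly
positive even on identical binary trees (it equals 4 for identical 3-leaf
trees).
"""

from __future__ import annotations

from typing import Dict, Optional

from .errors import InvalidInputError
from .trees import RNode, RootedGeneTree, SpeciesTree

COST_NAMES = ("dup", "dc", "rf")


def lca_mapping(tree: RootedGeneTree, species: SpeciesTree
                ) -> Dict[RNode, RNode]:
    """The lca mapping M: each leaf goes to the species leaf with its label,
    each internal node to the lca of its children's images."""
    mapping: Dict[RNode, RNode] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            mapping[node] = species.leaf(node.label)
        else:
            mapping[node] = species.lca_many(mapping[c] for c in node.children)
    return mapping


def duplication_cost(tree: RootedGeneTree, species: SpeciesTree,
                     mapping: Optional[Dict[RNode, RNode]] = None) -> int:
    """Number of duplication nodes: internal g with a child c such that
    M(g) = M(c)."""
    m = mapping if mapping is not None else lca_mapping(tree, species)
    total = 0
    for node in tree.internal_nodes():
        if any(m[c] is m[node] for c in node.children):
            total += 1
    return total


def deep_coalescence_cost(tree: RootedGeneTree, species: SpeciesTree,
                          mapping: Optional[Dict[RNode, RNode]] = None,
                          variant: str = "printed") -> int:
    """Sum over internal g and children c of ||M(g), M(c)||.

    variant="minus_one_per_edge" subtracts 1 for every child edge (the
    classical extra-lineages convention).
    """
    if variant not in ("printed", "minus_one_per_edge"):
        raise InvalidInputError(f"unknown dc variant {variant!r}")
    m = mapping if mapping is not None else lca_mapping(tree, species)
    total = 0
    for node in tree.internal_nodes():
        for child in node.children:
            total += species.distance(m[node], m[child])
            if variant == "minus_one_per_edge":
                total -= 1
    return total


def rf_rho(tree: RootedGeneTree, species: SpeciesTree,
           mapping: Optional[Dict[RNode, RNode]] = None) -> int:
    """Number of internal gene nodes whose cluster is not a species-tree
    cluster of their image: c(g) != c(M(g))."""
    m = mapping if mapping is not None else lca_mapping(tree, species)
    clusters = tree.clusters()
    total = 0
    for node in tree.internal_nodes():
        if clusters[node] != species.cluster[m[node]]:
            total += 1
    return total


def _check_bijective(tree: RootedGeneTree, species: SpeciesTree) -> None:
    gene_labels = tree.leaf_labels()
    if len(gene_labels) != len(set(gene_labels)) or \
            set(gene_labels) != species.labels():
        raise InvalidInputError(
            "the classical RF distance needs a bijective leaf labeling "
            "onto the species set")


def classic_rf(tree: RootedGeneTree, species: SpeciesTree) -> int:
    """Classical rooted Robinson-Foulds distance, via the conversion
    |I(S)| + 2*rho_RF(T,S) - |I(T)|; requires a bijective leaf labeling."""
    _check_bijective(tree, species)
    return (len(species.internal_nodes())
            + 2 * rf_rho(tree, species)
            - len(tree.internal_nodes()))


def cluster_symmetric_difference(tree: RootedGeneTree,
                                 species: SpeciesTree) -> int:
    """Classical rooted Robinson-Foulds distance computed directly as the
    symmetric difference of the internal-node cluster sets."""
    _check_bijective(tree, species)
    gene_clusters = {c for n, c in tree.clusters().items() if not n.is_leaf}
    species_clusters = {species.cluster[n] for n in species.internal_nodes()}
    return len(gene_clusters ^ species_clusters)


def rho(tree: RootedGeneTree, species: SpeciesTree, cost: str = "dup",
        mapping: Optional[Dict[RNode, RNode]] = None,
        dc_variant: str = "printed") -> int:
    """Dispatch to one of the internal-node-sum costs by name."""
    if cost == "dup":
        return duplication_cost(tree, species, mapping)
    if cost == "dc":
        return deep_coalescence_cost(tree, species, mapping, variant=dc_variant)
    if cost == "rf":
        return rf_rho(tree, species, mapping)
    raise InvalidInputError(f"unknown cost {cost!r}")
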