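"""Unrooted reconciliation: directed edge labeling, star classification,
per-edge rooting costs, and the linear-scan optimal-root locator.

The gene tree is viewed as a directed graph in which every undirected edge
{x, y} carries two labels: the label of <x, y> is the lca, in the species
tree, of the species images of all gene leaves in the component containing
x once the edge is removed.  TOP denotes the lca of the images of all
leaves of the gene tree (the root of the species tree restricted to the
instance; a proper descendant of the species root when only a subset of
species appears in the gene tree).

Every internal vertex, together with its incident edges, forms a star that
is classified by two counts over its k edges:

* alpha — edges whose subtree-side label (toward the center) is TOP;
* beta  — edges whose remainder-side label (away from the center) is TOP.

Star types: M1 (alpha=1, beta=k-1), M2 (0, k-1), M3 (1, k), M4 (k, k),
M5 (1<alpha<k, beta=k), M6 (0, k).  Since at most one subtree can be
indispensable for reaching TOP, beta is always k-1 or k and the six types
are exhaustive.  An edge is *empty* when neither label is TOP, *double*
when both are, *single* otherwise.  Empty edges, double edges, and the
edges of an M6 star are exactly the optimal places to root the tree, which
the locator exploits: it walks along single edges into the TOP-spanning
component (M1 stars) until it reaches a vertex incident to an empty or
double edge, or the center of the unique all-single M6 star.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .costs import rho
from .errors import InternalConsistencyError, InvalidInputError
from .trees import RNode, RootingChoice, SpeciesTree, UnrootedGeneTree

STAR_TYPES = ("M1", "M2", "M3", "M4", "M5", "M6")


@dataclass
class EdgeLabeling:
    """Both direction labels of every edge, plus the instance top TOP."""
    tree: UnrootedGeneTree
    species: SpeciesTree
    labels: Dict[Tuple[int, int], RNode]    # directed (tail, head) -> S node
    top: RNode

    def label(self, x: int, y: int) -> RNode:
        return self.labels[(x, y)]

    def edge_kind(self, x: int, y: int) -> str:
        a = self.labels[(x, y)] is self.top
        b = self.labels[(y, x)] is self.top
        if a and b:
            return "double"
        if a or b:
            return "single"
        return "empty"


@dataclass
class StarReport:
    """Classification of the star around one internal vertex."""
    center: int
    neighbors: List[int]
    subtree_labels: List[RNode]     # label of <w_i, center>, per neighbor
    remainder_labels: List[RNode]   # label of <center, w_i>, per neighbor
    alpha: int
    beta: int
    star_type: str
    edge_kinds: List[str] = field(default_factory=list)


def _validate_instance(tree: UnrootedGeneTree, species: SpeciesTree) -> None:
    if len(tree.leaves()) < 3:
        raise InvalidInputError("the gene tree needs at least three leaves")
    missing = tree.label_set() - species.labels()
    if missing:
        raise InvalidInputError(
            f"gene-tree labels absent from the species tree: {sorted(missing)}")


def label_edges(tree: UnrootedGeneTree, species: SpeciesTree) -> EdgeLabeling:
    """Label both directions of every edge in two passes: a leafward
    accumulation toward an arbitrary internal vertex, then a rootward
    broadcast using prefix/suffix lca folds (linear number of lca calls)."""
    _validate_instance(tree, species)
    start = tree.internal_vertices()[0]

    order: List[Tuple[int, int]] = []           # (vertex, parent) in BFS order
    parent: Dict[int, Optional[int]] = {start: None}
    queue = [start]
    while queue:
        v = queue.pop(0)
        for w in tree.adj[v]:
            if w != parent[v]:
                parent[w] = v
                order.append((w, v))
                queue.append(w)

    labels: Dict[Tuple[int, int], RNode] = {}
    # pass 1: labels pointing toward the start vertex
    for v, p in reversed(order):
        if v in tree.labels:
            labels[(v, p)] = species.leaf(tree.labels[v])
        else:
            labels[(v, p)] = species.lca_many(
                labels[(w, v)] for w in tree.adj[v] if w != p)
    # pass 2: labels pointing away from the start vertex
    for v, p in order:
        incoming: List[RNode] = []
        if parent[p] is not None:
            incoming.append(labels[(parent[p], p)])
        siblings = [w for w in tree.adj[p] if w != parent[p] and w != v]
        incoming.extend(labels[(w, p)] for w in siblings)
        labels[(p, v)] = species.lca_many(incoming)

    top = species.lca_many(
        species.leaf(lbl) for lbl in tree.labels.values())
    return EdgeLabeling(tree=tree, species=species, labels=labels, top=top)


def classify_star(labeling: EdgeLabeling, v: int) -> StarReport:
    """Assign exactly one of the six star types to an internal vertex."""
    tree = labeling.tree
    if tree.degree(v) < 3:
        raise InvalidInputError("stars are defined for internal vertices only")
    neighbors = list(tree.adj[v])
    subtree = [labeling.label(w, v) for w in neighbors]
    remainder = [labeling.label(v, w) for w in neighbors]
    top = labeling.top
    alpha = sum(1 for x in subtree if x is top)
    beta = sum(1 for x in remainder if x is top)
    k = len(neighbors)
    if alpha == 1 and beta == k - 1:
        star_type = "M1"
    elif alpha == 0 and beta == k - 1:
        star_type = "M2"
    elif alpha == 1 and beta == k:
        star_type = "M3"
    elif alpha == k and beta == k:
        star_type = "M4"
    elif 1 < alpha < k and beta == k:
        star_type = "M5"
    elif alpha == 0 and beta == k:
        star_type = "M6"
    else:
        raise InternalConsistencyError(
            f"unclassifiable star at vertex {v}: alpha={alpha}, beta={beta}, "
            f"k={k} (labeling bug)")
    kinds = [labeling.edge_kind(v, w) for w in neighbors]
    return StarReport(center=v, neighbors=neighbors, subtree_labels=subtree,
                      remainder_labels=remainder, alpha=alpha, beta=beta,
                      star_type=star_type, edge_kinds=kinds)


def star_table(tree: UnrootedGeneTree, species: SpeciesTree
               ) -> List[StarReport]:
    labeling = label_edges(tree, species)
    return [classify_star(labeling, v) for v in tree.internal_vertices()]


def rooting_cost_profile(tree: UnrootedGeneTree, species: SpeciesTree,
                         cost: str = "dup", dc_variant: str = "printed"
                         ) -> Dict[Tuple[int, int], int]:
    """The rooted cost of every edge rooting, by explicit re-rooting.

    This is the brute-force evaluation of the unrooted objective; quadratic
    overall, used for reports and as the reference the locator is checked
    against.
    """
    _validate_instance(tree, species)
    return {edge: rho(tree.root_at_edge(edge), species, cost,
                      dc_variant=dc_variant)
            for edge in tree.edges()}


def unrooted_cost(tree: UnrootedGeneTree, species: SpeciesTree,
                  cost: str = "dup", dc_variant: str = "printed"
                  ) -> Tuple[int, List[Tuple[int, int]]]:
    """Minimum rooted cost over all edge rootings, with the full set of
    optimal edges in canonical order."""
    profile = rooting_cost_profile(tree, species, cost, dc_variant=dc_variant)
    best = min(profile.values())
    optimal = [e for e in tree.edges_canonical() if profile[e] == best]
    return best, optimal


def find_optimal_root(tree: UnrootedGeneTree, species: SpeciesTree,
                      start: Optional[int] = None) -> RootingChoice:
    """Locate an optimal rooting by the single walk over the edge labeling.

    From any internal start vertex, repeatedly move across an edge whose
    label toward the current vertex is TOP while the label away from it is
    not (the M1 step, into the TOP-spanning component).  The walk ends at a
    vertex incident to an empty or double edge — root there — or at the
    center of the unique all-single M6 star — root at the vertex itself.
    The returned rooting attains the minimum rooted cost over all edge
    rootings for the duplication cost, and the same location is optimal for
    the deep coalescence and Robinson-Foulds costs.
    """
    labeling = label_edges(tree, species)
    top = labeling.top
    if start is None:
        leaf = min(tree.leaves(), key=lambda u: (tree.labels[u], u))
        start = tree.adj[leaf][0]
    elif tree.degree(start) < 3:
        raise InvalidInputError("the walk must start at an internal vertex")
    v = start
    visited = {v}
    while True:
        step = None
        for w in tree.adj[v]:
            if (labeling.label(w, v) is top
                    and labeling.label(v, w) is not top):
                step = w
                break
        if step is None:
            break
        if step in visited:
            raise InternalConsistencyError(
                "the root-locating walk revisited a vertex (labeling bug)")
        visited.add(step)
        v = step
    for w in sorted(tree.adj[v], key=lambda w: (tree.edge_split(
            (min(v, w), max(v, w))), w)):
        if labeling.edge_kind(v, w) in ("empty", "double"):
            return RootingChoice(kind="edge", edge=(min(v, w), max(v, w)))
    report = classify_star(labeling, v)
    if report.star_type != "M6":
        raise InternalConsistencyError(
            f"walk ended in a star of type {report.star_type} with no "
            "empty/double edge (labeling bug)")
    return RootingChoice(kind="node", node=v)


# ---------------------------------------------------------------------------
# Annotated exports (the decorated-graph views)
# ---------------------------------------------------------------------------

def _species_name(species: SpeciesTree, node: RNode) -> str:
    if node.is_leaf:
        return node.label
    return "{" + ",".join(sorted(species.cluster[node])) + "}"


def edges_tsv(tree: UnrootedGeneTree, species: SpeciesTree,
              costs: Tuple[str, ...] = ("dup",),
              dc_variant: str = "printed") -> str:
    """Per-edge table: endpoints, both direction labels, kind, and the
    rooted cost of rooting on the edge for each requested cost."""
    labeling = label_edges(tree, species)
    profiles = {c: rooting_cost_profile(tree, species, c, dc_variant=dc_variant)
                for c in costs}
    header = ["u", "v", "label_uv", "label_vu", "kind"]
    header += [f"cost_{c}" for c in costs]
    rows = ["\t".join(header)]
    for (u, v) in tree.edges_canonical():
        row = [str(u), str(v),
               _species_name(species, labeling.label(u, v)),
               _species_name(species, labeling.label(v, u)),
               labeling.edge_kind(u, v)]
        row += [str(profiles[c][(u, v)]) for c in costs]
        rows.append("\t".join(row))
    return "\n".join(rows) + "\n"


def stars_tsv(tree: UnrootedGeneTree, species: SpeciesTree) -> str:
    rows = ["\t".join(["center", "k", "alpha", "beta", "type", "edge_kinds"])]
    for report in star_table(tree, species):
        rows.append("\t".join([
            str(report.center), str(len(report.neighbors)),
            str(report.alpha), str(report.beta), report.star_type,
            ",".join(report.edge_kinds)]))
    return "\n".join(rows) + "\n"


def to_dot(tree: UnrootedGeneTree, species: SpeciesTree) -> str:
    """GraphViz export of the doubly-labeled gene tree, one edge per
    undirected edge with both direction labels and the edge kind."""
    labeling = label_edges(tree, species)
    lines = ["graph gene_tree {"]
    for v in tree.vertices():
        if v in tree.labels:
            lines.append(f'  n{v} [label="{tree.labels[v]}", shape=plaintext];')
        else:
            lines.append(f'  n{v} [label="", shape=point];')
    style = {"empty": "solid", "single": "dashed", "double": "bold"}
    for (u, v) in tree.edges_canonical():
        kind = labeling.edge_kind(u, v)
        lab = (f"{_species_name(species, labeling.label(u, v))} | "
               f"{_species_name(species, labeling.label(v, u))}")
        lines.append(f'  n{u} -- n{v} [label="{lab}", style={style[kind]}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
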