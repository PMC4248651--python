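"""Tree data model: species trees, rooted/unrooted gene trees, Newick I/O,
edge contraction, rooting, and binary-refinement enumeration.

Conventions used throughout the package:

* Child order is never semantically meaningful.  Every comparison and every
  serialization goes through a canonical form in which children are sorted
  by a structural key, so two trees are "the same" exactly when they are
  related by a label-preserving isomorphism.
* Gene-tree leaf labels are species names and may repeat; species-tree leaf
  labels must be unique.
* An unrooted tree has no degree-two vertices.  Rooting at an edge inserts
  a fresh root subdividing it (one extra node); rooting at an internal
  vertex promotes the vertex itself to the root (same node count).
* Branch lengths are parsed and ignored; internal node labels are ignored.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple

import dendropy

from .errors import CapExceededError, InvalidInputError

#: Default ceiling on the number of binary refinements any enumeration is
#: allowed to produce; protects against factorial blowup on large polytomies.
DEFAULT_ENUMERATION_CAP = 100_000


def double_factorial(n: int) -> int:
    """n!! for odd n (and 1 for n <= 0), the count of binary resolutions."""
    result = 1
    while n > 1:
        result *= n
        n -= 2
    return result


# ---------------------------------------------------------------------------
# Rooted trees
# ---------------------------------------------------------------------------

class RNode:
    """A node of a rooted tree.

    ``is_new`` marks nodes introduced by polytomy resolution, so a
    refinement can later be contracted back to the tree it refines.
    """

    __slots__ = ("label", "children", "parent", "is_new")

    def __init__(self, label: Optional[str] = None,
                 children: Optional[List["RNode"]] = None,
                 is_new: bool = False):
        self.label = label
        self.children: List[RNode] = []
        self.parent: Optional[RNode] = None
        self.is_new = is_new
        if children:
            for child in children:
                self.add_child(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "RNode") -> None:
        child.parent = self
        self.children.append(child)

    def postorder(self) -> Iterator["RNode"]:
        stack: List[Tuple[RNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["RNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)


def _canonical(node: RNode):
    """Structural key: equal for two subtrees iff they are label-isomorphic."""
    if node.is_leaf:
        return ("L", node.label)
    return ("N",) + tuple(sorted(_canonical(c) for c in node.children))


class RootedGeneTree:
    """Rooted, possibly multifurcating, leaf-labeled gene tree.

    Invariants checked on construction: every leaf carries a label and every
    internal node has at least two children.
    """

    def __init__(self, root: RNode):
        self.root = root
        for node in root.postorder():
            if node.is_leaf:
                if node.label is None:
                    raise InvalidInputError("unlabeled leaf in gene tree")
            elif len(node.children) < 2:
                raise InvalidInputError("internal node with fewer than 2 children")

    # -- queries ------------------------------------------------------------

    def nodes(self) -> List[RNode]:
        return list(self.root.postorder())

    def leaves(self) -> List[RNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def internal_nodes(self) -> List[RNode]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def leaf_labels(self) -> List[str]:
        """Sorted leaf-label list, with multiplicity."""
        return sorted(n.label for n in self.leaves())

    def label_set(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    def clusters(self) -> Dict[RNode, frozenset]:
        out: Dict[RNode, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                acc = frozenset()
                for child in node.children:
                    acc |= out[child]
                out[node] = acc
        return out

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def canonical(self):
        return _canonical(self.root)

    # -- construction helpers ----------------------------------------------

    def copy_with_map(self) -> Tuple["RootedGeneTree", Dict[RNode, RNode]]:
        mapping: Dict[RNode, RNode] = {}
        for node in self.root.postorder():
            clone = RNode(label=node.label, is_new=node.is_new)
            for child in node.children:
                clone.add_child(mapping[child])
            mapping[node] = clone
        return RootedGeneTree(mapping[self.root]), mapping

    def copy(self) -> "RootedGeneTree":
        return self.copy_with_map()[0]

    def newick(self) -> str:
        return _rooted_newick(self.root)

    def unroot(self) -> "UnrootedGeneTree":
        """Inverse of rooting.

        A binary root (two children) is suppressed, merging its two incident
        edges; a multifurcating root becomes an ordinary internal vertex.
        Edges of the result whose construction involved a resolution node are
        recorded in ``new_edges``.
        """
        ids: Dict[RNode, int] = {}
        for i, node in enumerate(self.root.preorder()):
            ids[node] = i
        adj: Dict[int, List[int]] = {ids[n]: [] for n in ids}
        labels: Dict[int, str] = {}
        new_edges = set()

        def connect(u: RNode, v: RNode, is_new: bool) -> None:
            adj[ids[u]].append(ids[v])
            adj[ids[v]].append(ids[u])
            if is_new:
                new_edges.add(frozenset((ids[u], ids[v])))

        root_children = self.root.children
        if len(root_children) == 2:
            a, b = root_children
            del adj[ids[self.root]]
            connect(a, b, a.is_new or b.is_new)
            skip_root = True
        elif len(root_children) >= 3:
            skip_root = False
        else:
            raise InvalidInputError("cannot unroot a single-leaf tree")
        for node in self.root.preorder():
            if node.is_leaf:
                labels[ids[node]] = node.label
            for child in node.children:
                if skip_root and node is self.root:
                    continue
                connect(node, child, child.is_new)
        tree = UnrootedGeneTree(adj, labels)
        tree.new_edges = frozenset(new_edges)
        return tree


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted species tree with unique leaf labels.

    Precomputes parent/depth tables so least-common-ancestor queries and
    path lengths are cheap; these back the lca mapping and the deep
    coalescence cost.
    """

    def __init__(self, root: RNode):
        self.root = root
        self.nodes: List[RNode] = list(root.postorder())
        self.depth: Dict[RNode, int] = {}
        for node in root.preorder():
            self.depth[node] = 0 if node.parent is None else self.depth[node.parent] + 1
        self.leaf_by_label: Dict[str, RNode] = {}
        for node in self.nodes:
            if node.is_leaf:
                if node.label is None:
                    raise InvalidInputError("unlabeled leaf in species tree")
                if node.label in self.leaf_by_label:
                    raise InvalidInputError(
                        f"duplicate species label {node.label!r}")
                self.leaf_by_label[node.label] = node
            elif len(node.children) < 2:
                raise InvalidInputError("internal node with fewer than 2 children")
        self.cluster: Dict[RNode, frozenset] = {}
        for node in self.nodes:
            if node.is_leaf:
                self.cluster[node] = frozenset([node.label])
            else:
                acc = frozenset()
                for child in node.children:
                    acc |= self.cluster[child]
                self.cluster[node] = acc

    def labels(self) -> frozenset:
        return frozenset(self.leaf_by_label)

    def internal_nodes(self) -> List[RNode]:
        return [n for n in self.nodes if not n.is_leaf]

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def leaf(self, label: str) -> RNode:
        try:
            return self.leaf_by_label[label]
        except KeyError:
            raise InvalidInputError(
                f"gene-tree label {label!r} absent from the species tree") from None

    def lca(self, x: RNode, y: RNode) -> RNode:
        while self.depth[x] > self.depth[y]:
            x = x.parent
        while self.depth[y] > self.depth[x]:
            y = y.parent
        while x is not y:
            x = x.parent
            y = y.parent
        return x

    def lca_many(self, nodes) -> RNode:
        it = iter(nodes)
        try:
            acc = next(it)
        except StopIteration:
            raise InvalidInputError("lca of an empty node set") from None
        for node in it:
            acc = self.lca(acc, node)
        return acc

    def distance(self, x: RNode, y: RNode) -> int:
        """Number of edges on the path between x and y."""
        return self.depth[x] + self.depth[y] - 2 * self.depth[self.lca(x, y)]

    def newick(self) -> str:
        return _rooted_newick(self.root)

    def canonical(self):
        return _canonical(self.root)


# ---------------------------------------------------------------------------
# Unrooted trees
# ---------------------------------------------------------------------------

class UnrootedGeneTree:
    """Unrooted, possibly multifurcating, leaf-labeled gene tree.

    Vertices are integers; ``adj`` maps each vertex to its (sorted) neighbor
    list and ``labels`` maps each degree-one vertex to its species name.
    ``new_edges`` is non-empty only on trees produced by refinement and
    records the resolution edges, so refinements can be contracted back.
    """

    def __init__(self, adj: Dict[int, List[int]], labels: Dict[int, str]):
        self.adj: Dict[int, List[int]] = {v: sorted(ns) for v, ns in adj.items()}
        self.labels = dict(labels)
        self.new_edges: frozenset = frozenset()
        self._validate()

    def _validate(self) -> None:
        n_edges = sum(len(ns) for ns in self.adj.values())
        if n_edges % 2 != 0:
            raise InvalidInputError("inconsistent adjacency")
        n_edges //= 2
        if n_edges != len(self.adj) - 1:
            raise InvalidInputError("not a tree (edge count)")
        if self.adj:
            seen = set()
            stack = [next(iter(self.adj))]
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                stack.extend(self.adj[v])
            if len(seen) != len(self.adj):
                raise InvalidInputError("not a tree (disconnected)")
        for v, ns in self.adj.items():
            if len(ns) == 2:
                raise InvalidInputError("degree-two vertex in unrooted tree")
            if len(ns) <= 1 and v not in self.labels:
                raise InvalidInputError("unlabeled leaf in unrooted tree")
            if len(ns) >= 3 and v in self.labels:
                raise InvalidInputError("label attached to an internal vertex")

    # -- queries ------------------------------------------------------------

    def vertices(self) -> List[int]:
        return sorted(self.adj)

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def leaves(self) -> List[int]:
        return sorted(v for v in self.adj if len(self.adj[v]) == 1)

    def internal_vertices(self) -> List[int]:
        return sorted(v for v in self.adj if len(self.adj[v]) >= 3)

    def edges(self) -> List[Tuple[int, int]]:
        return sorted((min(u, v), max(u, v))
                      for u in self.adj for v in self.adj[u] if u < v)

    def leaf_labels(self) -> List[str]:
        return sorted(self.labels.values())

    def label_set(self) -> frozenset:
        return frozenset(self.labels.values())

    def is_binary(self) -> bool:
        return all(len(ns) == 3 for v, ns in self.adj.items() if len(ns) > 1)

    def side_labels(self, x: int, y: int) -> Tuple[str, ...]:
        """Sorted labels (with multiplicity) of the component containing x
        once edge {x, y} is removed."""
        seen = {y, x}
        stack = [x]
        out: List[str] = []
        while stack:
            v = stack.pop()
            if v in self.labels:
                out.append(self.labels[v])
            for w in self.adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return tuple(sorted(out))

    def edge_split(self, edge: Tuple[int, int]):
        """Canonical key of an edge: the sorted pair of its side label lists."""
        u, v = edge
        return tuple(sorted((self.side_labels(u, v), self.side_labels(v, u))))

    def edges_canonical(self) -> List[Tuple[int, int]]:
        """Edges sorted by their canonical leaf-set keys (ties by vertex ids),
        the deterministic order used in every report."""
        return sorted(self.edges(), key=lambda e: (self.edge_split(e), e))

    # -- rooting ------------------------------------------------------------

    def _subtree(self, v: int, parent: int) -> RNode:
        node = RNode(label=self.labels.get(v))
        for w in self.adj[v]:
            if w != parent:
                node.add_child(self._subtree(w, v))
        return node

    def root_at_edge(self, edge: Tuple[int, int]) -> RootedGeneTree:
        u, v = edge
        if v not in self.adj.get(u, ()):  # also rejects unknown vertices
            raise InvalidInputError(f"edge {edge!r} not in the tree")
        root = RNode(children=[self._subtree(u, v), self._subtree(v, u)])
        return RootedGeneTree(root)

    def root_at_node(self, v: int) -> RootedGeneTree:
        if v not in self.adj:
            raise InvalidInputError(f"vertex {v!r} not in the tree")
        if len(self.adj[v]) < 3:
            raise InvalidInputError("cannot root at a leaf")
        root = RNode(children=[self._subtree(w, v) for w in self.adj[v]])
        return RootedGeneTree(root)

    # -- canonical form / output --------------------------------------------

    def canonical(self):
        return min(self.root_at_edge(e).canonical() for e in self.edges())

    def copy(self) -> "UnrootedGeneTree":
        tree = UnrootedGeneTree(self.adj, self.labels)
        tree.new_edges = self.new_edges
        return tree

    def newick(self) -> str:
        leaf = min(self.leaves(), key=lambda v: (self.labels[v], v))
        if len(self.adj) < 2:
            raise InvalidInputError("cannot serialize a single-vertex tree")
        center = self.adj[leaf][0]
        if len(self.adj[center]) < 3:
            raise InvalidInputError("unrooted tree needs an internal vertex")
        parts = sorted(
            (_canonical(self._subtree(w, center)), _newick_part(self._subtree(w, center)))
            for w in self.adj[center])
        return "(" + ",".join(p for _, p in parts) + ");"


@dataclass(frozen=True)
class RootingChoice:
    """Where to root an unrooted gene tree: on an edge, or at a vertex."""
    kind: str                                   # "edge" | "node"
    edge: Optional[Tuple[int, int]] = None
    node: Optional[int] = None

    def apply(self, tree: UnrootedGeneTree) -> RootedGeneTree:
        if self.kind == "edge":
            return tree.root_at_edge(self.edge)
        return tree.root_at_node(self.node)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _escape(label: str) -> str:
    if label == "" or _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_part(node: RNode) -> str:
    if node.is_leaf:
        return _escape(node.label)
    parts = sorted((_canonical(c), _newick_part(c)) for c in node.children)
    return "(" + ",".join(p for _, p in parts) + ")"


def _rooted_newick(root: RNode) -> str:
    return _newick_part(root) + ";"


def _from_dendropy(dnode) -> RNode:
    label = None
    if not dnode.child_nodes():
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        if label is None:
            raise InvalidInputError("unlabeled leaf in Newick input")
    node = RNode(label=label)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def _suppress_unary(node: RNode) -> RNode:
    while len(node.children) == 1:
        node = node.children[0]
        node.parent = None
    node.children = [_suppress_unary(c) for c in node.children]
    for child in node.children:
        child.parent = node
    return node


def parse_newick(text: str, mode: str = "rooted"):
    """Parse a Newick string.

    mode="rooted"   -> RootedGeneTree (repeated leaf labels allowed)
    mode="species"  -> SpeciesTree (unique leaf labels enforced)
    mode="unrooted" -> UnrootedGeneTree; a binary-rooted-looking Newick is
        accepted by suppressing the degree-two root; at least three leaves
        and one internal vertex are required, and any other degree-two
        vertex is an error.
    """
    if mode not in ("rooted", "species", "unrooted"):
        raise ValueError(f"unknown parse mode {mode!r}")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True,
                                  suppress_leaf_node_taxa=True)
    except Exception as exc:  # dendropy raises a mix of error types
        raise InvalidInputError(f"malformed Newick: {exc}") from None
    root = _suppress_unary(_from_dendropy(dtree.seed_node))
    if mode == "species":
        return SpeciesTree(root)
    if mode == "rooted":
        return RootedGeneTree(root)
    # unrooted
    if root.is_leaf or len(root.children) < 2:
        raise InvalidInputError("an unrooted tree needs at least 3 leaves")
    tree = RootedGeneTree(root).unroot()
    if len(tree.leaves()) < 3:
        raise InvalidInputError("an unrooted tree needs at least 3 leaves")
    tree.new_edges = frozenset()
    return tree


def write_newick(tree) -> str:
    return tree.newick()


# ---------------------------------------------------------------------------
# Contraction
# ---------------------------------------------------------------------------

def contract_edge(tree, edge):
    """Contract an internal edge, merging its endpoints; returns a new tree.

    For a rooted tree the edge is the (parent, child) pair of the input's own
    nodes; for an unrooted tree it is a vertex pair.  Leaf edges cannot be
    contracted.
    """
    if isinstance(tree, RootedGeneTree):
        parent, child = edge
        if child.is_leaf:
            raise InvalidInputError("cannot contract a leaf edge")
        if child.parent is not parent:
            raise InvalidInputError("edge is not a parent-child pair of this tree")
        copy, nmap = tree.copy_with_map()
        p, c = nmap[parent], nmap[child]
        idx = p.children.index(c)
        p.children[idx:idx + 1] = c.children
        for grandchild in c.children:
            grandchild.parent = p
        return RootedGeneTree(copy.root)
    if isinstance(tree, UnrootedGeneTree):
        u, v = edge
        if v not in tree.adj.get(u, ()):
            raise InvalidInputError(f"edge {edge!r} not in the tree")
        if len(tree.adj[u]) == 1 or len(tree.adj[v]) == 1:
            raise InvalidInputError("cannot contract a leaf edge")
        adj = {w: [x for x in ns] for w, ns in tree.adj.items()}
        merged = [w for w in adj[u] if w != v] + [w for w in adj[v] if w != u]
        del adj[v]
        adj[u] = merged
        for w in merged:
            adj[w] = [u if x == v else x for x in adj[w]]
        result = UnrootedGeneTree(adj, tree.labels)
        # carry over resolution-edge provenance, minus the contracted edge
        contracted = frozenset((u, v))
        result.new_edges = frozenset(
            frozenset(u if x == v else x for x in e)
            for e in tree.new_edges if e != contracted)
        return result
    raise TypeError("contract_edge expects a gene tree")


def contract_new_edges(tree: RootedGeneTree) -> RootedGeneTree:
    """Undo a refinement: contract every edge leading into a resolution node."""
    copy, _ = tree.copy_with_map()
    changed = True
    while changed:
        changed = False
        for node in list(copy.root.postorder()):
            if node.is_new and node.parent is not None:
                p = node.parent
                idx = p.children.index(node)
                p.children[idx:idx + 1] = node.children
                for child in node.children:
                    child.parent = p
                changed = True
    return RootedGeneTree(copy.root)


# ---------------------------------------------------------------------------
# Binary refinement enumeration
# ---------------------------------------------------------------------------

def iter_rooted_shapes(k: int) -> Iterator:
    """All rooted binary tree shapes over k distinguishable slots, as nested
    index pairs; there are (2k-3)!! of them.  Generated by sequential leaf
    insertion (each new slot joined at every node of every smaller shape)."""
    if k < 1:
        raise ValueError("need at least one slot")
    if k == 1:
        yield 0
        return
    for shape in iter_rooted_shapes(k - 1):
        yield from _insertions(shape, k - 1)


def _insertions(shape, i: int) -> Iterator:
    yield (shape, i)
    if isinstance(shape, tuple):
        left, right = shape
        for new_left in _insertions(left, i):
            yield (new_left, right)
        for new_right in _insertions(right, i):
            yield (left, new_right)


def build_shape(shape, slots: List[RNode]) -> RNode:
    """Materialize a shape over already-built child subtrees; inner nodes are
    flagged as resolution nodes."""
    if isinstance(shape, int):
        return slots[shape]
    left, right = shape
    return RNode(children=[build_shape(left, slots), build_shape(right, slots)],
                 is_new=True)


def count_binary_refinements(tree) -> int:
    """Closed-form refinement count: product of (2k-3)!! over rooted nodes
    with k children, or of (2d-5)!! over unrooted vertices of degree d."""
    if isinstance(tree, (RootedGeneTree, SpeciesTree)):
        total = 1
        for node in tree.root.postorder():
            total *= double_factorial(2 * len(node.children) - 3)
        return total
    if isinstance(tree, UnrootedGeneTree):
        total = 1
        for v in tree.internal_vertices():
            total *= double_factorial(2 * tree.degree(v) - 5)
        return total
    raise TypeError("count_binary_refinements expects a tree")


def _expand_polytomy(node: RNode, shape) -> None:
    slots = list(node.children)
    for slot in slots:
        slot.parent = None
    node.children = []
    left, right = shape            # a polytomy has >= 3 children, so the
    node.add_child(build_shape(left, slots))   # shape root is always a pair
    node.add_child(build_shape(right, slots))


def iter_rooted_refinements(tree: RootedGeneTree,
                            cap: int = DEFAULT_ENUMERATION_CAP
                            ) -> Iterator[RootedGeneTree]:
    """Every binary refinement of a rooted tree (as resolution combinations
    over distinguishable child subtrees; not deduplicated)."""
    total = count_binary_refinements(tree)
    if total > cap:
        raise CapExceededError(
            f"{total} refinements exceed the cap of {cap}")
    polytomies = [n for n in tree.root.postorder() if len(n.children) > 2]
    if not polytomies:
        yield tree.copy()
        return
    shape_lists = [list(iter_rooted_shapes(len(p.children))) for p in polytomies]
    for combo in itertools.product(*shape_lists):
        refined, nmap = tree.copy_with_map()
        for polytomy, shape in zip(polytomies, combo):
            _expand_polytomy(nmap[polytomy], shape)
        yield refined


def _first_leaf_edge(tree: UnrootedGeneTree) -> Tuple[int, int]:
    leaf = min(tree.leaves(), key=lambda v: (tree.labels[v], v))
    return (leaf, tree.adj[leaf][0])


def iter_unrooted_refinements(tree: UnrootedGeneTree,
                              cap: int = DEFAULT_ENUMERATION_CAP
                              ) -> Iterator[UnrootedGeneTree]:
    """Every binary refinement of an unrooted tree, with resolution edges
    recorded in ``new_edges`` (not deduplicated).

    Implemented by rooting at a fixed leaf edge: rooted refinements of that
    rooting correspond one-to-one to unrooted refinements of the tree.
    """
    if len(tree.leaves()) < 3:
        raise InvalidInputError("an unrooted tree needs at least 3 leaves")
    rooted = tree.root_at_edge(_first_leaf_edge(tree))
    for refined in iter_rooted_refinements(rooted, cap=cap):
        yield refined.unroot()


def enumerate_binary_refinements(tree, cap: int = DEFAULT_ENUMERATION_CAP):
    """All distinct binary refinements (deduplicated by labeled topology).

    With pairwise-distinct leaf labels the length equals
    ``count_binary_refinements``; repeated labels can make label-isomorphic
    resolutions collide, in which case each topology is emitted once.
    """
    if isinstance(tree, RootedGeneTree):
        it = iter_rooted_refinements(tree, cap=cap)
    elif isinstance(tree, UnrootedGeneTree):
        it = iter_unrooted_refinements(tree, cap=cap)
    else:
        raise TypeError("enumerate_binary_refinements expects a gene tree")
    seen = set()
    out = []
    for refined in it:
        key = refined.canonical()
        if key not in seen:
            seen.add(key)
            out.append(refined)
    return out


def same_topology(a, b) -> bool:
    """Label-preserving isomorphism test via canonical forms."""
    return a.canonical() == b.canonical()
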