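"""Seeded random generators for species trees and gene trees with
controlled polytomy structure.

These generators create structurally diverse test instances — random binary
shapes with optional label reuse (gene duplication leaves) and random edge
contractions (soft polytomies).  They emulate the combinatorial shape of
real gene-family data, not its inference process: there is no birth-death
or coalescent model behind them, no branch lengths, and contractions are
independent rather than support-driven.

Determinism: every call derives one named pseudo-random stream from the
integer seed in its config, so the same seed and config reproduce the same
Newick byte-for-byte, regardless of call order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .errors import InvalidInputError
from .trees import RNode, SpeciesTree, UnrootedGeneTree


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic instance family.

    n_species: leaf count of the species tree (labels s1..sn).
    n_gene_leaves: leaf count of the gene tree.
    duplication_label_rate: probability that a gene leaf reuses an already
        used species label (creating repeated labels, as gene duplications
        do); 0 with n_gene_leaves == n_species gives a bijective labeling.
    contraction_rate: probability that each internal edge of the binary
        gene tree is contracted (creating soft polytomies).
    seed: integer driving all randomness.
    """
    n_species: int = 8
    n_gene_leaves: int = 9
    duplication_label_rate: float = 0.2
    contraction_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise InvalidInputError("need at least 3 species")
        if self.n_gene_leaves < 3:
            raise InvalidInputError("need at least 3 gene leaves")
        for rate in (self.duplication_label_rate, self.contraction_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidInputError("rates must lie in [0, 1]")


def _stream(config: GeneratorConfig, name: str) -> random.Random:
    return random.Random(f"{config.seed}:{name}")


def random_species_tree(config: GeneratorConfig) -> SpeciesTree:
    """Random rooted binary species tree on s1..sn by sequential random
    pair-joining (uniform over labeled histories, not over topologies)."""
    rng = _stream(config, "species")
    forest: List[RNode] = [RNode(label=f"s{i + 1}")
                           for i in range(config.n_species)]
    while len(forest) > 1:
        i, j = sorted(rng.sample(range(len(forest)), 2))
        b = forest.pop(j)
        a = forest.pop(i)
        forest.append(RNode(children=[a, b]))
    return SpeciesTree(forest[0])


def _random_labels(species: SpeciesTree, config: GeneratorConfig,
                   rng: random.Random) -> List[str]:
    pool = sorted(species.labels())
    unused = list(pool)
    used: List[str] = []
    labels: List[str] = []
    for _ in range(config.n_gene_leaves):
        reuse = used and (not unused
                          or rng.random() < config.duplication_label_rate)
        if reuse:
            label = rng.choice(used)
        else:
            label = unused.pop(rng.randrange(len(unused)))
            used.append(label)
        labels.append(label)
    return labels


def random_gene_tree(species: SpeciesTree, config: GeneratorConfig
                     ) -> UnrootedGeneTree:
    """Random unrooted gene tree over labels drawn from the species set.

    A random binary unrooted shape is grown by attaching each leaf to a
    uniformly random edge, then each internal edge is contracted
    independently with ``contraction_rate``.
    """
    rng = _stream(config, "gene")
    labels = _random_labels(species, config, rng)

    # binary unrooted shape: vertices 0..; leaves carry labels
    adj: Dict[int, List[int]] = {0: [1, 2, 3], 1: [0], 2: [0], 3: [0]}
    leaf_label = {1: labels[0], 2: labels[1], 3: labels[2]}
    edges: List[Tuple[int, int]] = [(0, 1), (0, 2), (0, 3)]
    next_id = 4
    for label in labels[3:]:
        u, v = edges[rng.randrange(len(edges))]
        mid, leaf = next_id, next_id + 1
        next_id += 2
        adj[u] = [x if x != v else mid for x in adj[u]]
        adj[v] = [x if x != u else mid for x in adj[v]]
        adj[mid] = [u, v, leaf]
        adj[leaf] = [mid]
        leaf_label[leaf] = label
        edges.remove((u, v))
        edges += [(u, mid), (v, mid), (mid, leaf)]

    # contract internal edges independently (union-find merge)
    parent: Dict[int, int] = {v: v for v in adj}

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for (u, v) in sorted(edges):
        if len(adj[u]) > 1 and len(adj[v]) > 1 \
                and rng.random() < config.contraction_rate:
            parent[find(u)] = find(v)
    merged_adj: Dict[int, List[int]] = {}
    merged_labels: Dict[int, str] = {}
    for (u, v) in sorted(edges):
        ru, rv = find(u), find(v)
        if ru == rv:
            continue
        merged_adj.setdefault(ru, []).append(rv)
        merged_adj.setdefault(rv, []).append(ru)
    for leaf, label in leaf_label.items():
        merged_labels[find(leaf)] = label
    return UnrootedGeneTree(merged_adj, merged_labels)


def random_instance(config: GeneratorConfig
                    ) -> Tuple[UnrootedGeneTree, SpeciesTree]:
    species = random_species_tree(config)
    return random_gene_tree(species, config), species


def random_bounded_instance(seed: int,
                            max_species: int = 8,
                            max_gene_leaves: int = 9,
                            max_polytomies: int = 3,
                            max_polytomy_degree: int = 5,
                            bijective: bool = False
                            ) -> Tuple[UnrootedGeneTree, SpeciesTree,
                                       GeneratorConfig]:
    """Oracle-scale instance family: sizes and polytomy structure are drawn
    at random but kept small enough for exhaustive cross-checks, by
    rejection sampling on the polytomy caps.

    With ``bijective`` the gene leaves are a bijection onto the species set
    (the valid input family of the classical Robinson-Foulds distance).
    """
    rng = random.Random(f"{seed}:bounded")
    for attempt in range(1000):
        n_species = rng.randint(4, max_species)
        if bijective:
            n_leaves, dup_rate = n_species, 0.0
        else:
            n_leaves = rng.randint(4, max_gene_leaves)
            dup_rate = rng.choice([0.0, 0.2, 0.5])
        config = GeneratorConfig(
            n_species=n_species, n_gene_leaves=n_leaves,
            duplication_label_rate=dup_rate,
            contraction_rate=rng.choice([0.0, 0.2, 0.4, 0.6]),
            seed=rng.randrange(2 ** 30) * 1000 + attempt)
        gene, species = random_instance(config)
        polytomies = [v for v in gene.internal_vertices()
                      if gene.degree(v) > 3]
        if len(polytomies) <= max_polytomies and all(
                gene.degree(v) <= max_polytomy_degree for v in polytomies):
            return gene, species, config
    raise InvalidInputError("rejection sampling failed to find an instance")
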