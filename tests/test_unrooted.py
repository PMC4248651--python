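"""Edge labeling, star classification, rooting-cost profiles, and the
optimal-root locator."""

import pytest
from hypothesis import given, settings, strategies as st

import urefine as ur

from conftest import bounded_instances


def _edge_by_labels(gene, *labels):
    """The unique edge whose smaller side is exactly the given labels."""
    for e in gene.edges():
        u, v = e
        if tuple(sorted(labels)) in (gene.side_labels(u, v),
                                     gene.side_labels(v, u)):
            return e
    raise AssertionError("edge not found")


class TestLabeling:
    def test_leaf_rule(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        lab = ur.label_edges(g, s3)
        for leaf in g.leaves():
            (w,) = g.adj[leaf]
            assert lab.label(leaf, w) is s3.leaf(g.labels[leaf])

    def test_quartet_internal_edge(self, s4):
        g = ur.parse_newick("((a,b),(c,d));", "unrooted")
        lab = ur.label_edges(g, s4)
        (e,) = [e for e in g.edges()
                if g.degree(e[0]) > 1 and g.degree(e[1]) > 1]
        u, v = e
        sides = {s4.cluster[lab.label(u, v)], s4.cluster[lab.label(v, u)]}
        assert sides == {frozenset("ab"), frozenset("cd")}

    def test_star_remainder_labels(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        lab = ur.label_edges(g, s3)
        (center,) = g.internal_vertices()
        by_leaf = {g.labels[w]: lab.label(center, w) for w in g.adj[center]}
        assert by_leaf["a"] is s3.root and by_leaf["b"] is s3.root
        assert s3.cluster[by_leaf["c"]] == frozenset("ab")

    def test_too_few_leaves(self, s3):
        with pytest.raises(ur.InvalidInputError):
            ur.label_edges(ur.parse_newick("(a,b);", "unrooted"), s3)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_top_is_constant_across_edges(self, seed):
        gene, species, _ = ur.random_bounded_instance(seed)
        lab = ur.label_edges(gene, species)
        for (u, v) in gene.edges():
            assert species.lca(lab.label(u, v), lab.label(v, u)) is lab.top

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_labels_equal_component_lca(self, seed):
        """Each directed label is the lca of the species images of the
        leaves on its tail side (independent recomputation)."""
        gene, species, _ = ur.random_bounded_instance(seed)
        lab = ur.label_edges(gene, species)
        for (u, v) in gene.edges():
            expected = species.lca_many(
                species.leaf(l) for l in gene.side_labels(u, v))
            assert lab.label(u, v) is expected


class TestStars:
    def test_m2_with_empty_edge(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        (report,) = ur.star_table(g, s3)
        assert (report.star_type, report.alpha, report.beta) == ("M2", 0, 2)
        kinds = dict(zip(report.neighbors, report.edge_kinds))
        (c_leaf,) = [v for v in g.leaves() if g.labels[v] == "c"]
        assert kinds[c_leaf] == "empty"

    def test_m6_all_single(self, s4):
        g = ur.parse_newick("(a,b,c,d);", "unrooted")
        (report,) = ur.star_table(g, s4)
        assert (report.star_type, report.alpha, report.beta) == ("M6", 0, 4)
        assert report.edge_kinds == ["single"] * 4

    def test_m3_with_double_edge(self, s4):
        g = ur.parse_newick("((a,c),(b,d));", "unrooted")
        reports = ur.star_table(g, s4)
        assert {r.star_type for r in reports} == {"M3"}
        for r in reports:
            assert (r.alpha, r.beta) == (1, 3)
            assert r.edge_kinds.count("double") == 1

    def test_leaf_rejected(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        lab = ur.label_edges(g, s3)
        with pytest.raises(ur.InvalidInputError):
            ur.classify_star(lab, g.leaves()[0])


class TestProfiles:
    def test_star_profile(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        profile = ur.rooting_cost_profile(g, s3, "dup")
        by_leaf = {}
        for (u, v), cost in profile.items():
            leaf = u if u in g.labels else v
            by_leaf[g.labels[leaf]] = cost
        assert by_leaf == {"a": 1, "b": 1, "c": 0}

    def test_m6_plateau_profile(self, s4):
        g = ur.parse_newick("(a,b,c,d);", "unrooted")
        assert set(ur.rooting_cost_profile(g, s4, "dup").values()) == {1}

    def test_identity_has_zero_edge(self, s4):
        g = ur.parse_newick("((a,b),(c,d));", "unrooted")
        cost, optimal = ur.unrooted_cost(g, s4, "dup")
        assert cost == 0
        splits = [g.edge_split(e) for e in optimal]
        assert (("a", "b"), ("c", "d")) in splits

    def test_unrooted_cost_star(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        cost, optimal = ur.unrooted_cost(g, s3, "dup")
        assert cost == 0 and len(optimal) == 1
        assert g.edge_split(optimal[0]) == (("a", "b"), ("c",))

    def test_m6_all_edges_optimal(self, s4):
        g = ur.parse_newick("(a,b,c,d);", "unrooted")
        cost, optimal = ur.unrooted_cost(g, s4, "dup")
        assert cost == 1 and len(optimal) == 4


class TestOptimalRootLocator:
    def test_empty_edge_found(self, s3):
        g = ur.parse_newick("(a,b,c);", "unrooted")
        choice = ur.find_optimal_root(g, s3)
        assert choice.kind == "edge"
        assert g.edge_split(choice.edge) == (("a", "b"), ("c",))

    def test_m6_node_rooting(self, s4):
        g = ur.parse_newick("(a,b,c,d);", "unrooted")
        choice = ur.find_optimal_root(g, s4)
        assert choice.kind == "node"
        assert choice.node in g.internal_vertices()

    def test_identity_quartet(self, s4):
        g = ur.parse_newick("((a,b),(c,d));", "unrooted")
        choice = ur.find_optimal_root(g, s4)
        assert choice.kind == "edge"
        profile = ur.rooting_cost_profile(g, s4, "dup")
        assert profile[choice.edge] == 0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_walk_start_independence(self, seed):
        """The locator reaches an optimal rooting from every internal
        start vertex."""
        gene, species, _ = ur.random_bounded_instance(seed)
        profile = ur.rooting_cost_profile(gene, species, "dup")
        best = min(profile.values())
        for start in gene.internal_vertices():
            choice = ur.find_optimal_root(gene, species, start=start)
            if choice.kind == "edge":
                assert profile[choice.edge] == best
            else:
                lab = ur.label_edges(gene, species)
                assert ur.classify_star(lab, choice.node).star_type == "M6"


class TestPropositions:
    def test_trichotomy_and_exhaustive_types(self):
        for seed, gene, species in bounded_instances(120):
            lab = ur.label_edges(gene, species)
            kinds = {e: lab.edge_kind(*e) for e in gene.edges()}
            reports = [ur.classify_star(lab, v)
                       for v in gene.internal_vertices()]
            assert all(r.star_type in ur.unrooted.STAR_TYPES
                       for r in reports)
            has_empty = "empty" in kinds.values()
            has_double = "double" in kinds.values()
            m6 = [r for r in reports if r.star_type == "M6"]
            if not has_empty and not has_double:
                assert len(m6) == 1
                assert set(kinds.values()) == {"single"}

    def test_binary_instances_have_empty_or_double_edge(self):
        for seed in range(100):
            gene, species, cfg = ur.random_bounded_instance(seed * 13 + 5)
            if not gene.is_binary():
                cfg = ur.GeneratorConfig(
                    n_species=cfg.n_species, n_gene_leaves=cfg.n_gene_leaves,
                    duplication_label_rate=cfg.duplication_label_rate,
                    contraction_rate=0.0, seed=cfg.seed)
                gene, species = ur.random_instance(cfg)
            lab = ur.label_edges(gene, species)
            assert any(lab.edge_kind(*e) in ("empty", "double")
                       for e in gene.edges())

    def test_membership_and_plateau_and_dominance(self):
        """Empty/double/M6 edges attain the minimum; M4-M6 stars are cost
        plateaus; the distinguished edge of an M1/M2/M3 star dominates its
        star (brute-force arbitration of the dominance claims)."""
        for seed, gene, species in bounded_instances(100):
            lab = ur.label_edges(gene, species)
            profile = ur.rooting_cost_profile(gene, species, "dup")
            best = min(profile.values())
            for e in gene.edges():
                if lab.edge_kind(*e) in ("empty", "double"):
                    assert profile[e] == best
            for v in gene.internal_vertices():
                r = ur.classify_star(lab, v)
                star_costs = [profile[(min(v, w), max(v, w))]
                              for w in r.neighbors]
                if r.star_type in ("M4", "M5", "M6"):
                    assert len(set(star_costs)) == 1
                    if r.star_type == "M6":
                        assert star_costs[0] == best
                if r.star_type == "M2":
                    for i in range(len(r.neighbors)):
                        if (r.subtree_labels[i] is not lab.top
                                and r.remainder_labels[i] is not lab.top):
                            assert star_costs[i] == min(star_costs)
                if r.star_type in ("M1", "M3"):
                    for i in range(len(r.neighbors)):
                        if r.subtree_labels[i] is lab.top:
                            assert star_costs[i] == min(star_costs)


def test_tsv_and_dot_exports(s3):
    g = ur.parse_newick("(a,b,c);", "unrooted")
    tsv = ur.unrooted.edges_tsv(g, s3, costs=("dup", "dc"))
    assert tsv.startswith("u\tv\t")
    assert len(tsv.strip().splitlines()) == 1 + len(g.edges())
    stars = ur.unrooted.stars_tsv(g, s3)
    assert "M2" in stars
    dot = ur.unrooted.to_dot(g, s3)
    assert dot.startswith("graph") and "--" in dot
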