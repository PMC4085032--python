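import networkx as nx
import numpy as np
import pytest

from decisiphy.coverage_decisiveness import (
    CoverageMatrix,
    branchwise_decisive_counts,
    build_coverage,
    enumerate_partial_decisiveness,
    estimate_partial_decisiveness,
    four_way_partition,
    locus_is_decisive,
    missingness_summary,
    n_unrooted_trees,
)
from decisiphy.trees_io import Alignment, PartitionMap, ValidationError, parse_newick

from conftest import random_coverage, random_tree


def _aln(rows: dict) -> Alignment:
    return Alignment.from_rows(list(rows), list(rows.values()))


PARTS_2x2 = PartitionMap({"L1": [(1, 2)], "L2": [(3, 4)]})


class TestCoverage:
    def test_all_gap_alignment_is_all_false(self):
        aln = _aln({"t1": "----", "t2": "----"})
        cov = build_coverage(aln, PARTS_2x2)
        assert not cov.presence.any()
        assert cov.empty_taxa() == ["t1", "t2"]

    def test_full_locus_column_true(self):
        aln = _aln({"t1": "AC--", "t2": "GT--"})
        cov = build_coverage(aln, PARTS_2x2)
        assert cov.presence[:, 0].all() and not cov.presence[:, 1].any()

    def test_single_data_char_marks_only_its_locus(self):
        aln = _aln({"t1": "---A", "t2": "----"})
        cov = build_coverage(aln, PARTS_2x2)
        assert cov.locus_taxa("L2") == {"t1"}
        assert cov.locus_taxa("L1") == frozenset()

    def test_partial_ambiguity_counts_as_data_full_does_not(self):
        aln = _aln({"t1": "R-N?", "t2": "----"})
        cov = build_coverage(aln, PartitionMap({"L1": [(1, 1)], "L2": [(2, 4)]}))
        assert cov.presence[0, 0] and not cov.presence[0, 1]


class TestMissingnessSummary:
    def test_all_gap(self):
        aln = _aln({"t1": "----", "t2": "----"})
        out = missingness_summary(aln, PARTS_2x2)
        assert out["cellwise_missing_pct"] == 100.0
        assert out["n_site_patterns"] == 1

    def test_duplicate_columns_collapse_to_patterns(self):
        # columns: AAAA, AAAA, ACGT -> 2 distinct patterns
        aln = _aln({"t1": "AAA", "t2": "AAC", "t3": "AAG", "t4": "AAT"})
        out = missingness_summary(aln, PartitionMap({"L1": [(1, 3)]}))
        assert out["n_site_patterns"] == 2
        assert out["n_sites"] == 3
        assert out["cellwise_missing_pct"] == 0.0


class TestFourWayPartition:
    def test_five_taxon_central_edge_by_hand(self):
        tree = parse_newick("((a,b),((c,d),e));")
        blocks = {
            tree.edge_key(e): set(map(frozenset, four_way_partition(tree, e).blocks))
            for e in tree.internal_edges()
        }
        assert blocks["a|b"] == {
            frozenset("a"),
            frozenset("b"),
            frozenset({"c", "d"}),
            frozenset("e"),
        }

    def test_four_taxon_tree_singleton_blocks(self, quartet_tree):
        (edge,) = quartet_tree.internal_edges()
        fwp = four_way_partition(quartet_tree, edge)
        assert set(fwp.blocks) == {frozenset(x) for x in "abcd"}

    def test_pendant_edge_rejected(self, quartet_tree):
        tip = quartet_tree.tips()[0]
        with pytest.raises(ValidationError, match="terminal"):
            four_way_partition(quartet_tree, tip)

    @pytest.mark.parametrize("seed", range(10))
    def test_blocks_partition_tip_set(self, seed):
        tree = random_tree(int(np.random.default_rng(seed).integers(5, 40)), seed)
        tips = set(tree.tip_labels)
        for edge in tree.internal_edges():
            fwp = four_way_partition(tree, edge)
            assert all(fwp.blocks)
            union = set()
            total = 0
            for block in fwp.blocks:
                union |= block
                total += len(block)
            assert union == tips and total == len(tips)


def _nx_unrooted_graph(tree):
    """Independent route to the four-way blocks: build the unrooted graph and
    delete an edge's two endpoints; the remainder must fall into 4 components."""
    g = nx.Graph()
    for node in tree.root.preorder():
        for child in node.children:
            g.add_edge(id(node), id(child))
    if tree.has_bifurcating_root:
        c1, c2 = tree.root.children
        g.remove_node(id(tree.root))
        g.add_edge(id(c1), id(c2))
    labels = {id(t): t.label for t in tree.tips()}
    return g, labels


def _nx_blocks(tree, edge):
    g, labels = _nx_unrooted_graph(tree)
    parent = edge.parent
    if parent is tree.root and tree.has_bifurcating_root:
        parent = next(c for c in tree.root.children if c is not edge)
    h = g.copy()
    h.remove_node(id(edge))
    h.remove_node(id(parent))
    comps = list(nx.connected_components(h))
    assert len(comps) == 4
    return [frozenset(labels[n] for n in comp if n in labels) for comp in comps]


class TestBranchwiseCounts:
    def test_complete_coverage_counts_all_loci(self):
        tree = random_tree(12, seed=1)
        cov = CoverageMatrix(
            tree.tip_labels, ["L1", "L2", "L3"], np.ones((12, 3), dtype=bool)
        )
        counts = branchwise_decisive_counts(tree, cov)
        assert len(counts) == 12 - 3
        assert set(counts.values()) == {3}

    def test_empty_coverage_counts_zero(self):
        tree = random_tree(8, seed=2)
        cov = CoverageMatrix(tree.tip_labels, ["L1"], np.zeros((8, 1), dtype=bool))
        assert set(branchwise_decisive_counts(tree, cov).values()) == {0}

    def test_missing_tip_reported(self):
        tree = random_tree(6, seed=3)
        cov = CoverageMatrix(tree.tip_labels[:-1], ["L1"], np.ones((5, 1), dtype=bool))
        with pytest.raises(ValidationError, match=tree.tip_labels[-1]):
            branchwise_decisive_counts(tree, cov)

    @pytest.mark.parametrize("seed", range(50))
    def test_counts_match_graph_deletion_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tree = random_tree(n, seed)
        cov = random_coverage(n, int(rng.integers(1, 7)), seed + 1000,
                              density=float(rng.uniform(0.2, 0.9)),
                              taxa=tree.tip_labels)
        counts = branchwise_decisive_counts(tree, cov)
        locus_sets = cov.locus_taxon_sets()
        for edge in tree.internal_edges():
            blocks = _nx_blocks(tree, edge)
            brute = sum(
                1 for taxa in locus_sets if all(taxa & b for b in blocks)
            )
            assert counts[tree.edge_key(edge)] == brute

    def test_monotone_under_added_presence(self):
        tree = random_tree(10, seed=4)
        rng = np.random.default_rng(4)
        presence = rng.random((10, 4)) < 0.3
        cov = CoverageMatrix(tree.tip_labels, list("WXYZ"), presence)
        counts = branchwise_decisive_counts(tree, cov)
        for _ in range(25):
            i, j = int(rng.integers(10)), int(rng.integers(4))
            presence[i, j] = True
            cov2 = CoverageMatrix(tree.tip_labels, list("WXYZ"), presence)
            counts2 = branchwise_decisive_counts(tree, cov2)
            assert all(counts2[k] >= counts[k] for k in counts)
            counts = counts2

    def test_decisive_iff_all_blocks_intersected(self):
        tree = parse_newick("((a,b),((c,d),e));")
        (edge,) = [e for e in tree.internal_edges() if tree.edge_key(e) == "a|b"]
        fwp = four_way_partition(tree, edge)
        assert locus_is_decisive(fwp, frozenset("abcde"))
        assert locus_is_decisive(fwp, frozenset("abce"))
        assert not locus_is_decisive(fwp, frozenset("abc"))  # only 3 blocks hit


# --- partial decisiveness ---------------------------------------------------


def _tuple_tree_enumeration(taxa):
    """Independent enumeration of unrooted binary trees as nested tuples
    (root is the 3-tuple around the internal node adjacent to the first
    three taxa's star)."""

    def insertions(node, x):
        out = []
        for i, child in enumerate(node):
            out.append(node[:i] + ((child, x),) + node[i + 1:])
            if not isinstance(child, str):
                for v in insertions(child, x):
                    out.append(node[:i] + (v,) + node[i + 1:])
        return out

    trees = [tuple(taxa[:3])]
    for x in taxa[3:]:
        trees = [v for t in trees for v in insertions(t, x)]
    return trees


def _tuple_to_newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(_tuple_to_newick(c) for c in node) + ")"


def _oracle_partial_decisiveness(cov):
    """Exhaustive d via the tuple enumeration + the tree-object four-way
    machinery — a fully independent path from the bitmask enumerator."""
    locus_sets = cov.locus_taxon_sets()
    total = dec = 0
    for tup in _tuple_tree_enumeration(cov.taxa):
        tree = parse_newick(_tuple_to_newick(tup) + ";")
        for edge in tree.internal_edges():
            fwp = four_way_partition(tree, edge)
            total += 1
            dec += any(locus_is_decisive(fwp, s) for s in locus_sets)
    return dec / total


def _spec_instance():
    taxa = list("abcdef")
    presence = np.zeros((6, 2), dtype=bool)
    for j, members in enumerate(["abcd", "cdef"]):
        for t in members:
            presence[taxa.index(t), j] = True
    return CoverageMatrix(taxa, ["L1", "L2"], presence)


class TestPartialDecisiveness:
    def test_tree_counts(self):
        assert [n_unrooted_trees(n) for n in (4, 5, 6, 7)] == [3, 15, 105, 945]
        assert len(_tuple_tree_enumeration(list("abcdef"))) == 105

    def test_any_complete_locus_gives_one(self):
        cov = CoverageMatrix(list("abcdef"), ["L"], np.ones((6, 1), dtype=bool))
        assert enumerate_partial_decisiveness(cov) == 1.0

    def test_all_small_loci_give_zero(self):
        presence = np.zeros((6, 2), dtype=bool)
        presence[:3, 0] = True
        presence[3:, 1] = True
        cov = CoverageMatrix(list("abcdef"), ["L1", "L2"], presence)
        assert enumerate_partial_decisiveness(cov) == 0.0

    def test_six_taxon_instance_matches_independent_enumeration(self):
        cov = _spec_instance()
        exact = enumerate_partial_decisiveness(cov)
        assert exact == pytest.approx(_oracle_partial_decisiveness(cov), abs=1e-12)

    def test_random_instances_match_independent_enumeration(self):
        for seed in range(3):
            cov = random_coverage(6, 3, seed, density=0.6, taxa=list("abcdef"))
            assert enumerate_partial_decisiveness(cov) == pytest.approx(
                _oracle_partial_decisiveness(cov), abs=1e-12
            )

    def test_too_many_taxa_advises_estimator(self):
        cov = random_coverage(10, 2, 0)
        with pytest.raises(ValidationError, match="estimate_partial_decisiveness"):
            enumerate_partial_decisiveness(cov)

    def test_estimator_matches_enumeration_within_3_se(self):
        cov = _spec_instance()
        exact = enumerate_partial_decisiveness(cov)
        est = estimate_partial_decisiveness(cov, n_trees=2000, seed=11)
        assert abs(est.d_hat - exact) <= 3 * est.se

    def test_estimator_complete_coverage_exact_one(self):
        cov = CoverageMatrix(list("abcdefg"), ["L"], np.ones((7, 1), dtype=bool))
        est = estimate_partial_decisiveness(cov, n_trees=100, seed=0)
        assert est.d_hat == 1.0 and est.se == 0.0

    def test_estimator_reproducible_and_needs_four_taxa(self):
        cov = random_coverage(8, 3, 5, density=0.5)
        a = estimate_partial_decisiveness(cov, n_trees=200, seed=42)
        b = estimate_partial_decisiveness(cov, n_trees=200, seed=42)
        assert a.d_hat == b.d_hat and a.se == b.se
        with pytest.raises(ValidationError):
            estimate_partial_decisiveness(random_coverage(3, 1, 0), 10, 0)

    def test_nested_coverage_monotone_under_same_trees(self):
        rng = np.random.default_rng(9)
        small = rng.random((8, 4)) < 0.3
        large = small | (rng.random((8, 4)) < 0.3)
        taxa = [f"t{i}" for i in range(8)]
        loci = [f"L{j}" for j in range(4)]
        d_small = estimate_partial_decisiveness(
            CoverageMatrix(taxa, loci, small), n_trees=300, seed=7
        )
        d_large = estimate_partial_decisiveness(
            CoverageMatrix(taxa, loci, large), n_trees=300, seed=7
        )
        assert d_small.d_hat <= d_large.d_hat
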