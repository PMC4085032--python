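import math

import numpy as np
import pytest

from decisiphy.coverage_decisiveness import four_way_partition
from decisiphy.quartet_support import (
    _CHAR_TABLE,
    TOPOLOGY_PAIRS,
    QuartetEngine,
    SubstitutionModel,
    infer_quartet_topology,
    quartet_jackknife_branch,
    quartet_jackknife_tree,
    quartet_log_likelihood,
    sample_representative_quartet,
)
from decisiphy.synthetic_data import LocusSpec, simulate_alignment
from decisiphy.trees_io import Alignment, ValidationError, parse_newick

from conftest import random_tree


def brute_force_lnl(topology, codes, model, bls):
    """Likelihood by explicit summation over the 16 internal-node state
    pairs — the oracle for the pruning implementation."""
    i, j, k, l = TOPOLOGY_PAIRS[topology]
    pmats = [model.transition_matrix(t) for t in bls]
    total = 0.0
    for col in codes.T:
        tips = [_CHAR_TABLE[c] for c in col]
        site = 0.0
        for a in range(4):
            for b in range(4):
                site += (
                    model.freqs[a]
                    * pmats[4][a, b]
                    * (pmats[i][a] @ tips[i])
                    * (pmats[j][a] @ tips[j])
                    * (pmats[k][b] @ tips[k])
                    * (pmats[l][b] @ tips[l])
                )
        total += math.log(site)
    return total


class TestSubstitutionModels:
    def test_jc69_matrix_rows_sum_to_one(self):
        p = SubstitutionModel().transition_matrix(0.37)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(p, p.T)

    def test_jc69_long_branch_limit(self):
        p = SubstitutionModel().transition_matrix(50.0)
        assert np.allclose(p, 0.25, atol=1e-8)

    def test_gtr_with_equal_rates_reduces_to_jc69(self):
        gtr = SubstitutionModel("GTR", rates=np.ones(6), freqs=np.full(4, 0.25))
        jc = SubstitutionModel()
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(gtr.transition_matrix(t), jc.transition_matrix(t), atol=1e-10)

    def test_gtr_rows_sum_and_stationarity(self):
        rng = np.random.default_rng(3)
        freqs = rng.dirichlet(np.ones(4) * 5)
        gtr = SubstitutionModel("GTR", rates=rng.uniform(0.5, 3, 6), freqs=freqs)
        p = gtr.transition_matrix(0.7)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(freqs @ p, freqs)

    def test_propagate_equals_matrix_product(self):
        rng = np.random.default_rng(1)
        partial = rng.random((9, 4))
        for model in (
            SubstitutionModel(),
            SubstitutionModel("GTR", rates=rng.uniform(0.5, 2, 6), freqs=np.full(4, 0.25)),
        ):
            t = 0.42
            assert np.allclose(
                model.propagate(partial, t), partial @ model.transition_matrix(t).T
            )


class TestQuartetSampling:
    def test_singleton_blocks_always_same_quartet(self, quartet_tree, rng):
        (edge,) = quartet_tree.internal_edges()
        fwp = four_way_partition(quartet_tree, edge)
        draws = {sample_representative_quartet(fwp, rng) for _ in range(20)}
        assert len(draws) == 1

    def test_uniform_within_block(self):
        tree = parse_newick("(((a1,a2),b),((c,d),e));")
        edge = next(
            e for e in tree.internal_edges() if tree.edge_key(e) == "a1|a2|b"
        )
        fwp = four_way_partition(tree, edge)
        rng = np.random.default_rng(0)
        first = [sample_representative_quartet(fwp, rng)[0] for _ in range(10_000)]
        freq = first.count("a1") / 10_000
        assert abs(freq - 0.5) < 0.02

    def test_same_seed_same_sequence(self, quartet_tree):
        tree = random_tree(12, seed=5)
        edge = tree.internal_edges()[0]
        fwp = four_way_partition(tree, edge)
        seq1 = [sample_representative_quartet(fwp, np.random.default_rng(9)) for _ in range(5)]
        rng = np.random.default_rng(9)
        seq2 = [sample_representative_quartet(fwp, rng) for _ in range(5)]
        assert seq1[0] == seq2[0]


class TestQuartetLikelihood:
    def test_single_shared_state_zero_length_limit(self):
        codes = np.frombuffer(b"AAAA", dtype=np.uint8).reshape(4, 1)
        lnl = quartet_log_likelihood(0, codes, SubstitutionModel(), [1e-8] * 5)
        assert lnl == pytest.approx(math.log(0.25), abs=1e-6)

    def test_cherry_swap_symmetry(self):
        rng = np.random.default_rng(2)
        codes = rng.choice(np.frombuffer(b"ACGT-", dtype=np.uint8), size=(4, 40))
        bls = rng.uniform(0.05, 1.0, 5)
        base = quartet_log_likelihood(0, codes, SubstitutionModel(), bls)
        swapped_codes = codes[[1, 0, 2, 3]]
        swapped_bls = bls[[1, 0, 2, 3, 4]]
        assert quartet_log_likelihood(
            0, swapped_codes, SubstitutionModel(), swapped_bls
        ) == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_state_sum(self, seed):
        rng = np.random.default_rng(seed)
        model = (
            SubstitutionModel()
            if seed % 2
            else SubstitutionModel(
                "GTR", rates=rng.uniform(0.5, 2.5, 6), freqs=rng.dirichlet([6, 6, 6, 6])
            )
        )
        chars = np.frombuffer(b"ACGT-NRY", dtype=np.uint8)
        codes = rng.choice(chars, size=(4, 30))
        bls = rng.uniform(0.01, 2.0, 5)
        topo = int(rng.integers(3))
        fast = quartet_log_likelihood(topo, codes, model, bls)
        slow = brute_force_lnl(topo, codes, model, bls)
        assert fast == pytest.approx(slow, rel=1e-8)

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(ValidationError):
            quartet_log_likelihood(
                0, np.zeros((4, 0), dtype=np.uint8), SubstitutionModel(), [0.1] * 5
            )


class TestInferQuartetTopology:
    def test_all_gap_rows_uninformative_random_topology(self):
        aln = Alignment.from_rows(list("abcd"), ["----"] * 4)
        seen = set()
        for s in range(30):
            rep = infer_quartet_topology("abcd", aln, rng=np.random.default_rng(s))
            assert not rep.informative
            seen.add(rep.topology)
        assert seen == {0, 1, 2}

    def test_constant_sites_tie_broken_randomly(self):
        aln = Alignment.from_rows(list("abcd"), ["AAAAAAAA"] * 4)
        reps = [
            infer_quartet_topology("abcd", aln, rng=np.random.default_rng(s))
            for s in range(30)
        ]
        assert all(r.tie and r.informative for r in reps)
        assert {r.topology for r in reps} == {0, 1, 2}

    def test_min_sites_gate(self):
        # one column with 3 taxa sampled: informative at min_sites=1, not at 2
        aln = Alignment.from_rows(list("abcd"), ["A", "A", "A", "-"])
        rep1 = infer_quartet_topology("abcd", aln, rng=np.random.default_rng(0))
        rep2 = infer_quartet_topology(
            "abcd", aln, rng=np.random.default_rng(0), min_sites=2
        )
        assert rep1.informative and not rep2.informative

    def test_strong_quartet_recovered(self):
        tree = parse_newick("((t1:0.05,t2:0.05):0.5,(t3:0.05,t4:0.05):0.5);")
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 2000)], seed=5)
        rep = infer_quartet_topology(
            ("t1", "t2", "t3", "t4"), aln, rng=np.random.default_rng(0)
        )
        assert rep.topology == 0 and not rep.tie
        # the same tips presented in a conflicting block order flip the index
        rep_alt = infer_quartet_topology(
            ("t1", "t3", "t2", "t4"), aln, rng=np.random.default_rng(0)
        )
        assert rep_alt.topology == 1

    def test_missing_tip_rejected(self):
        aln = Alignment.from_rows(list("abc"), ["AC", "AC", "AC"])
        with pytest.raises(ValidationError):
            infer_quartet_topology("abcd", aln, rng=np.random.default_rng(0))

    def test_cache_transparent(self):
        tree = parse_newick("((t1:0.1,t2:0.1):0.1,(t3:0.1,t4:0.1):0.1);")
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 200)], seed=1)
        engine = QuartetEngine(aln)
        cold = engine.infer(("t1", "t2", "t3", "t4"), np.random.default_rng(3))
        warm = engine.infer(("t1", "t2", "t3", "t4"), np.random.default_rng(3))
        fresh = QuartetEngine(aln).infer(("t1", "t2", "t3", "t4"), np.random.default_rng(3))
        assert cold == warm == fresh


class TestJackknife:
    def test_tally_conservation_and_determinism(self):
        tree = random_tree(10, seed=2, height=0.3)
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 300)], seed=2)
        edge = tree.internal_edges()[1]
        t1 = quartet_jackknife_branch(
            tree, edge, aln, n_reps=40, rng=np.random.default_rng(8)
        )
        t2 = quartet_jackknife_branch(
            tree, edge, aln, n_reps=40, rng=np.random.default_rng(8)
        )
        assert sum(t1.counts) == 40
        assert t1.counts == t2.counts
        assert len(t1.replicates) == 40

    def test_zero_reps_empty_tally(self):
        from decisiphy.ica_stats import ica_from_tally

        tree = random_tree(6, seed=1)
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 50)], seed=1)
        tally = quartet_jackknife_branch(
            tree, tree.internal_edges()[0], aln, n_reps=0, rng=np.random.default_rng(0)
        )
        assert sum(tally.counts) == 0
        with pytest.raises(ValueError):
            ica_from_tally(tally)

    def test_four_tip_tree_has_single_tallied_branch(self, quartet_tree):
        aln = Alignment.from_rows(list("abcd"), ["ACGTACGT"] * 4)
        tallies = quartet_jackknife_tree(quartet_tree, aln, n_reps=10, seed=0)
        assert len(tallies) == 1

    def test_every_branch_tallied_and_conserved(self):
        tree = random_tree(16, seed=6, height=0.3)
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 200)], seed=6)
        tallies = quartet_jackknife_tree(tree, aln, n_reps=25, seed=1)
        assert len(tallies) == 16 - 3
        assert all(sum(t.counts) == 25 for t in tallies.values())

    def test_parallel_equals_serial(self):
        tree = random_tree(12, seed=3, height=0.3)
        aln, _ = simulate_alignment(tree, [LocusSpec("x", 200)], seed=3)
        serial = quartet_jackknife_tree(tree, aln, n_reps=20, seed=5, workers=1)
        parallel = quartet_jackknife_tree(tree, aln, n_reps=20, seed=5, workers=2)
        assert {k: t.counts for k, t in serial.items()} == {
            k: t.counts for k, t in parallel.items()
        }

    def test_uninformative_replicates_counted(self):
        # half the taxa have no data: quartets touching them are uninformative
        rows = ["ACGTACGT", "ACGTACGT", "--------", "--------",
                "ACGTACGT", "ACGTACGT", "--------", "--------"]
        tree = random_tree(8, seed=9)
        aln = Alignment.from_rows(tree.tip_labels, rows)
        tallies = quartet_jackknife_tree(tree, aln, n_reps=30, seed=2)
        assert any(t.n_uninformative > 0 for t in tallies.values())
        for t in tallies.values():
            assert sum(t.uninformative_counts) == t.n_uninformative
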