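import numpy as np
import pytest

from chronoseq import (
    GTR,
    GY94,
    HKY,
    BranchRateModel,
    EpochModel,
    Partition,
    SiteRateModel,
    build_rate_matrix,
    parse_tree,
    sample_root_sequence,
    simulate,
    simulate_partition,
    write_fasta,
)


class TestSampleRootSequence:
    def test_degenerate_frequencies(self, rng):
        spec = HKY(kappa=1.0, frequencies=(1.0, 0.0, 0.0, 0.0))
        states = sample_root_sequence(spec, 5, rng)
        assert np.array_equal(states, np.zeros(5, dtype=int))  # "AAAAA"

    def test_equilibrium_sampling_frequencies(self, rng):
        states = sample_root_sequence(HKY(kappa=1.0), 100_000, rng)
        se = np.sqrt(0.25 * 0.75 / 100_000)
        for s in range(4):
            assert abs((states == s).mean() - 0.25) < 3 * se

    def test_explicit_root_returned_verbatim(self, rng):
        states = sample_root_sequence(HKY(), 4, rng, root_sequence=list("ACGT"))
        assert states.tolist() == [0, 1, 2, 3]

    def test_out_of_alphabet_state_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_root_sequence(HKY(), 2, rng, root_sequence=["A", "X"])

    def test_epoch_root_uses_oldest_stationary(self, rng):
        # oldest epoch has frequencies concentrated on A; youngest uniform
        em = EpochModel(
            [1.0],
            [HKY(kappa=1.0),
             HKY(kappa=1.0, frequencies=(0.97, 0.01, 0.01, 0.01))],
        )
        states = sample_root_sequence(em, 2000, rng)
        assert (states == 0).mean() > 0.9


class TestSimulatePartition:
    def test_zero_branch_lengths_copy_root(self, rng):
        tree = parse_tree("((A:0.0,B:0.0):0.0,C:0.0);")
        part = Partition(n_sites=100, tree=tree, subst=HKY(kappa=4.0))
        states = simulate_partition(part, rng)
        root = states[tree.root]
        for node in tree.preorder():
            assert np.array_equal(states[node], root)

    def test_saturation_reaches_stationary_identity(self, rng):
        tree = parse_tree("(A:25,B:25);")  # pairwise distance 50
        part = Partition(n_sites=20_000, tree=tree, subst=HKY(kappa=1.0))
        states = simulate_partition(part, rng)
        a, b = (states[t] for t in tree.tips)
        identity = (a == b).mean()
        se = np.sqrt(0.25 * 0.75 / 20_000)
        assert abs(identity - 0.25) < 3 * se

    def test_stationarity_along_long_branch(self, rng):
        tree = parse_tree("(A:50,B:50);")
        pi = (0.4, 0.3, 0.2, 0.1)
        part = Partition(
            n_sites=50_000, tree=tree, subst=GTR(rates=(1, 2, 3, 4, 5, 6), frequencies=pi)
        )
        states = simulate_partition(part, rng)
        tip = states[tree.tips[0]]
        for s, f in enumerate(pi):
            se = np.sqrt(f * (1 - f) / 50_000)
            assert abs((tip == s).mean() - f) < 3 * se

    def test_epoch_model_requires_time_calibration(self, rng):
        tree = parse_tree("(A:1,B:1);", time_calibrated=False)
        em = EpochModel([0.5], [HKY(), HKY(kappa=5.0)])
        part = Partition(n_sites=10, tree=tree, subst=em)
        with pytest.raises(ValueError, match="time-calibrated"):
            simulate_partition(part, rng)

    def test_site_categories_modulate_divergence(self, rng):
        # invariant sites never change; variable sites do on a long branch
        tree = parse_tree("(A:5,B:5);")
        part = Partition(
            n_sites=5000, tree=tree, subst=HKY(kappa=2.0),
            site_model=SiteRateModel(alpha=1.0, n_categories=4, p_inv=0.5),
        )
        states = simulate_partition(part, rng)
        root = states[tree.root]
        tip = states[tree.tips[0]]
        identical = (root == tip).mean()
        assert identical > 0.5  # at least the invariant half survived


class TestSimulate:
    def test_two_partition_width(self, three_taxon_tree):
        parts = [
            Partition(n_sites=40, tree=three_taxon_tree, subst=HKY(kappa=4.0)),
            Partition(n_sites=25, tree=three_taxon_tree, subst=GTR()),
        ]
        aln = simulate(parts, global_seed=5)
        assert aln.n_columns == 65
        assert aln.partition_ranges == [(0, 40), (40, 65)]

    def test_missing_taxon_gap_padded(self):
        t1 = parse_tree("((A:1,B:1):1,C:2);")
        t2 = parse_tree("(A:1,B:1);")
        parts = [
            Partition(n_sites=30, tree=t1, subst=HKY()),
            Partition(n_sites=20, tree=t2, subst=HKY()),
        ]
        aln = simulate(parts, global_seed=5)
        assert aln.rows["C"][30:] == "-" * 20
        assert "-" not in aln.rows["C"][:30]

    def test_determinism_byte_identical_fasta(self, tmp_path, three_taxon_tree):
        part = Partition(n_sites=200, tree=three_taxon_tree, subst=HKY(kappa=4.0))
        out = []
        for run in (1, 2):
            aln = simulate([part], global_seed=99)
            path = tmp_path / f"run{run}.fa"
            write_fasta(aln, path)
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_partition_independence_under_added_partitions(self, three_taxon_tree):
        p1 = Partition(n_sites=50, tree=three_taxon_tree, subst=HKY(kappa=4.0))
        p2 = Partition(n_sites=30, tree=three_taxon_tree, subst=GTR())
        alone = simulate([p1], global_seed=11)
        joined = simulate([p1, p2], global_seed=11)
        for name in alone.taxa:
            assert joined.rows[name][:50] == alone.rows[name]

    def test_codon_partition_emits_triplets(self, three_taxon_tree):
        part = Partition(n_sites=10, tree=three_taxon_tree, subst=GY94(omega=0.5, kappa=2.0))
        aln = simulate([part], global_seed=3)
        assert aln.n_columns == 30
        assert set("".join(aln.rows.values())) <= set("ACGT")

    def test_codon_partition_amino_acid_emission(self, three_taxon_tree):
        part = Partition(
            n_sites=10, tree=three_taxon_tree,
            subst=GY94(omega=0.5, kappa=2.0), emit_amino_acids=True,
        )
        aln = simulate([part], global_seed=3)
        assert aln.n_columns == 10
        assert aln.datatype == "protein"

    def test_ancestral_alignment(self, three_taxon_tree):
        part = Partition(n_sites=15, tree=three_taxon_tree, subst=HKY())
        tips, anc = simulate([part], global_seed=4, keep_ancestral=True)
        assert sorted(anc.taxa) == ["node0", "node1"]  # root + one internal
        assert anc.n_columns == 15

    def test_relaxed_clock_runs_deterministically(self, three_taxon_tree):
        part = Partition(
            n_sites=60, tree=three_taxon_tree, subst=HKY(kappa=2.0),
            clock=BranchRateModel(kind="lognormal", mean=1.0, stdev=0.8),
        )
        a = simulate([part], global_seed=21)
        b = simulate([part], global_seed=21)
        assert a.rows == b.rows

    def test_simulation_matches_single_branch_transition_matrix(self, rng):
        # two tips separated by known distance: mismatch frequencies per
        # ordered state pair must match P entries within binomial error
        tree = parse_tree("(A:0.2,B:0.2);")
        spec = HKY(kappa=4.0, frequencies=(0.4, 0.1, 0.3, 0.2))
        part = Partition(n_sites=100_000, tree=tree, subst=spec)
        states = simulate_partition(part, rng)
        Q = build_rate_matrix(spec)
        from chronoseq import transition_probabilities

        P = transition_probabilities(Q, 0.4)  # A->root->B total distance
        a, b = (states[t] for t in tree.tips)
        for i in range(4):
            sel = a == i
            n = sel.sum()
            for j in range(4):
                obs = (b[sel] == j).mean()
                se = np.sqrt(P[i, j] * (1 - P[i, j]) / n)
                assert abs(obs - P[i, j]) < 4 * se
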