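import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chronoseq import (
    GTR,
    GY94,
    HKY,
    MG94,
    TN93,
    EmpiricalAA,
    General,
    build_rate_matrix,
    codon_space,
    f1x4_frequencies,
    general_space,
    nucleotide_space,
    stationary_distribution,
    transition_probabilities,
)
from chronoseq.substitution import EMPIRICAL_AA_MODELS, load_empirical_aa


def series_expm(M, terms=60):
    """Truncated Taylor-series oracle for the matrix exponential."""
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, terms + 1):
        term = term @ M / k
        out = out + term
    return out


class TestStateSpaces:
    def test_codon_space_universal_code(self):
        space = codon_space()
        assert space.size == 61
        assert "TAA" not in space.states and "TGA" not in space.states
        assert space.states[0] == "AAA"
        assert space.amino_acids[space.index("ATG")] == "M"

    def test_vertebrate_mito_code_has_60_codons(self):
        assert codon_space(2).size == 60  # AGA/AGG are stops, TGA codes W


class TestBuildRateMatrix:
    def test_hky_kappa1_is_jukes_cantor(self):
        Q = build_rate_matrix(HKY(kappa=1.0))
        off = Q.matrix[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0 / 3.0)

    def test_hky_transition_transversion_ratio(self):
        Q = build_rate_matrix(HKY(kappa=4.0))
        # A->G is a transition, A->C a transversion
        assert Q.matrix[0, 2] / Q.matrix[0, 1] == pytest.approx(4.0)

    def test_normalization_mean_rate_one(self):
        for spec in (
            HKY(kappa=3.0, frequencies=(0.1, 0.2, 0.3, 0.4)),
            TN93(kappa1=2.0, kappa2=5.0),
            GTR(rates=(1, 2, 3, 4, 5, 6), frequencies=(0.4, 0.3, 0.2, 0.1)),
            GY94(omega=0.3, kappa=2.0),
            MG94(alpha=1.0, beta=0.2),
            EmpiricalAA("WAG"),
        ):
            Q = build_rate_matrix(spec)
            assert -(Q.frequencies * np.diag(Q.matrix)).sum() == pytest.approx(
                1.0, abs=1e-10
            )
            assert np.allclose(Q.matrix.sum(axis=1), 0.0, atol=1e-10)

    def test_tn93_equal_kappas_equals_hky(self):
        a = build_rate_matrix(TN93(kappa1=3.5, kappa2=3.5))
        b = build_rate_matrix(HKY(kappa=3.5))
        assert np.allclose(a.matrix, b.matrix, atol=1e-12)

    def test_gtr_unit_rates_is_frequency_model(self):
        pi = (0.1, 0.2, 0.3, 0.4)
        Q = build_rate_matrix(GTR(rates=(1.0,) * 6, frequencies=pi))
        # F81-like: q_ij proportional to pi_j for all i != j
        for i, j in itertools.permutations(range(4), 2):
            ratio = Q.matrix[i, j] / pi[j]
            assert ratio == pytest.approx(Q.matrix[1, 0] / pi[0])

    def test_detailed_balance_for_reversible_models(self):
        for spec in (
            HKY(kappa=4.0, frequencies=(0.4, 0.1, 0.2, 0.3)),
            TN93(kappa1=2.0, kappa2=7.0, frequencies=(0.3, 0.3, 0.2, 0.2)),
            GTR(rates=(1, 2, 3, 4, 5, 6), frequencies=(0.25, 0.3, 0.15, 0.3)),
            GY94(omega=0.1, kappa=3.0),
            MG94(alpha=2.0, beta=0.5, kappa=2.0, nucleotide_frequencies=(0.4, 0.2, 0.2, 0.2)),
            EmpiricalAA("LG"),
        ):
            Q = build_rate_matrix(spec)
            flux = Q.frequencies[:, None] * Q.matrix
            assert np.allclose(flux, flux.T, atol=1e-10), type(spec).__name__

    def test_frequency_size_mismatch(self):
        with pytest.raises(ValueError):
            build_rate_matrix(HKY(kappa=1.0, frequencies=(0.5, 0.5)))


class TestGY94:
    def test_multi_position_changes_forbidden(self):
        space = codon_space()
        Q = build_rate_matrix(GY94(omega=0.7, kappa=3.0), space)
        assert Q.matrix[space.index("AAA"), space.index("ACC")] == 0.0

    def test_parameter_collapse_symmetry(self):
        space = codon_space()
        Q = build_rate_matrix(GY94(omega=1.0, kappa=1.0), space)
        # with omega=kappa=1 and uniform frequencies every allowed
        # single-position move shares one rate
        i = space.index("AAA")
        assert Q.matrix[i, space.index("ACA")] == pytest.approx(
            Q.matrix[i, space.index("AGA")]
        )
        off = Q.matrix[i][Q.matrix[i] > 0]
        assert np.allclose(off, off[0])

    def test_synonymous_vs_nonsynonymous_scaling(self):
        space = codon_space()
        Q = build_rate_matrix(GY94(omega=0.25, kappa=1.0), space)
        # TTA->CTA synonymous (both Leu); TTA->ATA nonsynonymous (Leu->Ile);
        # both are transversions at position 0
        syn = Q.matrix[space.index("TTA"), space.index("CTA")]
        nonsyn = Q.matrix[space.index("TTA"), space.index("ATA")]
        assert nonsyn / syn == pytest.approx(0.25)


class TestMG94:
    def test_target_nucleotide_frequency(self):
        space = codon_space()
        pi_nt = (0.4, 0.3, 0.2, 0.1)
        Q = build_rate_matrix(MG94(alpha=1.0, beta=1.0, nucleotide_frequencies=pi_nt), space)
        # AAA->AAC and AAA->AAG differ only in the incoming nucleotide (C vs G)
        r_c = Q.matrix[space.index("AAA"), space.index("AAC")]
        r_g = Q.matrix[space.index("AAA"), space.index("AAG")]
        assert r_c / r_g == pytest.approx(0.3 / 0.2)

    def test_stationary_is_f1x4(self):
        pi_nt = (0.4, 0.3, 0.2, 0.1)
        space = codon_space()
        Q = build_rate_matrix(MG94(alpha=1.5, beta=0.3, nucleotide_frequencies=pi_nt), space)
        assert np.allclose(
            stationary_distribution(Q), f1x4_frequencies(pi_nt, space), atol=1e-8
        )


class TestEmpiricalAA:
    @pytest.mark.parametrize("name", EMPIRICAL_AA_MODELS)
    def test_loadable_symmetric_normalized(self, name):
        S, freqs = load_empirical_aa(name)
        assert S.shape == (20, 20)
        assert np.allclose(S, S.T)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
        Q = build_rate_matrix(EmpiricalAA(name))
        assert -(Q.frequencies * np.diag(Q.matrix)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_lg_published_values(self):
        # spot-check against the published LG exchangeability matrix
        S, _ = load_empirical_aa("LG")
        order = "ARNDCQEGHILKMFPSTWYV"
        assert S[order.index("R"), order.index("A")] == pytest.approx(0.425093)
        assert S[order.index("N"), order.index("R")] == pytest.approx(0.751878)

    def test_frequency_override(self):
        pi = np.full(20, 0.05)
        Q = build_rate_matrix(EmpiricalAA("JTT", frequencies=pi))
        assert np.allclose(Q.frequencies, pi)


class TestGeneral:
    def test_rates_taken_verbatim_up_to_normalization(self):
        rates = np.array([[0, 2, 0], [0, 0, 1], [3, 0, 0]], dtype=float)
        space = general_space(["X", "Y", "Z"])
        Q = build_rate_matrix(General(rates=rates, labels=["X", "Y", "Z"]), space)
        assert Q.matrix[0, 2] == 0.0
        assert Q.matrix[0, 1] / Q.matrix[1, 2] == pytest.approx(2.0)
        assert not Q.reversible

    def test_all_zero_row_rejected(self):
        rates = [[0, 1, 0], [0, 0, 0], [1, 0, 0]]
        with pytest.raises(ValueError, match="all-zero"):
            build_rate_matrix(General(rates=rates, labels=list("XYZ")))


class TestTransitionProbabilities:
    def test_zero_distance_identity(self):
        Q = build_rate_matrix(GTR(rates=(1, 2, 3, 4, 5, 6)))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4))

    def test_jc_closed_form(self):
        Q = build_rate_matrix(HKY(kappa=1.0))
        P = transition_probabilities(Q, 0.1)
        expected_diag = 0.25 + 0.75 * np.exp(-4 * 0.1 / 3)
        assert np.allclose(np.diag(P), expected_diag, atol=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_nonreversible_matches_series_oracle(self, rng):
        n = 5
        rates = rng.uniform(0, 2, (n, n))
        rates[rng.random((n, n)) < 0.4] = 0.0  # sparse
        np.fill_diagonal(rates, 0.0)
        rates[rates.sum(axis=1) == 0, 0] = 1.0
        np.fill_diagonal(rates, 0.0)
        Q = build_rate_matrix(General(rates=rates, labels=[f"s{i}" for i in range(n)]))
        P = transition_probabilities(Q, 0.7)
        assert np.allclose(P, series_expm(Q.matrix * 0.7), atol=1e-8)

    def test_negative_distance_rejected(self):
        Q = build_rate_matrix(HKY(kappa=2.0))
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        d1=st.floats(0.01, 2.0),
        d2=st.floats(0.01, 2.0),
        kappa=st.floats(0.5, 10.0),
    )
    def test_chapman_kolmogorov(self, d1, d2, kappa):
        Q = build_rate_matrix(HKY(kappa=kappa, frequencies=(0.4, 0.1, 0.3, 0.2)))
        P12 = transition_probabilities(Q, d1 + d2)
        assert np.allclose(
            P12,
            transition_probabilities(Q, d1) @ transition_probabilities(Q, d2),
            atol=1e-8,
        )

    def test_chapman_kolmogorov_nonreversible(self, rng):
        rates = rng.uniform(0.1, 1.0, (4, 4))
        np.fill_diagonal(rates, 0.0)
        Q = build_rate_matrix(General(rates=rates, labels=list("WXYZ")))
        lhs = transition_probabilities(Q, 1.3)
        rhs = transition_probabilities(Q, 0.8) @ transition_probabilities(Q, 0.5)
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestStationaryDistribution:
    def test_jc_uniform(self):
        Q = build_rate_matrix(HKY(kappa=1.0))
        assert np.allclose(stationary_distribution(Q), 0.25, atol=1e-10)

    def test_gtr_returns_build_frequencies(self):
        pi = (0.1, 0.2, 0.3, 0.4)
        Q = build_rate_matrix(GTR(rates=(1, 2, 3, 4, 5, 6), frequencies=pi))
        assert np.allclose(stationary_distribution(Q), pi, atol=1e-8)

    def test_nonreversible_cycle_matches_linear_solve(self):
        # 3-state cycle X->Y->Z->X with unequal rates
        rates = np.array([[0, 2, 0], [0, 0, 5], [1, 0, 0]], dtype=float)
        Q = build_rate_matrix(General(rates=rates, labels=list("XYZ")))
        pi = stationary_distribution(Q)
        # oracle: left null vector by dense solve on the unnormalized system
        M = Q.matrix
        A = np.vstack([M.T[:-1], np.ones(3)])
        b = np.array([0.0, 0.0, 1.0])
        expected = np.linalg.solve(A, b)
        assert np.allclose(pi, expected, atol=1e-10)
        assert np.allclose(pi @ M, 0.0, atol=1e-12)

    def test_reducible_generator_reported(self):
        rates = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float
        )
        Q = build_rate_matrix(General(rates=rates, labels=list("WXYZ")))
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(Q)
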