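"""Frequency estimation, covariance, graphical lasso, coupling scores."""

import numpy as np
import pytest

from cdpred.coevolution import (
    CovarianceModel,
    PrecisionModel,
    coupling_scores,
    glasso_objective,
    glasso_precision,
    msa_couplings,
    sample_covariance,
    sequence_weights,
    shrink_to_spd,
    weighted_frequencies,
)
from cdpred.msa import Msa, N_STATES
from cdpred.reference import glasso_reference


def _random_spd(rng, p, n_factor=3):
    A = rng.normal(size=(p, n_factor * p))
    S = A @ A.T / (n_factor * p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestWeightedFrequencies:
    def test_identical_rows_no_pseudocount(self):
        msa = Msa("q", ["ACDE"] * 6)
        freqs = weighted_frequencies(msa, pseudocount=0.0)
        # each column's observed state has frequency exactly 1
        codes = msa.encoded()[0]
        for c, state in enumerate(codes):
            assert freqs.f1[c, state] == pytest.approx(1.0)
            assert freqs.f1[c].sum() == pytest.approx(1.0)

    def test_large_pseudocount_limit_is_uniform(self, tiny_msa):
        freqs = weighted_frequencies(tiny_msa, pseudocount=1e9)
        assert np.allclose(freqs.f1, 1.0 / N_STATES, atol=1e-6)

    def test_hand_counted_toy(self):
        # two columns, four rows, all mutually < 80% identical -> weight 1 each
        msa = Msa("q", ["AC", "AG", "TC", "TG"])
        w = sequence_weights(msa)
        assert np.allclose(w, 1.0)
        freqs = weighted_frequencies(msa, pseudocount=0.0)
        a, c, g, t = 0, 1, 5, 16  # indices in the alphabet
        assert freqs.f1[0, a] == pytest.approx(0.5)
        assert freqs.f1[0, t] == pytest.approx(0.5)
        assert freqs.f1[1, c] == pytest.approx(0.5)
        # pair table: each of the four combinations seen once -> 0.25
        q = N_STATES
        assert freqs.f2[0 * q + a, 1 * q + c] == pytest.approx(0.25)
        assert freqs.f2[0 * q + t, 1 * q + g] == pytest.approx(0.25)

    def test_redundant_rows_downweighted(self):
        # 3 identical rows + 1 distinct: the identical block shares weight
        msa = Msa("q", ["AAAA", "AAAA", "AAAA", "WWWW"])
        w = sequence_weights(msa)
        assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3, 1.0])

    def test_pair_tables_marginalise_to_single(self, tiny_msa):
        freqs = weighted_frequencies(tiny_msa, pseudocount=1.0)
        q = N_STATES
        for i in range(tiny_msa.width):
            for j in range(tiny_msa.width):
                block = freqs.f2[i * q : (i + 1) * q, j * q : (j + 1) * q]
                np.testing.assert_allclose(block.sum(axis=1), freqs.f1[i], atol=1e-12)

    def test_all_gap_column_warns(self):
        msa = Msa("q", ["A-C", "A-C", "T-G"])
        with pytest.warns(UserWarning, match="entirely gaps"):
            freqs = weighted_frequencies(msa, pseudocount=1.0)
        assert np.allclose(freqs.f1[1].sum(), 1.0)


class TestSampleCovariance:
    def test_independent_product_columns_zero_cross_block(self):
        # empirical pair frequencies factorise exactly
        msa = Msa("q", ["AC", "AG", "TC", "TG"])
        cov = sample_covariance(weighted_frequencies(msa, pseudocount=0.0))
        q = N_STATES
        cross = cov.matrix[0:q, q : 2 * q]
        assert np.abs(cross).max() < 1e-12

    def test_constant_column_zero_variance(self):
        msa = Msa("q", ["AA", "AC", "AG", "AT"])
        cov = sample_covariance(weighted_frequencies(msa, pseudocount=0.0))
        assert cov.matrix[0, 0] == pytest.approx(0.0)

    def test_toy_entries_match_hand_computation(self):
        msa = Msa("q", ["AC", "AG", "TC", "TG"])
        freqs = weighted_frequencies(msa, pseudocount=0.0)
        cov = sample_covariance(freqs)
        q = N_STATES
        a = 0
        # Var of indicator with p=0.5: f - f^2 = 0.25
        assert cov.matrix[a, a] == pytest.approx(0.25)
        assert np.allclose(cov.matrix, cov.matrix.T, atol=1e-10)


class TestShrinkToSpd:
    def test_already_pd_unchanged(self, rng):
        S = _random_spd(rng, 6)
        out = shrink_to_spd(CovarianceModel(S, 0.0, 0.0))
        assert out.shrinkage == 0.0
        np.testing.assert_array_equal(out.matrix, S)

    def test_rank_deficient_repaired(self):
        msa = Msa("q", ["ACDE", "ACDE", "WYYW"])
        cov = sample_covariance(weighted_frequencies(msa, pseudocount=1.0))
        assert np.linalg.eigvalsh(cov.matrix).min() < 1e-8  # genuinely deficient
        out = shrink_to_spd(cov)
        assert np.linalg.eigvalsh(out.matrix).min() > 1e-8

    def test_shrinkage_matches_eigen_scan_oracle(self, rng):
        A = rng.normal(size=(6, 3))
        S = A @ A.T  # singular 6x6
        step = 0.05
        out = shrink_to_spd(CovarianceModel(S, 0.0, 0.0), step=step)
        # brute-force scan of the same grid
        expected = None
        for k in range(21):
            s = round(k * step, 10)
            M = (1 - s) * S + s * np.diag(np.diag(S))
            if np.linalg.eigvalsh(M).min() > 1e-8:
                expected = s
                break
        assert out.shrinkage == pytest.approx(expected)


class TestGlasso:
    def test_identity_covariance_diagonal_precision(self):
        S = np.eye(8)
        pm = glasso_precision(CovarianceModel(S, 0.0, 0.0), rho=0.05)
        off = pm.matrix - np.diag(np.diag(pm.matrix))
        assert np.abs(off).max() < 1e-10

    def test_small_rho_recovers_inverse(self, rng):
        S = _random_spd(rng, 10, n_factor=5)
        pm = glasso_precision(
            CovarianceModel(S, 0.0, 0.0), rho=1e-8, tol=1e-10, max_iter=1000
        )
        assert np.abs(pm.matrix - np.linalg.inv(S)).max() < 1e-5

    def test_objective_matches_coordinate_descent_oracle(self, rng):
        S = _random_spd(rng, 10)
        rho = 0.1
        pm = glasso_precision(CovarianceModel(S, 0.0, 0.0), rho=rho, tol=1e-7,
                              max_iter=500)
        ref = glasso_reference(S, rho)
        assert abs(pm.objective - glasso_objective(ref, S, rho)) < 1e-4

    def test_output_symmetric_positive_definite(self, rng):
        S = _random_spd(rng, 12)
        pm = glasso_precision(CovarianceModel(S, 0.0, 0.0), rho=0.1)
        assert np.allclose(pm.matrix, pm.matrix.T, atol=1e-10)
        assert np.linalg.eigvalsh(pm.matrix).min() > 0

    def test_sparsity_monotone_in_rho(self, rng):
        S = _random_spd(rng, 15)
        nnz = []
        for rho in (0.01, 0.05, 0.1, 0.3):
            pm = glasso_precision(CovarianceModel(S, 0.0, 0.0), rho=rho,
                                  tol=1e-7, max_iter=500)
            off = pm.matrix - np.diag(np.diag(pm.matrix))
            nnz.append(int((np.abs(off) > 1e-8).sum()))
        assert nnz == sorted(nnz, reverse=True)

    def test_rho_must_be_positive(self):
        with pytest.raises(ValueError):
            glasso_precision(CovarianceModel(np.eye(3), 0.0, 0.0), rho=0.0)


class TestCouplingScores:
    def test_identity_precision_all_zero(self):
        pm = PrecisionModel(np.eye(N_STATES * 4), 0.1, 0.0, True)
        cm = coupling_scores(pm)
        assert np.abs(cm.scores).max() == 0.0

    def test_single_cross_block_detected(self):
        q = N_STATES
        L = 4
        mat = np.eye(q * L)
        mat[0 * q + 2, 2 * q + 3] = mat[2 * q + 3, 0 * q + 2] = 0.7
        cm = coupling_scores(PrecisionModel(mat, 0.1, 0.0, True), apc=False)
        assert cm.scores[0, 2] == pytest.approx(0.7)
        nonzero = {(i, j) for i in range(L) for j in range(L) if cm.scores[i, j] > 0}
        assert nonzero == {(0, 2), (2, 0)}

    def test_gap_state_excluded_from_norm(self):
        q = N_STATES
        mat = np.eye(q * 3)
        gap = q - 1
        mat[0 * q + gap, 1 * q + 4] = mat[1 * q + 4, 0 * q + gap] = 5.0
        cm = coupling_scores(PrecisionModel(mat, 0.1, 0.0, True), apc=False)
        assert cm.scores[0, 1] == 0.0

    def test_apc_matches_hand_formula(self, rng):
        q = N_STATES
        L = 5
        mat = rng.normal(size=(q * L, q * L))
        mat = mat + mat.T
        cm_raw = coupling_scores(PrecisionModel(mat, 0.1, 0.0, True), apc=False)
        cm_apc = coupling_scores(PrecisionModel(mat, 0.1, 0.0, True), apc=True)
        raw = cm_raw.scores
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                rm_i = raw[i].sum() / (L - 1)
                rm_j = raw[j].sum() / (L - 1)
                gm = raw.sum() / (L * (L - 1))
                assert cm_apc.scores[i, j] == pytest.approx(raw[i, j] - rm_i * rm_j / gm)

    def test_column_permutation_equivariance(self, toy30):
        from cdpred.synthetic import sample_coupled_msa

        msa = sample_coupled_msa(toy30, M=120, seed=9, n_aa_states=6,
                                 gap_fraction=0.0)
        cm = msa_couplings(msa, tol=1e-6, max_iter=300)
        rng = np.random.default_rng(4)
        perm = rng.permutation(msa.L)
        permuted = Msa(msa.query_id, ["".join(r[k] for k in perm) for r in msa.rows])
        cm_p = msa_couplings(permuted, tol=1e-6, max_iter=300)
        # agreement to solver tolerance (the sweep order differs)
        scale = np.abs(cm.scores).max()
        np.testing.assert_allclose(
            cm_p.scores, cm.scores[np.ix_(perm, perm)], atol=2e-3 * scale
        )
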