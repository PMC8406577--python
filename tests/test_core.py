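"""SVD denoising, neighborhoods, the three scorers, fusion and predict_all."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcfmda import (
    AssociationMatrix,
    HCFConfig,
    SimilarityMatrix,
    fuse,
    pair_similarity,
    predict_all,
    sda_score,
    sdma_score,
    sma_score,
    svd_denoise,
    top_n_neighbors,
)
from tests.conftest import random_similarity


def brute_force_predict(Xt, ID, IM, config):
    """Oracle: compose the scalar scorers entry by entry."""
    n_d, n_m = Xt.shape
    out = np.empty((n_d, n_m))
    for i in range(n_d):
        for j in range(n_m):
            out[i, j] = fuse(
                sda_score(Xt, ID, i, j, config),
                sma_score(Xt, IM, i, j, config),
                sdma_score(Xt, ID, IM, i, j, config),
                config,
            )
    return out


class TestSVD:
    def test_full_rank_reconstruction(self, small_assoc):
        cfg = HCFConfig(svd_rank=min(small_assoc.X.shape))
        assert np.allclose(svd_denoise(small_assoc, cfg), small_assoc.X, atol=1e-10)

    def test_rank_one_matrix_exact(self):
        u = np.array([1.0, 0.0, 1.0])
        v = np.array([1.0, 1.0, 0.0, 1.0])
        assoc = AssociationMatrix(
            ["d0", "d1", "d2"], ["m0", "m1", "m2", "m3"], np.outer(u, v)
        )
        out = svd_denoise(assoc, HCFConfig(svd_rank=1))
        assert np.allclose(out, assoc.X, atol=1e-10)

    def test_eckart_young_beats_random_competitors(self):
        rng = np.random.default_rng(17)
        X = (rng.random((6, 5)) < 0.4).astype(float)
        assoc = AssociationMatrix(
            [f"d{i}" for i in range(6)], [f"m{j}" for j in range(5)], X
        )
        k = 2
        Xt = svd_denoise(assoc, HCFConfig(svd_rank=k))
        err = np.linalg.norm(X - Xt)
        for _ in range(100):
            A = rng.standard_normal((6, k))
            B = rng.standard_normal((k, 5))
            M = A @ B
            assert err <= np.linalg.norm(X - M) + 1e-12

    def test_energy_fraction_selects_minimal_rank(self, small_assoc):
        U, s, Vt = np.linalg.svd(small_assoc.X, full_matrices=False)
        energy = np.cumsum(s**2) / (s**2).sum()
        for f in (0.5, 0.9, 0.99):
            Xt = svd_denoise(small_assoc, HCFConfig(svd_rank=f))
            k = int(np.searchsorted(energy, f) + 1)
            expect = (U[:, :k] * s[:k]) @ Vt[:k]
            assert np.allclose(Xt, expect, atol=1e-12)

    def test_excessive_rank_rejected(self, small_assoc):
        with pytest.raises(ValueError, match="rank"):
            svd_denoise(small_assoc, HCFConfig(svd_rank=10))


class TestNeighborhoods:
    def _sim(self, row):
        n = len(row)
        S = np.zeros((n, n))
        S[0] = row
        S[:, 0] = row
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix([f"e{i}" for i in range(n)], S, np.ones((n, n), bool))

    def test_best_single_neighbor(self):
        nb = top_n_neighbors(self._sim([1.0, 0.9, 0.2]), 0, 1)
        assert nb.indices.tolist() == [1]
        assert nb.similarities.tolist() == [0.9]
        assert not nb.shortfall

    def test_tie_broken_by_ascending_index(self):
        nb = top_n_neighbors(self._sim([1.0, 0.1, 0.5, 0.3, 0.5]), 0, 1)
        assert nb.indices.tolist() == [2]

    def test_shortfall_flag(self):
        nb = top_n_neighbors(self._sim([1.0, 0.9, 0.2]), 0, 5)
        assert nb.shortfall
        assert nb.indices.size == 2

    def test_exclusion_and_range_check(self):
        sim = self._sim([1.0, 0.9, 0.2])
        nb = top_n_neighbors(sim, 0, 1, exclude=[1])
        assert nb.indices.tolist() == [2]
        with pytest.raises(IndexError):
            top_n_neighbors(sim, 9, 1)


class TestScorers:
    def test_sda_worked_example(self):
        # neighbors of d0 with (s, x) = (0.8, 1), (0.4, 0) at N=2
        ID = SimilarityMatrix(
            ["d0", "d1", "d2"],
            np.array([[1.0, 0.8, 0.4], [0.8, 1.0, 0.0], [0.4, 0.0, 1.0]]),
            np.ones((3, 3), bool),
        )
        Xt = np.array([[0.0], [1.0], [0.0]])
        cfg = HCFConfig(n_neighbors=2)
        assert sda_score(Xt, ID, 0, 0, cfg) == pytest.approx(0.4)

    def test_sma_worked_example(self):
        IM = SimilarityMatrix(
            ["m0", "m1", "m2"],
            np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.0], [0.2, 0.0, 1.0]]),
            np.ones((3, 3), bool),
        )
        Xt = np.array([[0.0, 1.0, 1.0]])
        cfg = HCFConfig(n_neighbors=2)
        assert sma_score(Xt, IM, 0, 0, cfg) == pytest.approx(0.4)

    def test_sda_sma_mirror_under_transposition(self, small_assoc):
        rng = np.random.default_rng(23)
        ID = random_similarity(rng, 4)
        IM = random_similarity(rng, 5)
        cfg = HCFConfig(n_neighbors=3)
        for i in range(4):
            for j in range(5):
                assert sda_score(small_assoc.X, ID, i, j, cfg) == pytest.approx(
                    sma_score(small_assoc.X.T, ID, j, i, cfg)
                )

    def test_pair_similarity_values(self):
        assert pair_similarity(1.0, 1.0) == pytest.approx(1 / np.sqrt(2))
        s = 0.37
        assert pair_similarity(s, s) == pytest.approx(s / np.sqrt(2))
        assert pair_similarity(1e-9, 1.0) == pytest.approx(1e-9, rel=1e-6)
        assert pair_similarity(0.0, 1.0) is None
        assert pair_similarity(0.5, -0.1) is None
        assert pair_similarity(0.3, 0.8) == pair_similarity(0.8, 0.3)

    def test_sdma_single_candidate(self):
        # N=1, K=1: one candidate pair with s_d=0.8, s_m=0.6, x=1
        ID = SimilarityMatrix(
            ["d0", "d1"], np.array([[1.0, 0.8], [0.8, 1.0]]), np.ones((2, 2), bool)
        )
        IM = SimilarityMatrix(
            ["m0", "m1"], np.array([[1.0, 0.6], [0.6, 1.0]]), np.ones((2, 2), bool)
        )
        Xt = np.array([[0.0, 0.0], [0.0, 1.0]])
        cfg = HCFConfig(n_neighbors=1, k_pairs=1)
        expect = 1.0 / np.sqrt(1 / 0.64 + 1 / 0.36)
        got = sdma_score(Xt, ID, IM, 0, 0, cfg)
        assert got == pytest.approx(expect)
        assert got == pytest.approx(0.48)

    def test_sdma_zero_evidence(self):
        rng = np.random.default_rng(3)
        ID, IM = random_similarity(rng, 4), random_similarity(rng, 5)
        Xt = np.zeros((4, 5))
        assert sdma_score(Xt, ID, IM, 1, 2, HCFConfig(n_neighbors=2, k_pairs=3)) == 0.0

    def test_fuse_degeneracies(self):
        cfg = HCFConfig(alpha=0.7, beta=1.0)
        assert fuse(0.2, 0.9, 0.33, cfg) == pytest.approx(0.33)
        cfg = HCFConfig(alpha=1.0, beta=0.0)
        assert fuse(0.2, 0.9, 0.33, cfg) == pytest.approx(0.2)
        cfg = HCFConfig(alpha=0.3, beta=0.1)
        assert fuse(1.0, 1.0, 1.0, cfg) == pytest.approx(1.0)

    @given(
        alpha=st.floats(0, 1), beta=st.floats(0, 1),
        s=st.tuples(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_fuse_weights_conserve(self, alpha, beta, s):
        cfg = HCFConfig(alpha=alpha, beta=beta)
        a, b = alpha, beta
        assert a * (1 - b) + (1 - a) * (1 - b) + b == pytest.approx(1.0)
        # linearity: fusing equal inputs returns that input
        assert fuse(s[0], s[0], s[0], cfg) == pytest.approx(s[0], abs=1e-9)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            HCFConfig(alpha=1.5)
        with pytest.raises(ValueError):
            HCFConfig(beta=-0.1)


class TestPredictAll:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = (rng.random((6, 7)) < 0.35).astype(float)
        assoc = AssociationMatrix(
            [f"d{i}" for i in range(6)], [f"m{j}" for j in range(7)], X
        )
        ID = random_similarity(rng, 6, assoc.disease_ids)
        IM = random_similarity(rng, 7, assoc.mirna_ids)
        # mix in negative similarities, as z-scored matrices have
        ID.S[ID.S < 0.4] -= 0.5
        IM.S[IM.S < 0.4] -= 0.5
        cfg = HCFConfig(n_neighbors=3, k_pairs=4, svd_enabled=False)
        got = predict_all(assoc, ID, IM, cfg)
        expect = brute_force_predict(assoc.X, ID, IM, cfg)
        assert np.allclose(got.S_hat, expect, atol=1e-12)

    def test_matches_oracle_with_svd(self, small_assoc):
        rng = np.random.default_rng(9)
        ID = random_similarity(rng, 4, small_assoc.disease_ids)
        IM = random_similarity(rng, 5, small_assoc.mirna_ids)
        cfg = HCFConfig(n_neighbors=2, k_pairs=3, svd_rank=2, svd_enabled=True)
        Xt = svd_denoise(small_assoc, cfg)
        got = predict_all(small_assoc, ID, IM, cfg)
        expect = brute_force_predict(Xt, ID, IM, cfg)
        assert np.allclose(got.S_hat, expect, atol=1e-12)

    def test_beta_one_reproduces_sdma(self, small_assoc):
        rng = np.random.default_rng(41)
        ID = random_similarity(rng, 4, small_assoc.disease_ids)
        IM = random_similarity(rng, 5, small_assoc.mirna_ids)
        cfg = HCFConfig(beta=1.0, n_neighbors=2, k_pairs=2, svd_enabled=False)
        got = predict_all(small_assoc, ID, IM, cfg)
        for i in range(4):
            for j in range(5):
                assert got.S_hat[i, j] == pytest.approx(
                    sdma_score(small_assoc.X, ID, IM, i, j, cfg), abs=1e-12
                )

    def test_all_zero_matrix_scores_zero(self):
        assoc = AssociationMatrix(
            ["d0", "d1"], ["m0", "m1", "m2"], np.zeros((2, 3))
        )
        rng = np.random.default_rng(1)
        ID = random_similarity(rng, 2, assoc.disease_ids)
        IM = random_similarity(rng, 3, assoc.mirna_ids)
        out = predict_all(assoc, ID, IM, HCFConfig(svd_enabled=False, n_neighbors=1))
        assert np.allclose(out.S_hat, 0.0)

    def test_scores_bounded_by_max_similarity(self, small_assoc):
        rng = np.random.default_rng(7)
        ID = random_similarity(rng, 4, small_assoc.disease_ids)
        IM = random_similarity(rng, 5, small_assoc.mirna_ids)
        cfg = HCFConfig(n_neighbors=2, k_pairs=2, svd_enabled=False)
        out = predict_all(small_assoc, ID, IM, cfg)
        bound = max(ID.S.max(), IM.S.max())
        assert (out.S_hat <= bound + 1e-12).all()

    def test_adding_association_never_decreases_scores(self):
        """With nonnegative similarities and no denoising, each scorer is a
        nonnegative combination of matrix entries."""
        rng = np.random.default_rng(13)
        X = (rng.random((5, 6)) < 0.3).astype(float)
        assoc = AssociationMatrix(
            [f"d{i}" for i in range(5)], [f"m{j}" for j in range(6)], X
        )
        ID = random_similarity(rng, 5, assoc.disease_ids)
        IM = random_similarity(rng, 6, assoc.mirna_ids)
        cfg = HCFConfig(n_neighbors=2, k_pairs=3, svd_enabled=False)
        base = predict_all(assoc, ID, IM, cfg).S_hat
        zeros = np.argwhere(X == 0)
        i, j = zeros[len(zeros) // 2]
        X2 = X.copy()
        X2[i, j] = 1.0
        assoc2 = AssociationMatrix(list(assoc.disease_ids), list(assoc.mirna_ids), X2)
        bumped = predict_all(assoc2, ID, IM, cfg).S_hat
        assert (bumped >= base - 1e-12).all()

    def test_id_mismatch_rejected(self, small_assoc):
        rng = np.random.default_rng(2)
        ID = random_similarity(rng, 4)  # wrong labels
        IM = random_similarity(rng, 5, small_assoc.mirna_ids)
        with pytest.raises(ValueError, match="ids"):
            predict_all(small_assoc, ID, IM, HCFConfig())
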