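import numpy as np
import pytest
from sklearn.decomposition import NMF

from stscsr import SolverConfig, TriFactorModel, initialize, objective, solve
from stscsr.optimizer import (update_Be, update_Bs, update_C, update_Fe,
                              update_Fs, update_Z)

from conftest import tiny_tri_instance
from _oracles import oracle_affinity, oracle_basis, oracle_coefficients, oracle_core


def naive_objective(X, W, L, model, Z, alpha, beta, gamma):
    """Scalar-loop evaluation of every term, no matrix shortcuts."""
    def mm(A, B):
        out = np.zeros((A.shape[0], B.shape[1]))
        for i in range(A.shape[0]):
            for j in range(B.shape[1]):
                out[i, j] = sum(A[i, t] * B[t, j] for t in range(A.shape[1]))
        return out

    def fro2(M):
        return sum(M[i, j] ** 2 for i in range(M.shape[0])
                   for j in range(M.shape[1]))

    Re = X - mm(mm(model.B_e, model.C), model.F_e)
    Rs = W - mm(mm(model.B_s, model.C), model.F_s)
    val = fro2(Re) + fro2(Rs)
    FLFt = mm(mm(model.F_e, L), model.F_e.T)
    val += alpha * sum(FLFt[i, i] for i in range(FLFt.shape[0]))
    val += beta * (fro2(model.F_e - mm(model.F_e, Z))
                   + fro2(model.F_s - mm(model.F_s, Z)))
    val += gamma * sum(abs(Z[i, j]) for i in range(Z.shape[0])
                       for j in range(Z.shape[1]))
    return val


class TestObjective:
    def test_matches_scalar_loop_evaluation(self):
        rng = np.random.default_rng(0)
        m, n, k = 6, 8, 3
        X = rng.random((m, n))
        W = rng.random((n, n))
        W = 0.5 * (W + W.T)
        L = np.diag(W.sum(1)) - W
        model = TriFactorModel(rng.random((m, k)), rng.random((n, k)),
                               0.5 * (lambda c: c + c.T)(rng.random((k, k))),
                               rng.random((k, n)), rng.random((k, n)), k)
        Z = rng.standard_normal((n, n))
        Z = 0.5 * (Z + Z.T)
        np.fill_diagonal(Z, 0.0)
        got = objective(X, W, L, model, Z, 1.3, 0.7, 2.1)
        want = naive_objective(X, W, L, model, Z, 1.3, 0.7, 2.1)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_at_exact_factorization(self):
        rng = np.random.default_rng(1)
        k, m, n = 2, 5, 4
        B_e = rng.random((m, k))
        B_s = rng.random((n, k))
        C = np.eye(k)
        F_e = rng.random((k, n))
        F_s = rng.random((k, n))
        X = B_e @ C @ F_e
        W = B_s @ C @ F_s
        model = TriFactorModel(B_e, B_s, C, F_e, F_s, k)
        val = objective(X, W, np.zeros((n, n)), model, np.zeros((n, n)),
                        0.0, 0.0, 0.0)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_trace_term_vanishes_for_constant_columns(self):
        rng = np.random.default_rng(2)
        n, k = 6, 2
        W = rng.random((n, n))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L = np.diag(W.sum(1)) - W
        F_e = np.tile(rng.random((k, 1)), (1, n))  # constant across spots
        assert np.sum((F_e @ L) * F_e) == pytest.approx(0.0, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        model = TriFactorModel(np.ones((3, 2)), np.ones((4, 2)), np.eye(2),
                               np.ones((2, 4)), np.ones((2, 4)), 2)
        with pytest.raises(ValueError):
            objective(np.ones((3, 5)), np.ones((4, 4)), np.ones((4, 4)),
                      model, np.zeros((4, 4)), 0, 0, 0)


class TestInitialize:
    def test_rank_one_exact(self):
        rng = np.random.default_rng(3)
        u, v = rng.random(8) + 0.1, rng.random(6) + 0.1
        X = np.outer(u, v)
        W = np.outer(v, v)
        model, aff = initialize(X, W, 1, "nndsvd", 0)
        recon = model.B_e @ model.C @ model.F_e
        assert np.sum((X - recon) ** 2) <= 1e-6 * np.sum(X ** 2)
        np.testing.assert_array_equal(aff.Z, 0.0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X, W = rng.random((10, 8)), rng.random((8, 8))
        W = 0.5 * (W + W.T)
        m1, _ = initialize(X, W, 3, "random", 11)
        m2, _ = initialize(X, W, 3, "random", 11)
        for attr in ("B_e", "B_s", "C", "F_e", "F_s"):
            np.testing.assert_array_equal(getattr(m1, attr), getattr(m2, attr))

    def test_beats_all_ones_factors(self):
        rng = np.random.default_rng(5)
        X = rng.random((9, 7))
        W = rng.random((7, 7))
        W = 0.5 * (W + W.T)
        model, _ = initialize(X, W, 2, "nndsvd", 0)
        init_res = np.sum((X - model.B_e @ model.C @ model.F_e) ** 2)
        ones_res = np.sum((X - np.ones((9, 2)) @ np.ones((2, 7))) ** 2)
        assert init_res <= ones_res

    def test_rank_too_large_rejected(self):
        with pytest.raises(ValueError):
            initialize(np.ones((4, 3)), np.ones((3, 3)), 5)


@pytest.mark.parametrize("seed", [0, 1, 2])
class TestBlockOracles:
    """Each block update must match a generic constrained solver."""

    def test_basis_blocks(self, seed):
        X, W, L, B_e, B_s, C, F_e, F_s = tiny_tri_instance(seed)
        model = TriFactorModel(B_e, B_s, C, F_e, F_s, 3)
        A = C @ F_e
        got = update_Be(model, X)
        mine = np.sum((X - got @ A) ** 2)
        ref, _ = oracle_basis(X, A, B_e.shape)
        assert abs(mine - ref) <= 1e-4

        A2 = C @ F_s
        got2 = update_Bs(model, W)
        mine2 = np.sum((W - got2 @ A2) ** 2)
        ref2, _ = oracle_basis(W, A2, B_s.shape)
        assert abs(mine2 - ref2) <= 1e-4

    def test_core_block(self, seed):
        X, W, L, B_e, B_s, C, F_e, F_s = tiny_tri_instance(seed)
        model = TriFactorModel(B_e, B_s, C, F_e, F_s, 3)
        norm_max = np.sqrt(3)
        got = update_C(model, X, W, norm_max=norm_max)
        mine = (np.sum((X - B_e @ got @ F_e) ** 2)
                + np.sum((W - B_s @ got @ F_s) ** 2))
        ref, _ = oracle_core(X, W, B_e, B_s, F_e, F_s, 3, norm_max)
        assert np.abs(got - got.T).max() <= 1e-9
        assert np.linalg.norm(got) <= norm_max + 1e-9
        assert abs(mine - ref) <= 1e-4

    def test_coefficient_blocks(self, seed):
        X, W, L, B_e, B_s, C, F_e, F_s = tiny_tri_instance(seed)
        model = TriFactorModel(B_e, B_s, C, F_e, F_s, 3)
        rng = np.random.default_rng(100 + seed)
        Z = rng.standard_normal((5, 5)) * 0.1
        Z = 0.5 * (Z + Z.T)
        np.fill_diagonal(Z, 0)
        alpha, beta = 0.7, 0.5

        Q = B_e @ C
        IZ = np.eye(5) - Z
        right = alpha * L + beta * IZ @ IZ.T
        got = update_Fe(model, X, Z, L, alpha, beta)

        def block_obj(F):
            return (np.sum((X - Q @ F) ** 2) + alpha * np.sum((F @ L) * F)
                    + beta * np.sum((F - F @ Z) ** 2))

        ref, _ = oracle_coefficients(Q.T @ Q, right, Q.T @ X, F_e.shape)
        ref += np.sum(X * X)  # oracle drops the constant term
        assert abs(block_obj(got) - ref) <= 1e-4

        Q2 = B_s @ C
        got2 = update_Fs(model, W, Z, beta)
        ref2, _ = oracle_coefficients(Q2.T @ Q2, beta * IZ @ IZ.T, Q2.T @ W,
                                      F_s.shape)
        ref2 += np.sum(W * W)
        mine2 = np.sum((W - Q2 @ got2) ** 2) + beta * np.sum((got2 - got2 @ Z) ** 2)
        assert abs(mine2 - ref2) <= 1e-4

    def test_affinity_block(self, seed):
        _, _, _, _, _, _, F_e, F_s = tiny_tri_instance(seed)
        beta, gamma = 1.0, 0.5
        aff = update_Z(F_e, F_s, beta, gamma, tol=1e-10, max_inner=3000)

        def h(Z):
            return (beta * (np.sum((F_e - F_e @ Z) ** 2)
                            + np.sum((F_s - F_s @ Z) ** 2))
                    + gamma * np.abs(Z).sum())

        ref, _ = oracle_affinity(F_e, F_s, beta, gamma)
        assert abs(h(aff.Z) - ref) <= 1e-4
        assert np.abs(aff.Z - aff.Z.T).max() <= 1e-9
        assert np.abs(np.diag(aff.Z)).max() == 0.0


class TestAffinitySpecialCases:
    def test_huge_gamma_kills_all_entries(self):
        rng = np.random.default_rng(6)
        F = rng.random((3, 6))
        aff = update_Z(F, F, beta=1.0, gamma=1e9)
        np.testing.assert_array_equal(aff.Z, 0.0)

    def test_identity_representation_without_diag_constraint(self):
        F = np.eye(4)
        aff = update_Z(F, F, beta=1.0, gamma=0.0, zero_diag=False,
                       tol=1e-10, max_inner=5000)
        np.testing.assert_allclose(aff.Z, np.eye(4), atol=1e-5)

    def test_beta_zero_returns_zero(self):
        F = np.ones((2, 4))
        aff = update_Z(F, F, beta=0.0, gamma=3.0)
        np.testing.assert_array_equal(aff.Z, 0.0)
        assert aff.converged

    def test_sparsity_nonincreasing_in_gamma(self):
        rng = np.random.default_rng(7)
        F_e = rng.random((4, 12)) * 3
        F_s = rng.random((4, 12))
        nnz = []
        for gamma in (1.0, 10.0, 50.0, 100.0):
            aff = update_Z(F_e, F_s, 1.0, gamma)
            nnz.append(int((np.abs(aff.Z) > 1e-6).sum()))
        assert nnz == sorted(nnz, reverse=True)


class TestSolve:
    def test_noiseless_planted_instance_recovered(self):
        rng = np.random.default_rng(8)
        k, m, n = 3, 20, 15
        B_e = rng.random((m, k))
        B_e /= np.linalg.norm(B_e, axis=0)
        B_s = rng.random((n, k))
        B_s /= np.linalg.norm(B_s, axis=0)
        C = np.diag(rng.random(k) + 0.5)
        F_e = rng.random((k, n)) * 3
        X = B_e @ C @ F_e
        W = B_s @ C @ B_s.T
        L = np.diag(W.sum(1)) - W
        cfg = SolverConfig(alpha=0, beta=0, gamma=0, k=k, max_outer=60,
                           tol=1e-9, seed=0)
        model, aff = solve(X, W, L, cfg)
        res = np.sum((X - model.B_e @ model.C @ model.F_e) ** 2)
        assert res <= 1e-3 * np.sum(X ** 2)

    def test_same_seed_identical_traces(self):
        rng = np.random.default_rng(9)
        X = rng.random((15, 12)) * 2
        W = rng.random((12, 12))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L = np.diag(W.sum(1)) - W
        cfg = SolverConfig(alpha=0.5, beta=0.5, gamma=1.0, k=4, max_outer=8,
                           tol=1e-12, seed=5)
        _, a1 = solve(X, W, L, cfg)
        _, a2 = solve(X, W, L, cfg)
        assert a1.objective_trace == a2.objective_trace

    def test_constraints_and_monotonicity(self):
        rng = np.random.default_rng(10)
        X = rng.random((20, 16)) * 2
        W = rng.random((16, 16))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L = np.diag(W.sum(1)) - W
        cfg = SolverConfig(alpha=1.0, beta=0.5, gamma=2.0, k=5, max_outer=12,
                           tol=1e-12, seed=1)
        model, aff = solve(X, W, L, cfg)
        for name in ("B_e", "B_s", "F_e", "F_s"):
            assert getattr(model, name).min() >= 0.0
        assert np.abs(model.C - model.C.T).max() <= 1e-9
        assert np.abs(aff.Z - aff.Z.T).max() <= 1e-9
        assert np.abs(np.diag(aff.Z)).max() == 0.0
        tr = np.array(aff.objective_trace)
        assert np.all(np.diff(tr) <= 1e-6 * np.maximum(1.0, np.abs(tr[:-1])))

    def test_reduces_to_plain_nmf_when_regularizers_off(self):
        rng = np.random.default_rng(11)
        X = rng.random((30, 24)) * 3
        W = rng.random((24, 24))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0)
        L = np.diag(W.sum(1)) - W
        k = 5
        cfg = SolverConfig(alpha=0, beta=0, gamma=0, k=k, max_outer=50,
                           tol=1e-9, seed=0, fix_C=True)
        model, _ = solve(X, W, L, cfg)
        mine = np.sum((X - model.B_e @ model.F_e) ** 2)
        ref_model = NMF(n_components=k, init="nndsvda", random_state=0,
                        max_iter=2000, tol=1e-8)
        Wm = ref_model.fit_transform(X)
        ref = np.sum((X - Wm @ ref_model.components_) ** 2)
        assert mine <= ref * 1.02

    def test_rejects_invalid_inputs(self):
        X = np.ones((4, 3))
        W = np.ones((3, 3))
        L = np.zeros((3, 3))
        with pytest.raises(ValueError):
            solve(-X, W, L, SolverConfig(k=2))
        X2 = X.copy()
        X2[:, 1] = 0.0
        with pytest.raises(ValueError, match="empty spots"):
            solve(X2, W, L, SolverConfig(k=2))
        W2 = W.copy()
        W2[0, 1] = 5.0
        with pytest.raises(ValueError):
            solve(X, W2, L, SolverConfig(k=2))
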