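import numpy as np
import pytest
from scipy.special import expit

from lpipredict import (
    DataError,
    LatentFactors,
    NRLMFParams,
    build_laplacians,
    build_neighbors,
    fit,
    gradients,
    interaction_prob,
    objective,
    smooth_and_score,
)
from lpipredict.nrlmf import build_graph, prob_matrix, score_matrix_nrlmf
from conftest import random_similarity

from oracles import loglik_compact_form, loglik_split_form


def small_instance(seed=0, m=5, n=4, r=2, c=5.0, alpha=0.1, beta=0.1,
                   lam=0.5, density=0.4):
    rng = np.random.default_rng(seed)
    lnc_sim = random_similarity(m, rng, "lncrna")
    prot_sim = random_similarity(n, rng, "protein")
    Y = (rng.random((m, n)) < density).astype(float)
    params = NRLMFParams(r=r, c=c, alpha=alpha, beta=beta, lambda_l=lam,
                         lambda_p=lam, K1=2, K2=2, seed=seed)
    graph = build_graph(lnc_sim, prot_sim, params)
    factors = LatentFactors(rng.standard_normal((m, r)),
                            rng.standard_normal((n, r)))
    return Y, lnc_sim, prot_sim, params, graph, factors


class TestInteractionProb:
    def test_logistic_at_zero(self):
        assert interaction_prob(np.zeros(3), np.ones(3)) == 0.5

    def test_symmetry_identity(self, rng):
        u, v = rng.standard_normal(4), rng.standard_normal(4)
        assert interaction_prob(u, v) + interaction_prob(-u, v) == pytest.approx(1.0)

    def test_saturation_no_overflow(self):
        p = interaction_prob(np.array([500.0]), np.array([1.0]))
        assert 0.0 < p <= 1.0 and p == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(DataError):
            interaction_prob(np.ones(2), np.ones(3))


class TestBuildNeighbors:
    def test_all_neighbors_equals_zerodiag_similarity(self, rng):
        sim = random_similarity(5, rng)
        A = build_neighbors(sim, 4)
        expected = sim.M.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(A, expected)

    def test_rows_have_exactly_k_nonzeros(self, rng):
        sim = random_similarity(7, rng)
        A = build_neighbors(sim, 3)
        assert np.all((A > 0).sum(axis=1) == 3)

    def test_matches_sort_and_select_oracle(self, rng):
        sim = random_similarity(7, rng)
        K = 3
        A = build_neighbors(sim, K)
        for i in range(7):
            others = [(sim.M[i, j], j) for j in range(7) if j != i]
            top = sorted(others, key=lambda t: -t[0])[:K]
            expected = np.zeros(7)
            for s, j in top:
                expected[j] = s
            assert np.allclose(A[i], expected)

    def test_k_bounds(self, rng):
        with pytest.raises(DataError):
            build_neighbors(random_similarity(4, rng), 4)


class TestLaplacians:
    def test_zero_adjacency_gives_zero_laplacian(self):
        g = build_laplacians(np.zeros((3, 3)), np.zeros((2, 2)))
        assert np.all(g.laplacian_l == 0) and np.all(g.laplacian_p == 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_trace_identity(self, seed):
        # (1/2) sum_ij a_ij ||u_i - u_j||^2 == (1/2) tr(U' L U)
        r = np.random.default_rng(seed)
        A = r.random((6, 6))
        np.fill_diagonal(A, 0.0)
        U = r.standard_normal((6, 3))
        g = build_laplacians(A, np.zeros((2, 2)))
        lhs = 0.5 * sum(A[i, j] * np.sum((U[i] - U[j]) ** 2)
                        for i in range(6) for j in range(6))
        rhs = 0.5 * np.trace(U.T @ g.laplacian_l @ U)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_positive_semidefinite(self, seed):
        r = np.random.default_rng(10 + seed)
        A = r.random((8, 8))
        np.fill_diagonal(A, 0.0)
        L = build_laplacians(A, np.zeros((2, 2))).laplacian_l
        assert np.allclose(L, L.T)
        assert np.linalg.eigvalsh(L).min() >= -1e-9


class TestObjective:
    def test_closed_form_at_origin(self):
        Y, ls, ps, params, graph, _ = small_instance()
        m, n = Y.shape
        zero = LatentFactors(np.zeros((m, params.r)), np.zeros((n, params.r)))
        expected = np.sum(1.0 + (params.c - 1.0) * Y) * np.log(2.0)
        assert objective(zero, Y, graph, params) == pytest.approx(expected)

    def test_unregularized_reduces_to_softplus_sum(self):
        Y, ls, ps, params, graph, factors = small_instance(
            alpha=0.0, beta=0.0, lam=0.0)
        Y0 = np.zeros_like(Y)
        expected = np.log1p(np.exp(factors.U @ factors.V.T)).sum()
        assert objective(factors, Y0, graph, params) == pytest.approx(expected)

    def test_data_term_is_negative_loglik_when_c1(self):
        # with c = 1 the data term equals the plain Bernoulli NLL
        Y, ls, ps, params, graph, factors = small_instance(
            m=4, n=3, c=1.0, alpha=0.0, beta=0.0, lam=0.0)
        P = expit(factors.U @ factors.V.T)
        nll = -np.sum(Y * np.log(P) + (1 - Y) * np.log(1 - P))
        assert objective(factors, Y, graph, params) == pytest.approx(nll)

    def test_weighted_likelihood_forms_agree(self, rng):
        # the split-product form and the compact exponent form of the
        # c-weighted likelihood agree in log space
        Y = (rng.random((4, 3)) < 0.5).astype(float)
        P = np.clip(rng.random((4, 3)), 0.05, 0.95)
        for c in (1.0, 5.0):
            assert loglik_split_form(Y, P, c) == pytest.approx(
                loglik_compact_form(Y, P, c), rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("c,alpha", [(1.0, 0.0), (5.0, 0.1)])
    def test_matches_finite_differences(self, seed, c, alpha):
        Y, ls, ps, params, graph, factors = small_instance(
            seed=seed, c=c, alpha=alpha, beta=alpha)
        G_U, G_V = gradients(factors, Y, graph, params)
        eps = 1e-6
        scale = max(np.abs(G_U).max(), np.abs(G_V).max())
        for A, G in ((factors.U, G_U), (factors.V, G_V)):
            it = np.nditer(A, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = A[idx]
                A[idx] = orig + eps
                hi = objective(factors, Y, graph, params)
                A[idx] = orig - eps
                lo = objective(factors, Y, graph, params)
                A[idx] = orig
                assert (hi - lo) / (2 * eps) == pytest.approx(
                    G[idx], rel=1e-5, abs=1e-5 * scale)

    def test_simplifies_to_plain_logistic_mf(self):
        Y, ls, ps, params, graph, factors = small_instance(
            c=1.0, alpha=0.0, beta=0.0, lam=0.0)
        G_U, _ = gradients(factors, Y, graph, params)
        P = expit(factors.U @ factors.V.T)
        assert np.allclose(G_U, (P - Y) @ factors.V)


class TestFit:
    def test_deterministic_given_seed(self):
        Y, ls, ps, params, graph, _ = small_instance(m=8, n=5, r=2)
        f1 = fit(Y, ls, ps, params)
        f2 = fit(Y, ls, ps, params)
        assert np.array_equal(f1.U, f2.U) and np.array_equal(f1.V, f2.V)

    def test_objective_decreases(self):
        Y, ls, ps, params, graph, _ = small_instance(m=8, n=5, r=2)
        factors, history = fit(Y, ls, ps, params, return_history=True)
        assert objective(factors, Y, graph, params) < history[0]

    def test_planted_model_recovery(self):
        rng = np.random.default_rng(3)
        m, n, r = 30, 15, 2
        U0 = rng.standard_normal((m, r))
        V0 = rng.standard_normal((n, r))
        Y = (expit(2.0 * U0 @ V0.T) > 0.5).astype(float)
        ls = random_similarity(m, rng, "lncrna")
        ps = random_similarity(n, rng, "protein")
        params = NRLMFParams(r=r, K1=3, K2=3, seed=0)
        factors = fit(Y, ls, ps, params)
        P = prob_matrix(factors)
        assert P[Y == 1].mean() > P[Y == 0].mean()

    def test_regularization_shrinks_factors(self):
        Y, ls, ps, _, _, _ = small_instance(m=8, n=5)
        norms = []
        for lam in (0.1, 10.0):
            params = NRLMFParams(r=2, lambda_l=lam, lambda_p=lam,
                                 K1=2, K2=2, seed=0)
            factors = fit(Y, ls, ps, params)
            norms.append(np.linalg.norm(factors.U))
        assert norms[1] < norms[0]


class TestSmoothAndScore:
    def test_no_cold_entities_scores_equal_probs(self, rng):
        Y, ls, ps, params, graph, _ = small_instance(m=6, n=4, density=0.9)
        assert Y.sum(axis=1).min() >= 1 and Y.sum(axis=0).min() >= 1
        factors = fit(Y, ls, ps, params)
        S = smooth_and_score(factors, Y, ls, ps, K2=2)
        assert np.allclose(S.M, prob_matrix(factors))

    def test_cold_lncrna_single_neighbor_copies_vector(self, rng):
        Y, ls, ps, params, graph, _ = small_instance(m=5, n=4, density=0.9)
        Y[2] = 0.0  # make lncRNA 2 cold
        factors = fit(Y, ls, ps, params)
        warm = [i for i in range(5) if i != 2]
        S1 = smooth_and_score(factors, Y, ls, ps, K2=1)
        nbr = max(warm, key=lambda i: ls.M[2, i])
        expected = expit(factors.U[nbr] @ _smoothed_V(factors, Y, ps, 1).T)
        assert np.allclose(S1.M[2], expected)

    def test_cold_lncrna_weighted_mean_oracle(self):
        Y, ls, ps, params, graph, _ = small_instance(m=6, n=4, density=0.9)
        Y[3] = 0.0
        factors = fit(Y, ls, ps, params)
        warm = [i for i in range(6) if i != 3]
        sims = sorted(((ls.M[3, i], i) for i in warm), reverse=True)[:3]
        w = np.array([s for s, _ in sims])
        w = w / w.sum()
        u_tilde = sum(wk * factors.U[i] for wk, (_, i) in zip(w, sims))
        S = smooth_and_score(factors, Y, ls, ps, K2=3)
        expected = expit(u_tilde @ _smoothed_V(factors, Y, ps, 3).T)
        assert np.allclose(S.M[3], expected)

    def test_scores_strictly_inside_unit_interval(self):
        Y, ls, ps, params, graph, _ = small_instance(m=6, n=4)
        factors = fit(Y, ls, ps, params)
        factors.U *= 100.0  # force logistic saturation
        S = smooth_and_score(factors, Y, ls, ps, K2=2)
        assert S.M.min() > 0.0 and S.M.max() < 1.0


def _smoothed_V(factors, Y, prot_sim, K2):
    """Protein-side smoothing, recomputed independently for the tests."""
    V = factors.V.copy()
    warm = np.nonzero(Y.sum(axis=0) > 0)[0]
    for j in np.nonzero(Y.sum(axis=0) == 0)[0]:
        sims = sorted(((prot_sim.M[j, v], v) for v in warm), reverse=True)[:K2]
        w = np.array([s for s, _ in sims])
        w = w / w.sum()
        V[j] = sum(wk * factors.V[v] for wk, (_, v) in zip(w, sims))
    return V


class TestScoreMatrixNrlmf:
    def test_full_pipeline_shapes_and_range(self, tiny_dataset, tiny_sims):
        lnc, prot = tiny_sims
        params = NRLMFParams(r=2, K1=2, K2=2)
        S = score_matrix_nrlmf(tiny_dataset, lnc, prot, params)
        assert S.M.shape == tiny_dataset.shape
        assert S.source == "nrlmf"
        assert 0.0 < S.M.min() and S.M.max() < 1.0
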