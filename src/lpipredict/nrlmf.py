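"""Neighborhood-regularized logistic matrix factorization.

The probability that lncRNA i interacts with protein j is modeled as a
logistic function of the inner product of latent vectors,
p_ij = sigma(u_i . v_j), with positive observations up-weighted by c >= 1
(there are no verified negatives; zeros are weakly-weighted unknowns).
Gaussian priors on the factors give Frobenius penalties (lambda = 1/sigma^2),
and a graph-Laplacian term pulls each entity toward its K1 most similar
neighbors in latent space.  The objective minimized over U (m x r) and
V (n x r) is

  sum_ij (1 + c y_ij - y_ij) ln(1 + exp(u_i.v_j)) - c y_ij u_i.v_j
    + 1/2 tr[U'(lambda_l I + alpha L_l)U] + 1/2 tr[V'(lambda_p I + beta L_p)V]

where L_l = (D + D~) - (A + A') is the Laplacian of the (asymmetric)
K1-nearest-neighbor similarity adjacency A, and likewise L_p for
proteins.  Optimization is full-gradient AdaGrad.

After fitting, entities with no training interactions (cold start) have
their latent vector replaced by the similarity-weighted mean of their K2
nearest neighbors among entities that do have interactions; scores are
then S_N(i, j) = sigma(u~_i . v~_j).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .datasets import InteractionDataset
from .ensemble import ScoreMatrix
from .errors import DataError, DivergenceError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

# keeps scores strictly inside (0, 1) despite float saturation of expit
_P_EPS = 1e-15


@dataclass(frozen=True)
class NRLMFParams:
    """Hyperparameters of the factorization.

    r : latent dimension (must satisfy r < min(m, n)).
    c : importance weight of positive observations (>= 1).
    lambda_l, lambda_p : Gaussian-prior precisions (1/sigma^2) on the
        lncRNA and protein factors.
    alpha, beta : neighborhood-regularization weights.
    K1 : neighbors used in the training Laplacians.
    K2 : neighbors used for cold-start smoothing.
    learn_rate, max_iter : AdaGrad step scale and iteration count.
    seed : RNG seed for the factor initialization.
    """

    r: int = 3
    c: float = 10.0
    lambda_l: float = 0.5
    lambda_p: float = 0.5
    alpha: float = 2.0
    beta: float = 2.0
    K1: int = 5
    K2: int = 5
    learn_rate: float = 0.5
    max_iter: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.r < 1:
            raise DataError("latent dimension r must be >= 1")
        if self.c < 1:
            raise DataError("positive-sample weight c must be >= 1")
        if min(self.lambda_l, self.lambda_p, self.alpha, self.beta) < 0:
            raise DataError("regularization weights must be nonnegative")
        if self.K1 < 1 or self.K2 < 1:
            raise DataError("neighborhood sizes must be >= 1")
        if self.learn_rate <= 0 or self.max_iter < 1:
            raise DataError("learn_rate must be > 0 and max_iter >= 1")

    def check_shapes(self, m: int, n: int) -> None:
        if self.r >= min(m, n):
            raise DataError(f"r={self.r} must be < min(m, n) = {min(m, n)}")
        if self.K1 >= min(m, n) or self.K2 >= min(m, n):
            raise DataError("K1, K2 must be smaller than both entity counts")


@dataclass
class LatentFactors:
    """Fitted latent vectors: U rows are lncRNAs, V rows are proteins."""

    U: np.ndarray = field(repr=False)
    V: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=np.float64)
        self.V = np.asarray(self.V, dtype=np.float64)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise DataError("U and V must be 2-d with a common latent dimension")
        if not (np.isfinite(self.U).all() and np.isfinite(self.V).all()):
            raise DataError("latent factors contain non-finite entries")


@dataclass
class NeighborGraph:
    """K-nearest-neighbor adjacencies and their graph Laplacians."""

    A: np.ndarray = field(repr=False)
    B: np.ndarray = field(repr=False)
    laplacian_l: np.ndarray = field(repr=False)
    laplacian_p: np.ndarray = field(repr=False)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    """ln(1 + exp(x)) without overflow (softplus)."""
    return np.logaddexp(0.0, x)


def interaction_prob(u: np.ndarray, v: np.ndarray) -> float:
    """Logistic interaction probability sigma(u . v) for one pair."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise DataError(f"latent dimension mismatch: {u.shape} vs {v.shape}")
    return float(expit(u @ v))


def prob_matrix(factors: LatentFactors) -> np.ndarray:
    """P with p_ij = sigma(u_i . v_j), clipped strictly inside (0, 1)."""
    return np.clip(expit(factors.U @ factors.V.T), _P_EPS, 1.0 - _P_EPS)


def build_neighbors(sim: SimilarityMatrix, K: int) -> np.ndarray:
    """K-nearest-neighbor adjacency from a similarity matrix.

    Row i keeps the similarity values of the K most similar *other*
    entities and zeroes the rest.  Generally asymmetric.  Ties are
    broken by index order (stable argsort), so the result is
    deterministic.
    """
    k_total = len(sim.ids)
    if not (1 <= K < k_total):
        raise DataError(f"K={K} must satisfy 1 <= K < {k_total}")
    S = sim.M.copy()
    np.fill_diagonal(S, -np.inf)
    order = np.argsort(-S, axis=1, kind="stable")[:, :K]
    A = np.zeros((k_total, k_total))
    rows = np.repeat(np.arange(k_total), K)
    A[rows, order.ravel()] = sim.M[rows, order.ravel()]
    return A


def _laplacian(A: np.ndarray) -> np.ndarray:
    d_out = np.diag(A.sum(axis=1))
    d_in = np.diag(A.sum(axis=0))
    return (d_out + d_in) - (A + A.T)


def build_laplacians(A: np.ndarray, B: np.ndarray) -> NeighborGraph:
    """Graph Laplacians L = (D + D~) - (A + A') for both adjacencies.

    D and D~ hold row and column sums; the result is symmetric positive
    semidefinite, and (1/2) tr(U' L U) equals the weighted sum of squared
    latent distances between neighbors.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    for name, M in (("A", A), ("B", B)):
        if (M < 0).any() or np.diagonal(M).any():
            raise DataError(f"adjacency {name} must be nonnegative with zero diagonal")
    return NeighborGraph(A, B, _laplacian(A), _laplacian(B))


def _weights(Y: np.ndarray, c: float) -> np.ndarray:
    # (1 + c*y - y): c for positives, 1 for unknowns
    return 1.0 + (c - 1.0) * Y


def objective(factors: LatentFactors, Y: np.ndarray, graph: NeighborGraph,
              params: NRLMFParams) -> float:
    """Regularized negative log-posterior being minimized."""
    U, V = factors.U, factors.V
    Z = U @ V.T
    data = np.sum(_weights(Y, params.c) * _log1pexp(Z) - params.c * Y * Z)
    reg_u = 0.5 * np.trace(
        U.T @ (params.lambda_l * np.eye(U.shape[0]) + params.alpha * graph.laplacian_l) @ U
    )
    reg_v = 0.5 * np.trace(
        V.T @ (params.lambda_p * np.eye(V.shape[0]) + params.beta * graph.laplacian_p) @ V
    )
    return float(data + reg_u + reg_v)


def gradients(factors: LatentFactors, Y: np.ndarray, graph: NeighborGraph,
              params: NRLMFParams) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`objective` with respect to U and V.

    G_U = P V + (c-1)(Y o P) V - c Y V + (lambda_l I + alpha L_l) U
    and symmetrically for V (o is the Hadamard product).
    """
    U, V = factors.U, factors.V
    P = expit(U @ V.T)  # unclipped: the true gradient of softplus
    W = P + (params.c - 1.0) * (Y * P) - params.c * Y
    G_U = W @ V + params.lambda_l * U + params.alpha * (graph.laplacian_l @ U)
    G_V = W.T @ U + params.lambda_p * V + params.beta * (graph.laplacian_p @ V)
    return G_U, G_V


def build_graph(lnc_sim: SimilarityMatrix, prot_sim: SimilarityMatrix,
                params: NRLMFParams) -> NeighborGraph:
    """Convenience: K1-NN adjacencies and Laplacians for both sides."""
    A = build_neighbors(lnc_sim, params.K1)
    B = build_neighbors(prot_sim, params.K1)
    return build_laplacians(A, B)


def fit(Y: np.ndarray, lnc_sim: SimilarityMatrix, prot_sim: SimilarityMatrix,
        params: NRLMFParams | None = None,
        graph: NeighborGraph | None = None,
        return_history: bool = False):
    """Fit the factorization by full-gradient AdaGrad.

    Factors initialize from a seeded standard normal scaled by 1/sqrt(r).
    Each coordinate's step is learn_rate / (sqrt(accumulated squared
    gradient) + 1e-8).  The best-objective iterate seen is returned, so
    the final objective never exceeds the initial one.  Deterministic
    given ``params.seed``.

    Returns LatentFactors, or (LatentFactors, objective_history) with
    ``return_history=True``.
    """
    params = params or NRLMFParams()
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    params.check_shapes(m, n)
    if graph is None:
        graph = build_graph(lnc_sim, prot_sim, params)

    rng = np.random.default_rng(params.seed)
    U = rng.standard_normal((m, params.r)) / np.sqrt(params.r)
    V = rng.standard_normal((n, params.r)) / np.sqrt(params.r)
    factors = LatentFactors(U, V)

    acc_U = np.zeros_like(U)
    acc_V = np.zeros_like(V)
    history = [objective(factors, Y, graph, params)]
    best = (history[0], U.copy(), V.copy())
    for it in range(params.max_iter):
        G_U, G_V = gradients(factors, Y, graph, params)
        acc_U += G_U ** 2
        acc_V += G_V ** 2
        factors.U -= params.learn_rate * G_U / (np.sqrt(acc_U) + 1e-8)
        factors.V -= params.learn_rate * G_V / (np.sqrt(acc_V) + 1e-8)
        obj = objective(factors, Y, graph, params)
        if not np.isfinite(obj):
            raise DivergenceError(
                f"objective became non-finite at iteration {it + 1}; "
                "try a smaller learn_rate"
            )
        history.append(obj)
        if obj < best[0]:
            best = (obj, factors.U.copy(), factors.V.copy())
    logger.debug("nrlmf fit: objective %0.4f -> %0.4f over %d iterations",
                 history[0], best[0], params.max_iter)
    out = LatentFactors(best[1], best[2])
    return (out, history) if return_history else out


def _smooth_side(F: np.ndarray, positive: np.ndarray, sim: np.ndarray,
                 K2: int) -> np.ndarray:
    """Replace cold rows of F by weighted means of warm neighbors' rows."""
    pos_idx = np.nonzero(positive)[0]
    if pos_idx.size == 0:
        raise DataError("no entity has a known interaction; nothing to smooth from")
    out = F.copy()
    for i in np.nonzero(~positive)[0]:
        sims = sim[i, pos_idx]
        k = min(K2, pos_idx.size)
        top = np.argsort(-sims, kind="stable")[:k]
        nbr = pos_idx[top]
        w = sim[i, nbr]
        total = w.sum()
        if total <= 0:
            # no similarity signal at all: plain mean over the neighbors
            w = np.full(k, 1.0 / k)
        else:
            w = w / total
        out[i] = w @ F[nbr]
    return out


def smooth_and_score(factors: LatentFactors, Y: np.ndarray,
                     lnc_sim: SimilarityMatrix, prot_sim: SimilarityMatrix,
                     K2: int = 5, lnc_ids: list[str] | None = None,
                     prot_ids: list[str] | None = None) -> ScoreMatrix:
    """Cold-start smoothing followed by logistic scoring: the S_N matrix.

    LncRNAs with at least one training interaction keep their fitted
    vector; the rest get the similarity-weighted mean of the vectors of
    their K2 most similar lncRNAs among those with interactions (weights
    normalized to sum to 1).  Proteins are treated symmetrically.
    """
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    U = _smooth_side(factors.U, Y.sum(axis=1) > 0, lnc_sim.M, K2)
    V = _smooth_side(factors.V, Y.sum(axis=0) > 0, prot_sim.M, K2)
    S = np.clip(expit(U @ V.T), _P_EPS, 1.0 - _P_EPS)
    return ScoreMatrix(
        lnc_ids if lnc_ids is not None else [f"l{i}" for i in range(m)],
        prot_ids if prot_ids is not None else [f"p{j}" for j in range(n)],
        S, source="nrlmf",
    )


def score_matrix_nrlmf(ds: InteractionDataset, lnc_sim: SimilarityMatrix,
                       prot_sim: SimilarityMatrix,
                       params: NRLMFParams | None = None) -> ScoreMatrix:
    """Fit on the dataset and return the smoothed score matrix S_N."""
    params = params or NRLMFParams()
    lsim = lnc_sim.reorder(ds.lnc_ids)
    psim = prot_sim.reorder(ds.prot_ids)
    factors = fit(ds.Y, lsim, psim, params)
    return smooth_and_score(factors, ds.Y, lsim, psim, params.K2,
                            lnc_ids=list(ds.lnc_ids), prot_ids=list(ds.prot_ids))


def grid_search(ds: InteractionDataset, lnc_sim: SimilarityMatrix,
                prot_sim: SimilarityMatrix, grid: dict[str, list],
                score_fn, base: NRLMFParams | None = None):
    """Exhaustive hyperparameter search over a small grid.

    `grid` maps NRLMFParams field names (e.g. ``r``, ``c``, ``lambda_l``,
    ``alpha``) to candidate values; `score_fn(params) -> float` evaluates
    one setting (higher is better).  Returns (best_params, results)
    where results is a list of (params, score), in evaluation order.
    """
    base = base or NRLMFParams()
    names = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[k] for k in names)):
        params = replace(base, **dict(zip(names, combo)))
        results.append((params, float(score_fn(params))))
    best = max(results, key=lambda t: t[1])
    logger.info("grid search: best score %.4f at %s", best[1], best[0])
    return best[0], results
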