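"""Per-protein restart random walk over the lncRNA similarity graph.

For each protein the lncRNAs it is known to interact with form the
labeled set Q; all others are unlabeled (U).  A relevance matrix R
weights similarity edges by w_Q or w_U depending on whether the source
vertex is labeled, is row-normalized into a one-step transition matrix
L, and L is split into L_Q (labeled rows) and L_U (unlabeled rows).
Starting from the uniform distribution X over Q, the walker iterates

    S(t+1) = r_Q L_Q' S(t) + p_Q (1 - r_Q) X
           + r_U L_U' S(t) + p_U (1 - r_U) X

where p_Q = sum of S(t) over Q is recomputed every step and
p_U = 1 - p_Q: mass sitting on labeled vertices restarts with retention
r_Q, mass on unlabeled vertices with the smaller retention r_U.  The
iteration stops when the L1 change drops below `tol`; the steady state
of one walk is one column of the score matrix S_R.

Isolated vertices (no positive-similarity neighbor) retain their walk
mass through an implicit self-loop, the usual dangling-node convention,
so total probability is conserved exactly at every step.  Because w_Q and w_U scale whole rows of R they cancel in the row
normalization; the restart weights r_Q > r_U carry the labeled/unlabeled
asymmetry instead.

The edge set is the complete graph on positive-similarity pairs; an
optional k-nearest-neighbor sparsification keeps only each vertex's
top-k edges (symmetrized).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import InteractionDataset
from .ensemble import ScoreMatrix
from .errors import ConvergenceError, DataError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkParams:
    """Restart-walk parameters.

    r_Q, r_U : retention probabilities for labeled/unlabeled vertices,
        both in (0, 1) with r_Q > r_U.
    w_Q, w_U : relevance weights for labeled/unlabeled source rows, both
        in (0, 1) with w_Q > w_U (cancelled by row normalization; kept
        for fidelity to the model's construction).
    tol : L1 convergence tolerance.
    max_iter : iteration cap before a ConvergenceError.
    knn : optional neighbor count for edge sparsification (None = all
        positive-similarity edges).
    """

    r_Q: float = 0.8
    r_U: float = 0.3
    w_Q: float = 0.8
    w_U: float = 0.3
    tol: float = 1e-10
    max_iter: int = 5000
    knn: int | None = None

    def __post_init__(self):
        if not (0 < self.r_U < self.r_Q < 1):
            raise DataError("require 0 < r_U < r_Q < 1")
        if not (0 < self.w_U < self.w_Q < 1):
            raise DataError("require 0 < w_U < w_Q < 1")
        if self.tol <= 0:
            raise DataError("tol must be positive")
        if self.max_iter < 1:
            raise DataError("max_iter must be >= 1")


def _edge_mask(sim: np.ndarray, knn: int | None) -> np.ndarray:
    """Boolean adjacency: positive-similarity pairs, optionally kNN-pruned."""
    M = sim.shape[0]
    mask = sim > 0
    np.fill_diagonal(mask, False)
    if knn is not None:
        if not (1 <= knn < M):
            raise DataError(f"knn must be in [1, {M - 1})")
        keep = np.zeros_like(mask)
        masked = np.where(mask, sim, -np.inf)
        idx = np.argsort(-masked, axis=1)[:, :knn]
        rows = np.repeat(np.arange(M), knn)
        keep[rows, idx.ravel()] = True
        keep &= mask
        mask = keep | keep.T  # symmetrize: an edge kept by either endpoint
    return mask


def build_relevance(sim: SimilarityMatrix, labeled: np.ndarray,
                    params: WalkParams) -> np.ndarray:
    """Relevance matrix R: similarity weighted by the source's label status.

    ``R[i, j] = sim[i, j] * w_Q`` if vertex i is labeled and (i, j) is an
    edge, ``sim[i, j] * w_U`` if i is unlabeled and (i, j) is an edge,
    and 0 otherwise (no edge, or i == j).
    """
    labeled = np.asarray(labeled, dtype=int)
    M = len(sim.ids)
    if labeled.size == 0:
        raise DataError("labeled set is empty; the walk has no seeds")
    if labeled.min() < 0 or labeled.max() >= M:
        raise DataError("labeled indices out of range")
    mask = _edge_mask(sim.M, params.knn)
    w = np.full(M, params.w_U)
    w[labeled] = params.w_Q
    return np.where(mask, sim.M * w[:, None], 0.0)


def transition_split(R: np.ndarray, labeled: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize R into L and split by source label status.

    Rows with positive sum are divided by that sum; all-zero rows stay
    zero.  L_Q keeps the labeled rows of L (others zeroed), L_U keeps the
    unlabeled rows; L_Q + L_U == L exactly.
    """
    R = np.asarray(R, dtype=float)
    if (R < 0).any():
        raise DataError("relevance matrix must be nonnegative")
    rowsum = R.sum(axis=1)
    L = np.divide(R, rowsum[:, None], out=np.zeros_like(R),
                  where=rowsum[:, None] > 0)
    is_labeled = np.zeros(R.shape[0], dtype=bool)
    is_labeled[np.asarray(labeled, dtype=int)] = True
    L_Q = np.where(is_labeled[:, None], L, 0.0)
    L_U = np.where(~is_labeled[:, None], L, 0.0)
    return L_Q, L_U


def init_distribution(labeled: np.ndarray, M: int) -> np.ndarray:
    """Uniform start distribution over the labeled set: S_i(0) = 1/|Q|."""
    labeled = np.asarray(labeled, dtype=int)
    if labeled.size == 0:
        raise DataError("labeled set is empty")
    S0 = np.zeros(M)
    S0[labeled] = 1.0 / labeled.size
    return S0


def walk(L_Q: np.ndarray, L_U: np.ndarray, S0: np.ndarray,
         labeled: np.ndarray, params: WalkParams) -> tuple[np.ndarray, int]:
    """Iterate the restart walk to its steady state.

    Returns the converged probability vector and the number of
    iterations.  Raises ConvergenceError (with the last residual) if
    `max_iter` steps do not reach `tol` in L1.
    """
    is_labeled = np.zeros(len(S0), dtype=bool)
    is_labeled[np.asarray(labeled, dtype=int)] = True
    X = np.asarray(S0, dtype=float)
    S = X.copy()
    A = params.r_Q * L_Q.T + params.r_U * L_U.T
    # isolated vertices (all-zero rows of L) retain their walk mass via an
    # implicit self-loop, so total probability is conserved exactly
    isolated = (L_Q + L_U).sum(axis=1) == 0
    retain = np.where(isolated, np.where(is_labeled, params.r_Q, params.r_U), 0.0)
    A[np.arange(len(S0)), np.arange(len(S0))] += retain
    for t in range(1, params.max_iter + 1):
        p_Q = S[is_labeled].sum()
        p_U = 1.0 - p_Q
        restart = p_Q * (1.0 - params.r_Q) + p_U * (1.0 - params.r_U)
        S_next = A @ S + restart * X
        total = S_next.sum()
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(
                f"probability not conserved at iteration {t}: sum={total!r}"
            )
        residual = np.abs(S_next - S).sum()
        S = S_next
        if residual < params.tol:
            return S, t
    raise ConvergenceError(
        f"walk did not converge in {params.max_iter} iterations "
        f"(last L1 residual {residual:.3e})",
        residual=float(residual),
    )


def walk_for_protein(ds: InteractionDataset, lnc_sim: SimilarityMatrix,
                     j: int, params: WalkParams,
                     labeled: np.ndarray | None = None
                     ) -> tuple[np.ndarray, int]:
    """Run the full walk pipeline for one protein column.

    `labeled` overrides the labeled set (used by cross-validation folds);
    by default it is the set of lncRNAs with Y[:, j] == 1.
    """
    if labeled is None:
        labeled = np.nonzero(ds.Y[:, j])[0]
    labeled = np.asarray(labeled, dtype=int)
    if labeled.size == 0:
        raise DataError(
            f"protein {ds.prot_ids[j]!r} has no known lncRNA partners; "
            "the walk has no seeds"
        )
    R = build_relevance(lnc_sim, labeled, params)
    L_Q, L_U = transition_split(R, labeled)
    S0 = init_distribution(labeled, len(ds.lnc_ids))
    return walk(L_Q, L_U, S0, labeled, params)


def score_matrix_rw(ds: InteractionDataset, lnc_sim: SimilarityMatrix,
                    params: WalkParams | None = None) -> ScoreMatrix:
    """Assemble S_R: one restart walk per protein, steady states as columns.

    Each column is a probability distribution over lncRNAs (sums to 1
    when no vertex is isolated).  The similarity matrix must cover the
    dataset's lncRNA ids; it is reordered to match.
    """
    params = params or WalkParams()
    sim = lnc_sim.reorder(ds.lnc_ids)
    m, n = ds.shape
    S_R = np.zeros((m, n))
    iters = []
    for j in range(n):
        S_R[:, j], it = walk_for_protein(ds, sim, j, params)
        iters.append(it)
    logger.info("random walk: %d proteins, iterations min/median/max = %d/%d/%d",
                n, min(iters), int(np.median(iters)), max(iters))
    return ScoreMatrix(list(ds.lnc_ids), list(ds.prot_ids), S_R, source="rw")
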