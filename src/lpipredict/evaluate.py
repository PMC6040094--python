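"""Leave-one-out cross-validation and ranking/classification metrics.

Every experimentally known interaction is withheld in turn; the chosen
scoring arm (random walk, matrix factorization, or their average) is
retrained/rescored without it, and the withheld pair's score is recorded
as a positive.  All pairs absent from the original matrix are scored
once by the full-data model and pooled as negatives (per-fold negative
rescoring is available but N-fold costlier and leaves positives
unchanged).  AUC is the Mann-Whitney probability that a random positive
outscores a random negative (ties count half); AUPR is the step-wise
non-interpolated precision-recall area.  Binary metrics (ACC, SEN, PRE,
F1) are reported at a threshold, by default the one maximizing F1 on the
pooled scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .datasets import InteractionDataset
from .ensemble import integrate
from .errors import DataError
from .nrlmf import NRLMFParams, build_graph, fit, smooth_and_score
from .similarity import SimilarityMatrix
from .walk import WalkParams, score_matrix_rw, walk_for_protein

logger = logging.getLogger(__name__)

ARMS = ("rw", "nrlmf", "integrated")


@dataclass
class CVResult:
    """Pooled scores and labels from a cross-validation run.

    ``fold_ids[k]`` is the index of the held-out interaction that
    produced score k (-1 for negatives, which come from the full-data
    model).
    """

    scores: np.ndarray
    labels: np.ndarray
    fold_ids: np.ndarray = field(default=None)
    threshold: float | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise DataError("scores and labels must have the same length")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be 0 or 1")
        if self.fold_ids is None:
            self.fold_ids = np.full(self.scores.shape, -1, dtype=int)
        else:
            self.fold_ids = np.asarray(self.fold_ids, dtype=int)


def roc_auc(result: CVResult) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties half)."""
    if result.labels.min() == result.labels.max():
        raise DataError("AUC requires both classes")
    return float(roc_auc_score(result.labels, result.scores))


def aupr(result: CVResult) -> float:
    """Area under the precision-recall curve (step-wise estimator)."""
    if result.labels.sum() == 0:
        raise DataError("AUPR requires at least one positive")
    return float(average_precision_score(result.labels, result.scores))


def binary_metrics(result: CVResult, threshold: float) -> dict[str, float]:
    """Confusion-matrix metrics at ``score >= threshold``.

    Returns ACC, SEN (recall), PRE, F1 plus the raw counts.  PRE is
    reported as 0.0 with ``pre_defined=False`` when nothing is predicted
    positive.
    """
    if not np.isfinite(threshold):
        raise DataError("threshold must be finite")
    pred = result.scores >= threshold
    pos = result.labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else 0.0
    sen = tp / (tp + fn) if tp + fn else 0.0
    pre_defined = (tp + fp) > 0
    pre = tp / (tp + fp) if pre_defined else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {"ACC": acc, "SEN": sen, "PRE": pre, "F1": f1,
            "TP": tp, "FP": fp, "FN": fn, "TN": tn,
            "pre_defined": pre_defined, "threshold": float(threshold)}


def best_f1_threshold(result: CVResult) -> float:
    """Score threshold maximizing F1 over the pooled scores."""
    candidates = np.unique(result.scores)
    best_t, best_f1 = candidates[0], -1.0
    for t in candidates:
        f1 = binary_metrics(result, t)["F1"]
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return float(best_t)


def _nrlmf_scores(Y, lsim, psim, nrlmf_params, graph):
    factors = fit(Y, lsim, psim, nrlmf_params, graph=graph)
    return smooth_and_score(factors, Y, lsim, psim, nrlmf_params.K2).M


def loocv(ds: InteractionDataset, lnc_sim: SimilarityMatrix,
          prot_sim: SimilarityMatrix,
          walk_params: WalkParams | None = None,
          nrlmf_params: NRLMFParams | None = None,
          arm: str = "integrated",
          negatives: str = "full",
          nrlmf_refit_every: int = 1,
          normalize: bool = False) -> CVResult:
    """Leave-one-out cross-validation of one scoring arm.

    For each known pair (i, j), Y[i, j] is set to 0, the arm is
    retrained/rescored, and the pair's score becomes one positive.
    Negatives are the Y == 0 pairs of the original matrix, scored by the
    full-data model (``negatives="full"``, default) or once per fold and
    averaged (``negatives="per-fold"``).

    The random-walk arm only recomputes the affected protein's column
    per fold (the other columns are unchanged by construction).  The
    factorization arm refits per fold; ``nrlmf_refit_every=k`` refits
    only every k-th fold and reuses the latest factors otherwise -- an
    approximation for large runs, logged when active.

    Requires every entity to have degree >= 2 (run the dataset filter
    first), so no fold leaves a protein without labeled lncRNAs.
    """
    if arm not in ARMS:
        raise DataError(f"unknown arm {arm!r}; choose from {ARMS}")
    if negatives not in ("full", "per-fold"):
        raise DataError("negatives must be 'full' or 'per-fold'")
    walk_params = walk_params or WalkParams()
    nrlmf_params = nrlmf_params or NRLMFParams()
    Y = ds.Y
    row_deg, col_deg = Y.sum(axis=1), Y.sum(axis=0)
    if Y.size == 0 or (row_deg.min() < 2) or (col_deg.min() < 2):
        raise DataError(
            "LOOCV requires min degree >= 2 on both axes; filter the dataset first"
        )
    lsim = lnc_sim.reorder(ds.lnc_ids)
    psim = prot_sim.reorder(ds.prot_ids)
    use_rw = arm in ("rw", "integrated")
    use_nr = arm in ("nrlmf", "integrated")
    if nrlmf_refit_every > 1:
        logger.info("approximate LOOCV: refitting NRLMF every %d folds",
                    nrlmf_refit_every)

    graph = build_graph(lsim, psim, nrlmf_params) if use_nr else None
    S_R_full = score_matrix_rw(ds, lsim, walk_params).M if use_rw else None
    S_N_full = (_nrlmf_scores(Y, lsim, psim, nrlmf_params, graph)
                if use_nr else None)

    def combined(S_R, S_N):
        if arm == "rw":
            return S_R
        if arm == "nrlmf":
            return S_N
        if normalize:
            from .ensemble import _minmax_columns
            return (_minmax_columns(S_R) + _minmax_columns(S_N)) / 2.0
        return (S_R + S_N) / 2.0

    full_scores = combined(S_R_full, S_N_full)
    folds = list(zip(*np.nonzero(Y)))
    neg_mask = Y == 0
    neg_i, neg_j = np.nonzero(neg_mask)

    pos_scores = np.empty(len(folds))
    neg_accum = np.zeros(neg_i.shape[0]) if negatives == "per-fold" else None
    last_factors = None
    for f, (i, j) in enumerate(folds):
        Y_fold = Y.copy()
        Y_fold[i, j] = 0.0
        S_R_f = S_N_f = None
        if use_rw:
            labeled = np.nonzero(Y_fold[:, j])[0]
            col, _ = walk_for_protein(ds, lsim, j, walk_params, labeled=labeled)
            if negatives == "per-fold":
                S_R_f = S_R_full.copy()
                S_R_f[:, j] = col
            else:
                S_R_f = col  # only the affected column is needed
        if use_nr:
            if last_factors is None or f % nrlmf_refit_every == 0:
                last_factors = fit(Y_fold, lsim, psim, nrlmf_params, graph=graph)
            S_N_f = smooth_and_score(last_factors, Y_fold, lsim, psim,
                                     nrlmf_params.K2).M
        if negatives == "per-fold":
            S_f = combined(S_R_f, S_N_f)
            pos_scores[f] = S_f[i, j]
            neg_accum += S_f[neg_i, neg_j]
        else:
            rw_val = S_R_f[i] if use_rw else None
            nr_val = S_N_f[i, j] if use_nr else None
            if arm == "rw":
                pos_scores[f] = rw_val
            elif arm == "nrlmf":
                pos_scores[f] = nr_val
            elif normalize:
                col_r = S_R_full[:, j].copy()
                col_r[i] = rw_val  # normalize within the fold's own column
                col_r = np.where(col_r.max() > col_r.min(),
                                 (col_r - col_r.min()) / (col_r.max() - col_r.min() + 1e-300),
                                 0.0)
                col_n = S_N_f[:, j]
                col_n = np.where(col_n.max() > col_n.min(),
                                 (col_n - col_n.min()) / (col_n.max() - col_n.min() + 1e-300),
                                 0.0)
                pos_scores[f] = (col_r[i] + col_n[i]) / 2.0
            else:
                pos_scores[f] = (rw_val + nr_val) / 2.0

    if negatives == "per-fold":
        neg_scores = neg_accum / len(folds)
    else:
        neg_scores = full_scores[neg_i, neg_j]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(folds), dtype=int),
                             np.zeros(neg_scores.size, dtype=int)])
    fold_ids = np.concatenate([np.arange(len(folds)),
                               np.full(neg_scores.size, -1)])
    result = CVResult(scores, labels, fold_ids)
    result.threshold = best_f1_threshold(result)
    logger.info("LOOCV (%s): %d positives, %d negatives", arm, len(folds),
                neg_scores.size)
    return result


def evaluate_arms(ds, lnc_sim, prot_sim, walk_params=None, nrlmf_params=None,
                  arms=ARMS, **kw) -> dict[str, dict[str, float]]:
    """Run LOOCV for several arms and tabulate the headline metrics."""
    table = {}
    for arm in arms:
        res = loocv(ds, lnc_sim, prot_sim, walk_params, nrlmf_params,
                    arm=arm, **kw)
        metrics = binary_metrics(res, res.threshold)
        table[arm] = {
            "AUC": roc_auc(res), "AUPR": aupr(res),
            "ACC": metrics["ACC"], "PRE": metrics["PRE"],
            "SEN": metrics["SEN"], "F1": metrics["F1"],
            "threshold": res.threshold,
        }
    return table
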