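"""Independent reference implementations used only as test oracles.

Everything here is written as plainly as possible (explicit loops, no
vectorization) and stays independent of the code paths it checks.
"""

from __future__ import annotations

import numpy as np


def gotoh_local(a: str, b: str, score_fn, gap_open: float,
                gap_extend: float) -> float:
    """Textbook O(len^2) affine-gap local alignment (Gotoh).

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``;
    `score_fn(x, y)` gives the substitution score of a pair of letters.
    Returns the best local alignment score (>= 0; the empty alignment).
    """
    la, lb = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (moving along b)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def auc_pair_count(scores, labels) -> float:
    """Mann-Whitney AUC by explicit pairwise comparison, ties count half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_steps(scores, labels) -> float:
    """Step-wise (non-interpolated) PR area: sum of precision * recall
    increments walking down the score-sorted list."""
    order = sorted(range(len(scores)), key=lambda k: -scores[k])
    n_pos = sum(labels)
    tp = fp = 0
    prev_recall = 0.0
    area = 0.0
    # ties: process groups of equal score together
    k = 0
    while k < len(order):
        g = k
        while g < len(order) and scores[order[g]] == scores[order[k]]:
            tp += labels[order[g]]
            fp += 1 - labels[order[g]]
            g += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        k = g
    return area


def walk_longrun(L_Q, L_U, S0, labeled, r_Q, r_U, iters=10000):
    """Fixed point of the restart walk by plain long-run iteration."""
    M = len(S0)
    labeled = set(int(i) for i in labeled)
    S = [float(x) for x in S0]
    X = list(S)
    for _ in range(iters):
        p_Q = sum(S[i] for i in labeled)
        p_U = 1.0 - p_Q
        nxt = [0.0] * M
        for j in range(M):
            acc = p_Q * (1 - r_Q) * X[j] + p_U * (1 - r_U) * X[j]
            for i in range(M):
                acc += r_Q * L_Q[i][j] * S[i] + r_U * L_U[i][j] * S[i]
            nxt[j] = acc
        S = nxt
    return np.array(S)


def brute_filter(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed point of the degree >= 2 filter; returns kept row/col masks."""
    keep_r = np.ones(Y.shape[0], dtype=bool)
    keep_c = np.ones(Y.shape[1], dtype=bool)
    changed = True
    while changed:
        changed = False
        sub = Y[np.ix_(keep_r, keep_c)]
        rows = np.nonzero(keep_r)[0]
        cols = np.nonzero(keep_c)[0]
        for k, i in enumerate(rows):
            if sub[k].sum() < 2:
                keep_r[i] = False
                changed = True
        sub = Y[np.ix_(keep_r, keep_c)]
        cols = np.nonzero(keep_c)[0]
        for k, j in enumerate(cols):
            if sub[:, k].sum() < 2:
                keep_c[j] = False
                changed = True
    return keep_r, keep_c


def loglik_split_form(Y, P, c) -> float:
    """Log of the split-product weighted likelihood: positives raised to
    the power c, unknowns to the power 1."""
    total = 0.0
    m, n = Y.shape
    for i in range(m):
        for j in range(n):
            term = Y[i, j] * np.log(P[i, j]) + (1 - Y[i, j]) * np.log(1 - P[i, j])
            total += (c if Y[i, j] == 1 else 1.0) * term
    return total


def loglik_compact_form(Y, P, c) -> float:
    """Log of the compact form: prod p^(c y) (1-p)^(1-y)."""
    total = 0.0
    m, n = Y.shape
    for i in range(m):
        for j in range(n):
            total += c * Y[i, j] * np.log(P[i, j]) + (1 - Y[i, j]) * np.log(1 - P[i, j])
    return total


def naive_loocv(ds, lsim, psim, arm, walk_params, nrlmf_params):
    """Rebuild the full model from scratch for every held-out pair."""
    from lpipredict.datasets import InteractionDataset
    from lpipredict.nrlmf import build_graph, fit, smooth_and_score
    from lpipredict.walk import score_matrix_rw

    Y = ds.Y
    pos = list(zip(*np.nonzero(Y)))
    scores, labels = [], []

    def score_full(Yx):
        dsx = InteractionDataset(list(ds.lnc_ids), list(ds.prot_ids), Yx.copy())
        S_R = score_matrix_rw(dsx, lsim, walk_params).M
        graph = build_graph(lsim, psim, nrlmf_params)
        factors = fit(Yx, lsim, psim, nrlmf_params, graph=graph)
        S_N = smooth_and_score(factors, Yx, lsim, psim, nrlmf_params.K2).M
        return {"rw": S_R, "nrlmf": S_N, "integrated": (S_R + S_N) / 2}[arm]

    full = score_full(Y)
    for i, j in pos:
        Yf = Y.copy()
        Yf[i, j] = 0.0
        scores.append(score_full(Yf)[i, j])
        labels.append(1)
    for i, j in zip(*np.nonzero(Y == 0)):
        scores.append(full[i, j])
        labels.append(0)
    return np.array(scores), np.array(labels)
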