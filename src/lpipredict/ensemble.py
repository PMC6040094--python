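"""Score matrices and the integration of the two predictors.

The final prediction averages the random-walk score matrix S_R and the
matrix-factorization score matrix S_N elementwise: S = (S_R + S_N) / 2.
The two live on different scales (walk columns are probability
distributions summing to 1; factorization entries are logistic
probabilities), and the default integrates the raw scales.  An optional
column-wise min-max normalization of each input before averaging is
available for score distributions whose scales differ too much for a
global ranking to be meaningful; within a single protein's column,
rankings are unaffected by that choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

SOURCES = ("rw", "nrlmf", "integrated")


@dataclass
class ScoreMatrix:
    """Real-valued lncRNA x protein association scores."""

    lnc_ids: list[str]
    prot_ids: list[str]
    M: np.ndarray = field(repr=False)
    source: str = "integrated"

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.shape != (len(self.lnc_ids), len(self.prot_ids)):
            raise DataError(
                f"score matrix shape {self.M.shape} does not match id lists"
            )
        if self.source not in SOURCES:
            raise DataError(f"unknown score source {self.source!r}")
        if self.M.size and not np.isfinite(self.M).all():
            raise DataError("score matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.lnc_ids, columns=self.prot_ids)


def _minmax_columns(M: np.ndarray) -> np.ndarray:
    lo = M.min(axis=0, keepdims=True)
    hi = M.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.divide(M - lo, span, out=np.zeros_like(M), where=span > 0)
    return out


def integrate(S_R: ScoreMatrix, S_N: ScoreMatrix,
              normalize: bool = False) -> ScoreMatrix:
    """Average two score matrices into the integrated prediction.

    With ``normalize=True`` each input is first column-wise min-max
    scaled to [0, 1] (constant columns map to 0).  Axes and identifier
    order must agree exactly.
    """
    if S_R.lnc_ids != S_N.lnc_ids or S_R.prot_ids != S_N.prot_ids:
        bad_l = [x for x in S_R.lnc_ids if x not in set(S_N.lnc_ids)]
        bad_p = [x for x in S_R.prot_ids if x not in set(S_N.prot_ids)]
        raise DataError(
            "score matrices have mismatched axes; e.g. lncRNAs "
            f"{bad_l[:3]} / proteins {bad_p[:3]} (or ordering differs)"
        )
    A, B = S_R.M, S_N.M
    if normalize:
        A, B = _minmax_columns(A), _minmax_columns(B)
    return ScoreMatrix(list(S_R.lnc_ids), list(S_R.prot_ids),
                       (A + B) / 2.0, source="integrated")


def top_pairs(scores: ScoreMatrix, k: int = 10,
              exclude: np.ndarray | None = None) -> pd.DataFrame:
    """Rank candidate pairs by score, highest first.

    `exclude` is an optional boolean/binary matrix of pairs to omit
    (typically the known interactions, so only novel candidates are
    ranked).  Returns a DataFrame with lncRNA, protein, score, rank.
    """
    M = scores.M
    mask = np.ones_like(M, dtype=bool)
    if exclude is not None:
        mask &= ~(np.asarray(exclude) > 0)
    ii, jj = np.nonzero(mask)
    order = np.argsort(-M[ii, jj], kind="stable")[:k]
    rows = [
        {"lncrna": scores.lnc_ids[ii[o]], "protein": scores.prot_ids[jj[o]],
         "score": M[ii[o], jj[o]], "rank": r + 1}
        for r, o in enumerate(order)
    ]
    return pd.DataFrame(rows, columns=["lncrna", "protein", "score", "rank"])
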