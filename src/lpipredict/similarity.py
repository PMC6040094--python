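"""Normalized Smith-Waterman sequence similarity matrices.

Pairwise similarity between two sequences is the optimal local-alignment
(Smith-Waterman) score normalized by the larger of the two self-alignment
scores:

    S(a, b) = sw(a, b) / max(sw(a, a), sw(b, b))

which yields a symmetric matrix with unit diagonal and entries in [0, 1]
for any scoring scheme under which a sequence aligns best to itself.
Alignment uses affine gap penalties: a gap of length k costs
``gap_open + (k - 1) * gap_extend``.

The alignment engine is Biopython's ``PairwiseAligner`` (C core); the
scoring parameters below are package defaults in the style of EMBOSS
water, since the choice of substitution scores is an implementation
decision and is echoed into output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .datasets import SequenceRecord
from .errors import AlphabetError, DataError, DegenerateSequenceError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution and affine-gap parameters for local alignment.

    For ``kind="lncrna"`` substitution is match/mismatch over nucleotide
    letters; for ``kind="protein"`` a named substitution matrix
    (e.g. BLOSUM62) is used and match/mismatch are ignored.
    """

    kind: str
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.kind not in ("lncrna", "protein"):
            raise DataError(f"unknown scoring kind {self.kind!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise DataError("require gap_open >= gap_extend >= 0")
        if self.kind == "lncrna" and self.match <= 0:
            raise DataError("nucleotide match score must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner(mode="local")
        if self.kind == "protein":
            a.substitution_matrix = substitution_matrices.load(
                self.matrix_name or "BLOSUM62"
            )
        else:
            a.match_score = self.match
            a.mismatch_score = self.mismatch
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a

    def metadata(self) -> dict:
        d = {"kind": self.kind, "gap_open": self.gap_open,
             "gap_extend": self.gap_extend}
        if self.kind == "protein":
            d["matrix"] = self.matrix_name or "BLOSUM62"
        else:
            d.update(match=self.match, mismatch=self.mismatch)
        return d


def nucleotide_scoring(**kw) -> AlignmentScoring:
    """Default nucleotide scoring: match +5 / mismatch -4, gap 10 / 0.5."""
    return AlignmentScoring(kind="lncrna", **kw)


def protein_scoring(**kw) -> AlignmentScoring:
    """Default protein scoring: BLOSUM62, gap 10 / 0.5."""
    return AlignmentScoring(kind="protein", **kw)


def _prepare(rec: SequenceRecord, scoring: AlignmentScoring) -> str:
    if rec.kind != scoring.kind:
        raise AlphabetError(
            f"sequence {rec.id!r} has kind {rec.kind!r} but the scoring "
            f"scheme is for {scoring.kind!r}"
        )
    if not rec.seq:
        raise DataError(f"sequence {rec.id!r} is empty")
    seq = rec.seq
    if scoring.kind == "lncrna":
        seq = seq.replace("U", "T")  # RNA and DNA alphabets score identically
    return seq


def sw_score(a: SequenceRecord, b: SequenceRecord,
             scoring: AlignmentScoring) -> float:
    """Optimal Smith-Waterman local-alignment score of two sequences.

    Symmetric in its arguments and >= 0 (the empty alignment scores 0).
    """
    sa, sb = _prepare(a, scoring), _prepare(b, scoring)
    return float(scoring.aligner().score(sa, sb))


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over ordered identifiers.

    Invariants: symmetric, unit diagonal, entries in [0, 1].
    """

    ids: list[str]
    M: np.ndarray
    kind: str

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        k = len(self.ids)
        if self.M.shape != (k, k):
            raise DataError(f"similarity matrix shape {self.M.shape} != ({k},{k})")
        if len(set(self.ids)) != k:
            raise DataError("duplicate identifiers in similarity matrix")
        if not np.allclose(self.M, self.M.T, atol=1e-8):
            raise DataError("similarity matrix is not symmetric")
        if self.M.size and (self.M.min() < -1e-12 or self.M.max() > 1 + 1e-12):
            raise DataError("similarity entries outside [0, 1]")

    def reorder(self, ids: list[str]) -> "SimilarityMatrix":
        """Return the submatrix over `ids`, in that order."""
        index = {x: i for i, x in enumerate(self.ids)}
        missing = [x for x in ids if x not in index]
        if missing:
            raise DataError(f"ids missing from similarity matrix: {missing[:5]}")
        idx = np.array([index[x] for x in ids])
        return SimilarityMatrix(list(ids), self.M[np.ix_(idx, idx)], self.kind)


def similarity_matrix(seqs: list[SequenceRecord],
                      scoring: AlignmentScoring) -> SimilarityMatrix:
    """All-pairs normalized Smith-Waterman similarity.

    ``M[i, j] = sw(i, j) / max(sw(i, i), sw(j, j))``, clamped to [0, 1]
    (clamping can only trigger for exotic scoring schemes where a cross
    score exceeds a self score; any clamp is logged).  Diagonal is 1.

    Raises
    ------
    DegenerateSequenceError
        If any sequence has self-alignment score 0.
    """
    if len(seqs) < 2:
        raise DataError("need at least 2 sequences")
    ids = [r.id for r in seqs]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sequence identifiers")
    k = len(seqs)
    aligner = scoring.aligner()
    prepared = [_prepare(r, scoring) for r in seqs]
    self_scores = np.array([float(aligner.score(s, s)) for s in prepared])
    zero = np.nonzero(self_scores <= 0)[0]
    if zero.size:
        raise DegenerateSequenceError(
            f"sequences with zero self-alignment score: "
            f"{[ids[i] for i in zero[:5]]}"
        )
    M = np.eye(k)
    clamped = 0
    for i in range(k):
        for j in range(i + 1, k):
            s = float(aligner.score(prepared[i], prepared[j]))
            v = s / max(self_scores[i], self_scores[j])
            if v < 0.0 or v > 1.0:
                clamped += 1
                v = min(max(v, 0.0), 1.0)
            M[i, j] = M[j, i] = v
    if clamped:
        logger.warning("clamped %d similarity entries into [0, 1]", clamped)
    return SimilarityMatrix(ids, M, scoring.kind)


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV (header row, id-labeled rows).

    Values are written at 10 significant digits, enough to round-trip
    through :func:`read_similarity` losslessly at that precision.
    """
    df = pd.DataFrame(sim.M, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="id")


def read_similarity(path: str | Path, kind: str) -> SimilarityMatrix:
    """Read a square similarity matrix written by :func:`write_similarity`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(x) for x in df.index]
    if [str(c) for c in df.columns] != ids:
        raise DataError(f"{path}: row and column identifiers disagree")
    M = df.to_numpy(dtype=float)
    M = (M + M.T) / 2.0  # absorb last-digit asymmetry from text round-trip
    return SimilarityMatrix(ids, M, kind)
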