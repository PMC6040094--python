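"""Interaction edge lists, sequence collections, and the degree filter.

The interaction data is a sparse binary bipartite matrix ``Y`` (lncRNAs x
proteins) built from a two-column edge list.  Identifier order is
first-appearance order in the file and fixes the row/column order of every
downstream matrix.  Before modeling, entities without a sequence record
are dropped, and lncRNAs or proteins with a single interaction are removed
(low-information, likely-noise pairs); removal cascades to a fixed point
by default so the "degree >= 2" property holds as an invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlphabetError, DataError, ParseError

logger = logging.getLogger(__name__)

# IUPAC one-letter codes (ambiguity codes included); U is accepted for RNA.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


@dataclass(frozen=True)
class SequenceRecord:
    """A named biological sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a collection.
    seq : str
        Upper-case sequence over the alphabet of `kind`.
    kind : {"lncrna", "protein"}
    """

    id: str
    seq: str
    kind: str

    def __post_init__(self):
        if not self.id:
            raise DataError("sequence record with empty identifier")
        if not self.seq:
            raise DataError(f"sequence {self.id!r} is empty")
        if self.kind not in ("lncrna", "protein"):
            raise DataError(f"unknown sequence kind {self.kind!r}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "lncrna" else PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.kind} alphabet"
            )


def make_record(id: str, seq: str, kind: str) -> SequenceRecord:
    """Build a record, trimming whitespace and upper-casing the sequence."""
    return SequenceRecord(id=id.strip(), seq=seq.strip().upper(), kind=kind)


@dataclass
class InteractionDataset:
    """Binary adjacency matrix over ordered identifier lists.

    ``Y[i, j] == 1`` iff lncRNA ``lnc_ids[i]`` interacts with protein
    ``prot_ids[j]``.
    """

    lnc_ids: list[str]
    prot_ids: list[str]
    Y: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        if self.Y.shape != (len(self.lnc_ids), len(self.prot_ids)):
            raise DataError(
                f"Y shape {self.Y.shape} does not match id lists "
                f"({len(self.lnc_ids)} x {len(self.prot_ids)})"
            )
        if self.Y.size and not np.isin(self.Y, (0, 1)).all():
            raise DataError("Y entries must be exactly 0 or 1")
        self.Y = self.Y.astype(np.float64)
        for name, ids in (("lncRNA", self.lnc_ids), ("protein", self.prot_ids)):
            if len(set(ids)) != len(ids):
                raise DataError(f"duplicate {name} identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Y.shape

    @property
    def n_interactions(self) -> int:
        return int(self.Y.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known interactions as (lncRNA id, protein id) tuples."""
        return [
            (self.lnc_ids[i], self.prot_ids[j]) for i, j in zip(*np.nonzero(self.Y))
        ]


def _detect_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    raise DataError("could not detect delimiter (expected tab or comma)")


def read_interactions(path: str | Path) -> InteractionDataset:
    """Read a two-column lncRNA/protein edge list (TSV or CSV).

    The delimiter is auto-detected from the first non-blank line; a header
    row is detected by checking whether its fields reappear in the body.
    Duplicate pairs collapse to a single 1.  Identifier order is
    first-appearance order.

    Raises
    ------
    ParseError
        If a line does not have exactly two fields.
    DataError
        If the file is empty or contains no pairs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows: list[tuple[int, str, str]] = []
    delim = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if delim is None:
            delim = _detect_delimiter(line)
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != 2 or not all(fields):
            raise ParseError(path, lineno, f"expected 2 fields, got {len(fields)}")
        rows.append((lineno, fields[0], fields[1]))
    if not rows:
        raise DataError(f"{path}: empty interaction file")
    # Header heuristic: drop the first row iff neither of its fields recurs
    # anywhere in the body (a real id recurs or at least could; a header
    # like "lncRNA<tab>protein" never matches body ids).
    if len(rows) > 1:
        body_ids = {f for _, a, b in rows[1:] for f in (a, b)}
        if rows[0][1] not in body_ids and rows[0][2] not in body_ids:
            first_pair = (rows[0][1], rows[0][2])
            body_pairs = {(a, b) for _, a, b in rows[1:]}
            if first_pair not in body_pairs:
                logger.debug("treating first line as header: %s", first_pair)
                rows = rows[1:]

    lnc_ids: list[str] = []
    prot_ids: list[str] = []
    lnc_index: dict[str, int] = {}
    prot_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    for _, lnc, prot in rows:
        if lnc not in lnc_index:
            lnc_index[lnc] = len(lnc_ids)
            lnc_ids.append(lnc)
        if prot not in prot_index:
            prot_index[prot] = len(prot_ids)
            prot_ids.append(prot)
        pairs.add((lnc_index[lnc], prot_index[prot]))
    Y = np.zeros((len(lnc_ids), len(prot_ids)))
    for i, j in pairs:
        Y[i, j] = 1.0
    ds = InteractionDataset(lnc_ids, prot_ids, Y)
    logger.info(
        "read %d interactions over %d lncRNAs x %d proteins from %s",
        ds.n_interactions, *ds.shape, path,
    )
    return ds


def write_interactions(ds: InteractionDataset, path: str | Path) -> None:
    """Write the dataset back out as a two-column TSV edge list."""
    with open(path, "w") as fh:
        for lnc, prot in ds.pairs():
            fh.write(f"{lnc}\t{prot}\n")


def read_fasta(path: str | Path, kind: str) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    The identifier is the first whitespace-delimited token of the header.
    Sequences are upper-cased on load.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DataError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(make_record(rec.id, str(rec.seq), kind))
    if not records:
        raise DataError(f"{path}: no FASTA records found")
    return records


def _subset(ds: InteractionDataset, keep_rows: np.ndarray, keep_cols: np.ndarray
            ) -> InteractionDataset:
    return InteractionDataset(
        [x for x, k in zip(ds.lnc_ids, keep_rows) if k],
        [x for x, k in zip(ds.prot_ids, keep_cols) if k],
        ds.Y[np.ix_(keep_rows, keep_cols)],
    )


def filter_dataset(
    ds: InteractionDataset,
    lnc_seqs: Iterable[SequenceRecord] | None = None,
    prot_seqs: Iterable[SequenceRecord] | None = None,
    cascade: bool = True,
) -> InteractionDataset:
    """Apply the sequence-availability and minimum-degree filters.

    First removes any lncRNA or protein without a sequence record (when a
    sequence collection is given; ``None`` skips that side's check), then
    removes lncRNAs interacting with a single protein and proteins
    interacting with a single lncRNA.  With ``cascade=True`` (default) the
    degree filter repeats to a fixed point, so every surviving entity has
    degree >= 2; ``cascade=False`` performs one sweep only.

    Identifier order is preserved; the result may be empty.
    """
    keep_r = np.ones(len(ds.lnc_ids), dtype=bool)
    keep_c = np.ones(len(ds.prot_ids), dtype=bool)
    if lnc_seqs is not None:
        have = {r.id for r in lnc_seqs}
        keep_r = np.array([x in have for x in ds.lnc_ids], dtype=bool)
    if prot_seqs is not None:
        have = {r.id for r in prot_seqs}
        keep_c = np.array([x in have for x in ds.prot_ids], dtype=bool)
    out = _subset(ds, keep_r, keep_c)

    while True:
        row_deg = out.Y.sum(axis=1)
        col_deg = out.Y.sum(axis=0)
        keep_r = row_deg >= 2
        keep_c = col_deg >= 2
        if keep_r.all() and keep_c.all():
            break
        out = _subset(out, keep_r, keep_c)
        if not cascade:
            break
        if out.Y.size == 0:
            break
    if out.Y.size == 0:
        # no interaction can survive once either axis empties
        out = InteractionDataset([], [], np.zeros((0, 0)))
    logger.info(
        "filter: %dx%d (%d edges) -> %dx%d (%d edges)",
        *ds.shape, ds.n_interactions, *out.shape, out.n_interactions,
    )
    return out
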