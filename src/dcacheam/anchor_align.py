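"""Sequence I/O, pairwise anchoring and reference-anchored position maps.

Motif positions are defined on a reference protein (PctD numbering for the
amine motif, PctA numbering for the amino-acid motif).  To evaluate a motif
on an arbitrary query the reference position must be carried through an
alignment to the query row; this module builds that mapping either from a
pre-computed multiple sequence alignment or from a self-contained global
pairwise alignment of query against reference.

Coordinate conventions: reference positions are 1-based (residue numbering,
e.g. W155); alignment columns are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = set(AMINO_ACIDS) | {"X"}
GAP = "-"


class FastaParseError(ValueError):
    """Raised when a FASTA/Stockholm file cannot be parsed or violates invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: accession-like id, free-text description, residues.

    Residues are upper-case letters from the 20-standard + 'X' alphabet.
    Aligned rows (which may contain '-') live in :class:`Alignment`, not here.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRow:
    """A row of an alignment; residues may contain '-' gaps."""

    id: str
    residues: str
    description: str = ""

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(
            self.id, self.residues.replace(GAP, ""), self.description
        )


@dataclass
class Alignment:
    """A rectangular alignment with a designated reference (anchor) row."""

    rows: list[AlignedRow]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        n = len(self.rows[0].residues)
        for r in self.rows:
            if len(r.residues) != n:
                raise ValueError(
                    f"alignment not rectangular: row {r.id!r} has length "
                    f"{len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        if self.reference_id not in ids:
            raise ValueError(f"reference id {self.reference_id!r} not among rows")
        self._by_id = {r.id: r for r in self.rows}

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> AlignedRow:
        try:
            return self._by_id[row_id]
        except KeyError:
            raise KeyError(row_id) from None

    @property
    def reference(self) -> AlignedRow:
        return self.row(self.reference_id)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for global pairwise anchoring.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the opening
    residue carries the open penalty).  Penalties are stored positive.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    def score_pair(self, a: str, b: str) -> float:
        # 'X' is evidence-free: scores 0 against everything.
        if a == "X" or b == "X":
            return 0.0
        return float(self.matrix()[a, b])


# ---------------------------------------------------------------------------
# FASTA / Stockholm I/O


def _records_from_seqio(seqio_records, path) -> list[tuple[str, str, str]]:
    out = []
    seen: set[str] = set()
    for rec in seqio_records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper(), rec.description))
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read plain (ungapped) FASTA into SequenceRecords.

    Raises :class:`FastaParseError` on duplicate ids or malformed entries.
    """
    path = Path(path)
    triples = _records_from_seqio(SeqIO.parse(path, "fasta"), path)
    if not triples:
        raise FastaParseError(f"{path}: no FASTA records found")
    records = []
    for i, (rid, seq, desc) in enumerate(triples, 1):
        try:
            records.append(SequenceRecord(rid, seq, desc))
        except ValueError as exc:
            raise FastaParseError(f"{path}: record {i} ({rid!r}): {exc}") from exc
    return records


def write_fasta(records: Sequence[SequenceRecord | AlignedRow], path: str | Path) -> None:
    if not records:
        raise ValueError("refusing to write empty FASTA")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_alignment_fasta(path: str | Path, reference_id: str) -> Alignment:
    """Read aligned FASTA ('-' gaps) into an :class:`Alignment`."""
    path = Path(path)
    triples = _records_from_seqio(SeqIO.parse(path, "fasta"), path)
    if not triples:
        raise FastaParseError(f"{path}: no FASTA records found")
    rows = [AlignedRow(rid, seq, desc) for rid, seq, desc in triples]
    return Alignment(rows, reference_id)


def read_stockholm(path: str | Path, reference_id: str) -> Alignment:
    """Read a Stockholm alignment (sequence lines only; #=GC and other
    annotation lines are skipped) into an :class:`Alignment`.

    '.' gaps are normalized to '-'.
    """
    msa = AlignIO.read(str(path), "stockholm")
    rows = [
        AlignedRow(rec.id, str(rec.seq).upper().replace(".", GAP), rec.description)
        for rec in msa
    ]
    return Alignment(rows, reference_id)


# ---------------------------------------------------------------------------
# Global pairwise alignment (Gotoh affine-gap DP)

# Deterministic tie-break on equal scores, in traceback from the end:
# diagonal (match/mismatch) > gap in query (reference residue over '-')
# > gap in reference.

_NEG = -1e30


def global_align(
    query: SequenceRecord, reference: SequenceRecord, params: AlignParams | None = None
) -> Alignment:
    """Needleman–Wunsch global alignment with affine gaps.

    Returns a two-row :class:`Alignment`, reference row first, whose score is
    maximal under ``params``.  Ties are broken deterministically (see module
    comment), so equal inputs always yield byte-identical alignments.
    """
    params = params or AlignParams()
    a = reference.residues  # rows of DP
    b = query.residues
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    mat = params.matrix()

    # integer-encode against a dense score table; 'X' (code 20) scores 0
    code = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    code["X"] = 20
    S = np.zeros((21, 21))
    for x in AMINO_ACIDS:
        for y in AMINO_ACIDS:
            S[code[x], code[y]] = float(mat[x, y])
    ai = np.array([code[ch] for ch in a])
    bi = np.array([code[ch] for ch in b])

    def sub(x: str, y: str) -> float:
        return float(S[code[x], code[y]])

    # M: a[i] aligned to b[j]; Ix: gap in query (a consumed); Iy: gap in ref.
    # Rows are filled vectorized; the within-row Iy recurrence
    # Iy[i,j] = max(M[i,j-1]-go, Ix[i,j-1]-go, Iy[i,j-1]-ge) collapses to a
    # running maximum of (max(M,Ix)[i,k] - go + ge*k).
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    Ix[1:, 0] = -go - np.arange(n) * ge
    Iy[0, 1:] = -go - np.arange(m) * ge
    col = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1, :-1], Ix[i - 1, :-1]), Iy[i - 1, :-1])
        M[i, 1:] = prev_best + S[ai[i - 1], bi]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge), Iy[i - 1, 1:] - go
        )
        entry = np.maximum(M[i, :], Ix[i, :]) - go + ge * col
        Iy[i, 1:] = np.maximum.accumulate(entry)[:-1] - ge * (col[1:] - 1)

    # Traceback with the stated preference order.
    i, j = n, m
    finals = [("M", M[n, m]), ("Ix", Ix[n, m]), ("Iy", Iy[n, m])]
    best = max(v for _, v in finals)
    state = next(k for k, v in finals if v == best)
    ref_out: list[str] = []
    qry_out: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            ref_out.append(a[i - 1])
            qry_out.append(b[j - 1])
            s = sub(a[i - 1], b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for cand in ("M", "Ix", "Iy"):
                if {"M": M, "Ix": Ix, "Iy": Iy}[cand][i, j] == target:
                    state = cand
                    break
        elif state == "Ix":  # gap in query
            ref_out.append(a[i - 1])
            qry_out.append(GAP)
            val = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - go == val:
                state = "M"
            elif Ix[i, j] - ge == val:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy: gap in reference
            ref_out.append(GAP)
            qry_out.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] - go == val:
                state = "M"
            elif Iy[i, j] - ge == val:
                state = "Iy"
            else:
                state = "Ix"
    ref_row = AlignedRow(reference.id, "".join(reversed(ref_out)), reference.description)
    qry_row = AlignedRow(query.id, "".join(reversed(qry_out)), query.description)
    return Alignment([ref_row, qry_row], reference_id=reference.id)


def alignment_score(alignment: Alignment, params: AlignParams | None = None) -> float:
    """Recompute the affine-gap score of an alignment column-by-column."""
    params = params or AlignParams()
    if alignment.n_rows != 2:
        raise ValueError("score defined for pairwise alignments")
    a = alignment.rows[0].residues
    b = alignment.rows[1].residues
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == GAP and y == GAP:
            raise ValueError("all-gap column in pairwise alignment")
        if x == GAP:
            score -= params.gap_extend if in_gap_a else params.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score -= params.gap_extend if in_gap_b else params.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += params.score_pair(x, y)
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# Position maps


@dataclass
class PositionMap:
    """Maps 1-based reference positions to alignment columns and query residues."""

    alignment: Alignment
    entries: list[tuple[int, int]]  # (reference_position, column), both increasing

    def __post_init__(self) -> None:
        pos = [p for p, _ in self.entries]
        col = [c for _, c in self.entries]
        if pos != sorted(set(pos)) or col != sorted(set(col)):
            raise ValueError("position map entries must be strictly increasing")

    @property
    def positions(self) -> list[int]:
        return [p for p, _ in self.entries]

    def column_of(self, reference_position: int) -> int:
        for p, c in self.entries:
            if p == reference_position:
                return c
        raise KeyError(f"reference position {reference_position} not mapped")

    def residue(self, query_id: str, reference_position: int) -> str:
        """Query residue at a reference position; '-' when the query is gapped."""
        return self.alignment.row(query_id).residues[self.column_of(reference_position)]

    def to_table(self) -> list[dict]:
        rows = []
        for p, c in self.entries:
            for r in self.alignment.rows:
                rows.append(
                    {
                        "reference_position": p,
                        "column_index": c,
                        "query_id": r.id,
                        "residue": r.residues[c],
                    }
                )
        return rows

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reference_position\tcolumn_index\tquery_id\tresidue\n")
            for row in self.to_table():
                fh.write(
                    f"{row['reference_position']}\t{row['column_index']}\t"
                    f"{row['query_id']}\t{row['residue']}\n"
                )


def map_positions(alignment: Alignment, positions: Iterable[int]) -> PositionMap:
    """Locate 1-based reference positions in alignment columns.

    The reference row is scanned once; its k-th non-gap character sits at the
    column mapped to reference position k.
    """
    positions = sorted(set(int(p) for p in positions))
    if positions and positions[0] < 1:
        raise ValueError("reference positions are 1-based (>= 1)")
    ref = alignment.reference.residues
    ungapped_len = sum(1 for ch in ref if ch != GAP)
    too_big = [p for p in positions if p > ungapped_len]
    if too_big:
        raise ValueError(
            f"positions {too_big} exceed ungapped reference length {ungapped_len}"
        )
    wanted = set(positions)
    entries = []
    k = 0
    for j, ch in enumerate(ref):
        if ch != GAP:
            k += 1
            if k in wanted:
                entries.append((k, j))
    return PositionMap(alignment, entries)


# ---------------------------------------------------------------------------
# Gap-based column trimming


def trim_alignment(
    alignment: Alignment,
    gap_fraction: float = 0.10,
    min_keep_fraction: float = 0.60,
) -> Alignment:
    """Remove columns gapped in >= ``gap_fraction`` of the rows, unless that
    would leave fewer than ``min_keep_fraction`` of the columns; in that case
    keep the ceil(min_keep_fraction * n) columns with the fewest gaps
    (ties to the lower column index), original order preserved.
    """
    n_cols = alignment.n_columns
    n_rows = alignment.n_rows
    gap_counts = [
        sum(1 for r in alignment.rows if r.residues[j] == GAP) for j in range(n_cols)
    ]
    keep = [j for j in range(n_cols) if gap_counts[j] / n_rows < gap_fraction]
    min_keep = int(np.ceil(min_keep_fraction * n_cols))
    if len(keep) < min_keep:
        # fallback: rank columns by gap count, ties to lower index
        ranked = sorted(range(n_cols), key=lambda j: (gap_counts[j], j))
        keep = sorted(ranked[:min_keep])
    rows = [
        AlignedRow(r.id, "".join(r.residues[j] for j in keep), r.description)
        for r in alignment.rows
    ]
    return Alignment(rows, alignment.reference_id)
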