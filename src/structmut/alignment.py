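"""Multiple-sequence-alignment parsing, per-column conservation and motif boxes.

Conservation here is deliberately simple: the per-column score is the fraction
of all sequences (gaps included in the denominator) carrying the single most
frequent non-gap residue, with alphabetical tie-breaking.  Motif boxes are
maximal runs of high-scoring columns, tolerating a bounded number of
below-threshold columns inside a run.  All residue and column indices on the
public surface are 1-based, matching mutation nomenclature such as V310M.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


class AlignmentParseError(ValueError):
    pass


@dataclass
class AlignedSequenceSet:
    """A gapped protein alignment: ordered ids and equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.rows:
            width = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise ValueError(
                        f"ragged alignment: {sid} has length {len(row)}, expected {width}"
                    )

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no sequence {seq_id!r} in alignment") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


@dataclass
class ConservationProfile:
    score: np.ndarray  # fraction of sequences carrying the majority residue
    majority_residue: np.ndarray  # '-' sentinel for all-gap columns
    coverage: np.ndarray  # fraction of non-gap entries

    @property
    def n_columns(self) -> int:
        return self.score.size


@dataclass
class MotifBox:
    start_column: int  # 1-based inclusive
    end_column: int
    consensus: str
    label: int


def read_clustal(path: str | Path) -> AlignedSequenceSet:
    """Read a Clustal (or clustal_num) alignment file."""
    try:
        aln = AlignIO.read(str(path), "clustal")
    except (ValueError, AssertionError) as exc:
        raise AlignmentParseError(f"{path}: {exc}") from exc
    return AlignedSequenceSet(
        ids=[rec.id for rec in aln], rows=[str(rec.seq).upper() for rec in aln]
    )


def write_clustal(aln: AlignedSequenceSet, path: str | Path) -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), "clustal")


def column_conservation(aln: AlignedSequenceSet) -> ConservationProfile:
    """Score each column by its majority non-gap residue.

    score[c] = count(majority residue among non-gap entries) / n_sequences;
    ties broken alphabetically; an all-gap column scores 0 with majority '-'.
    """
    if aln.n_sequences == 0 or aln.n_columns == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(row) for row in aln.rows])
    n_seq, n_col = mat.shape
    score = np.zeros(n_col)
    majority = np.full(n_col, GAP, dtype="<U1")
    coverage = np.zeros(n_col)
    for c in range(n_col):
        col = mat[:, c]
        residues, counts = np.unique(col[col != GAP], return_counts=True)
        coverage[c] = (col != GAP).sum() / n_seq
        if residues.size == 0:
            continue
        best = min(residues[counts == counts.max()].tolist())  # alphabetical tie-break
        majority[c] = best
        score[c] = counts.max() / n_seq
    return ConservationProfile(score=score, majority_residue=majority, coverage=coverage)


def find_conserved_motifs(
    profile: ConservationProfile,
    min_score: float = 1.0,
    min_length: int = 2,
    max_gap: int = 1,
) -> list[MotifBox]:
    """Maximal runs of columns scoring >= min_score, bridging short dips.

    Runs start and end at above-threshold columns; up to ``max_gap``
    consecutive below-threshold columns are tolerated inside a run.  Boxes of
    fewer than ``min_length`` columns are dropped.  Returned boxes are
    disjoint and sorted by start column (1-based).
    """
    if not 0 < min_score <= 1:
        raise ValueError("min_score must be in (0, 1]")
    above = np.flatnonzero(profile.score >= min_score)
    boxes: list[MotifBox] = []
    if above.size == 0:
        return boxes
    runs: list[tuple[int, int]] = []
    start = prev = above[0]
    for idx in above[1:]:
        if idx - prev - 1 <= max_gap:
            prev = idx
        else:
            runs.append((start, prev))
            start = prev = idx
    runs.append((start, prev))
    label = 1
    for s, e in runs:
        if e - s + 1 < min_length:
            continue
        consensus = "".join(profile.majority_residue[s : e + 1])
        boxes.append(MotifBox(start_column=s + 1, end_column=e + 1, consensus=consensus, label=label))
        label += 1
    return boxes


def map_residue_to_column(aln: AlignedSequenceSet, seq_id: str, residue_index: int) -> int:
    """1-based ungapped residue position -> 1-based alignment column."""
    row = aln.row(seq_id)
    if residue_index < 1:
        raise IndexError("residue_index is 1-based")
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == residue_index:
                return col
    raise IndexError(
        f"residue {residue_index} beyond ungapped length {seen} of {seq_id}"
    )


def column_to_residue(aln: AlignedSequenceSet, seq_id: str, column: int) -> int:
    """1-based alignment column -> 1-based ungapped residue position."""
    row = aln.row(seq_id)
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside alignment width {len(row)}")
    if row[column - 1] == GAP:
        raise ValueError(f"{seq_id} has a gap at column {column}")
    return sum(1 for ch in row[:column] if ch != GAP)


def count_conserved_residue(
    aln: AlignedSequenceSet,
    profile: ConservationProfile,
    residue: str,
    min_score: float = 1.0,
) -> int:
    """Number of columns whose majority residue is ``residue`` at score >= min_score."""
    if len(residue) != 1 or not residue.isalpha():
        raise ValueError("residue must be a single amino-acid letter")
    residue = residue.upper()
    return int(
        ((profile.majority_residue == residue) & (profile.score >= min_score)).sum()
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity after global alignment (BLOSUM62, -11/-1 gaps).

    Identity = identical aligned pairs / columns where neither sequence is
    gapped, in percent, so terminal extensions do not dilute the value.
    """
    seq_a, seq_b = seq_a.replace(GAP, ""), seq_b.replace(GAP, "")
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    alignment = aligner.align(seq_a, seq_b)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    both = [(x, y) for x, y in zip(a_row, b_row) if x != GAP and y != GAP]
    if not both:
        raise ValueError("no aligned residue pairs")
    ident = sum(1 for x, y in both if x == y)
    return 100.0 * ident / len(both)
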