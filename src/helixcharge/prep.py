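"""Alignment-level preprocessing.

Gap-threshold trimming and coverage filtering follow the trimAl ``-gt``
convention (keep columns whose non-gap fraction is at least the threshold).
Greedy identity clustering follows the CD-HIT convention: sequences are
processed longest-first and identity is exact matches in a global alignment
divided by the shorter sequence's length.

Segment extraction splits every row into an N-terminal and an internal part,
either at an explicit alignment-column range or at the first predicted
alpha-helix of each sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import Alignment, ProteinSequence

# Chou-Fasman style helix propensities (relative to 1.0 = indifferent); used
# only by the optional heuristic stand-in for an external secondary-structure
# predictor, and only when explicitly enabled.
HELIX_PROPENSITY = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
    "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
    "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
    "W": 1.08, "Y": 0.69, "X": 1.00,
}


@dataclass
class SegmentSpec:
    """Where the N-terminal segment ends.

    ``column_range`` mode gives an alignment-column window [col_start,
    col_end) (0-based half-open); ``first_helix`` mode finds the boundary per
    sequence from its secondary structure.
    """

    source: str = "column_range"  # column_range | first_helix
    col_start: int = 0
    col_end: int | None = None
    min_run: int = 10

    def __post_init__(self) -> None:
        if self.source not in ("column_range", "first_helix"):
            raise ValueError(f"unknown segment source {self.source!r}")
        if self.source == "column_range":
            if self.col_end is None or not (self.col_start < self.col_end):
                raise ValueError("column_range requires col_start < col_end")


@dataclass
class ClusterSet:
    clusters: list[tuple[str, list[str]]]
    threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def _nongap_fraction(column: str) -> float:
    return sum(c != "-" for c in column) / len(column)


def trim_by_gap_threshold(aln: Alignment, gt: float) -> tuple[Alignment, list[int]]:
    """Keep the columns whose non-gap fraction is >= ``gt``.

    Returns the trimmed alignment plus the original-column indices kept, for
    coordinate mapping back to the untrimmed alignment.
    """
    if not (0 < gt <= 1):
        raise ValueError(f"gap threshold must be in (0, 1], got {gt}")
    kept = [j for j in range(aln.n_cols) if _nongap_fraction(aln.column(j)) >= gt]
    if not kept:
        warnings.warn("gap-threshold trimming removed every column")
        return Alignment(ids=list(aln.ids), rows=[""] * aln.n_rows), []
    rows = ["".join(row[j] for j in kept) for row in aln.rows]
    return Alignment(ids=list(aln.ids), rows=rows), kept


def filter_by_coverage(aln: Alignment, min_cov: float) -> Alignment:
    """Drop rows whose non-gap fraction over the (trimmed) columns is < min_cov."""
    if not (0 < min_cov <= 1):
        raise ValueError(f"min_cov must be in (0, 1], got {min_cov}")
    keep_idx = [
        i
        for i, row in enumerate(aln.rows)
        if aln.n_cols > 0 and sum(c != "-" for c in row) / aln.n_cols >= min_cov
    ]
    return Alignment(
        ids=[aln.ids[i] for i in keep_idx], rows=[aln.rows[i] for i in keep_idx]
    )


_ALIGNER: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    # BLOSUM62 with gap open 10 / extend 1; matches scored as identity only
    # when counting, the matrix just shapes the alignment path.
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Exact matches in one optimal global alignment / shorter length."""
    alignment = _global_aligner().align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        # X marks an unknown residue; an X-X pair is not evidence of identity
        matches += sum(x == y and x != "X" for x, y in zip(seg_a, seg_b))
    return matches / min(len(a), len(b))


def greedy_identity_cluster(
    seqs: Sequence[ProteinSequence], threshold: float
) -> ClusterSet:
    """Greedy incremental clustering at an identity threshold.

    Sequences are sorted longest-first (ties by id, ascending); each joins the
    first existing cluster whose representative it matches at >= threshold
    identity, otherwise it founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    reps: list[ProteinSequence] = []
    members: list[list[str]] = []
    for seq in order:
        placed = False
        for k, rep in enumerate(reps):
            if seq.residues == rep.residues or pairwise_identity(
                seq.residues, rep.residues
            ) >= threshold:
                members[k].append(seq.id)
                placed = True
                break
        if not placed:
            reps.append(seq)
            members.append([seq.id])
    return ClusterSet(
        clusters=[(rep.id, mem) for rep, mem in zip(reps, members)],
        threshold=threshold,
    )


def extract_segments(
    aln: Alignment, spec: SegmentSpec, ss_by_id: dict[str, str] | None = None
) -> dict[str, tuple[str, str]]:
    """Split each row into ungapped (nterm, internal) residue strings.

    In ``column_range`` mode the N-terminal segment is the ungapped residues
    within [col_start, col_end); the internal segment is everything else.
    All-gap windows yield an empty segment (kept, with a warning).
    """
    out: dict[str, tuple[str, str]] = {}
    if spec.source == "column_range":
        if spec.col_end > aln.n_cols or spec.col_start < 0:
            raise ValueError(
                f"column range [{spec.col_start}, {spec.col_end}) outside "
                f"alignment of {aln.n_cols} columns"
            )
        for sid, row in zip(aln.ids, aln.rows):
            window = row[spec.col_start : spec.col_end]
            rest = row[: spec.col_start] + row[spec.col_end :]
            nterm = window.replace("-", "")
            internal = rest.replace("-", "")
            if not nterm:
                warnings.warn(f"row {sid!r}: all-gap N-terminal window")
            out[sid] = (nterm, internal)
        return out

    if ss_by_id is None:
        raise ValueError("first_helix extraction requires secondary structure")
    for sid, row in zip(aln.ids, aln.rows):
        residues = row.replace("-", "")
        ss = ss_by_id.get(sid)
        if ss is None:
            raise ValueError(f"row {sid!r}: secondary structure required")
        seq = ProteinSequence(id=sid, residues=residues, ss=ss)
        rng = first_helix_segment(seq, min_run=spec.min_run)
        if rng is None:
            warnings.warn(f"row {sid!r}: no qualifying first helix; empty N-terminus")
            out[sid] = ("", residues)
        else:
            out[sid] = (residues[rng[0] : rng[1]], residues[: rng[0]] + residues[rng[1] :])
    return out


def predict_ss_propensity(residues: str, window: int = 7, cutoff: float = 1.03) -> str:
    """Sliding-window helix-propensity call: 'H' when the window mean exceeds
    the cutoff, else 'C'. An acknowledged simplification standing in for an
    external neural secondary-structure predictor; config-gated, never silent.
    """
    half = window // 2
    n = len(residues)
    calls = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        mean = sum(HELIX_PROPENSITY[c] for c in residues[lo:hi]) / (hi - lo)
        calls.append("H" if mean > cutoff else "C")
    return "".join(calls)


def first_helix_segment(
    seq: ProteinSequence,
    min_run: int,
    *,
    use_heuristic: bool = False,
    search_window: int = 30,
) -> tuple[int, int] | None:
    """First maximal run of 'H' of length >= min_run starting within the first
    ``search_window`` residues; 0-based half-open, or None if absent.
    """
    ss = seq.ss
    if ss is None:
        if not use_heuristic:
            raise ValueError(f"sequence {seq.id!r}: secondary structure required")
        ss = predict_ss_propensity(seq.residues)
    i = 0
    n = len(ss)
    while i < n and i < search_window:
        if ss[i] == "H":
            j = i
            while j < n and ss[j] == "H":
                j += 1
            if j - i >= min_run:
                return (i, j)
            i = j
        else:
            i += 1
    return None
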