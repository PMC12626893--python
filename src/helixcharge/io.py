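"""Readers and writers for the external formats the pipeline touches.

Sequences and alignments are plain FASTA (Biopython parses them); trees are
Newick (dendropy parses them, see :mod:`helixcharge.tree`); continuous tip
traits are two-column TSV; predicted-aligned-error (PAE) matrices are
ColabFold-style JSON. Every reader validates eagerly and names the first
offending record, because downstream numerics assume clean containers.

Residue and column coordinates are 0-based half-open throughout the library;
the command line converts to/from 1-based inclusive at the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity codes collapsed to X on input (the pipeline treats X as
#: uncountable everywhere: composition, charge, entropy).
AMBIGUOUS_TO_X = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}

_RESIDUE_ALPHABET = frozenset(STANDARD_AA + "X")
_ALIGNED_ALPHABET = frozenset(STANDARD_AA + "X-")

FAMILY_LABELS = ("I", "II", "III", "other")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass
class ProteinSequence:
    """A protein sequence with optional family label and secondary structure.

    ``ss``, when present, is a per-residue string over {H, E, C} of the same
    length as ``residues``.
    """

    id: str
    residues: str
    family: str | None = None
    ss: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _RESIDUE_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-residue characters {sorted(bad)}"
            )
        if self.family is not None and self.family not in FAMILY_LABELS:
            raise FormatError(f"sequence {self.id!r}: unknown family {self.family!r}")
        if self.ss is not None:
            if len(self.ss) != len(self.residues):
                raise FormatError(
                    f"sequence {self.id!r}: ss length {len(self.ss)} != "
                    f"residue length {len(self.residues)}"
                )
            bad = set(self.ss) - set("HEC")
            if bad:
                raise FormatError(f"sequence {self.id!r}: ss characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length rows over residues + '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            dup = _first_duplicate(self.ids)
            raise FormatError(f"duplicate id {dup!r} in alignment")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise FormatError(
                        f"ragged alignment: row {sid!r} has length {len(row)}, "
                        f"expected {n}"
                    )
                bad = set(row) - _ALIGNED_ALPHABET
                if bad:
                    raise FormatError(f"row {sid!r}: bad characters {sorted(bad)}")
                if set(row) == {"-"}:
                    raise FormatError(f"row {sid!r} is all gaps")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        return self.rows[self.ids.index(sid)]

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass
class PaeMatrix:
    """Square predicted-aligned-error matrix (Angstrom) with a chain boundary.

    ``chain_break`` is the 0-based index of the first residue of chain B.
    """

    e: np.ndarray
    chain_break: int
    model_id: str = ""

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if self.e.ndim != 2 or self.e.shape[0] != self.e.shape[1]:
            raise FormatError(f"PAE matrix not square: shape {self.e.shape}")
        if np.any(self.e < 0) or not np.all(np.isfinite(self.e)):
            raise FormatError("PAE entries must be finite and >= 0")
        n = self.e.shape[0]
        if not (0 < self.chain_break < n):
            raise FormatError(f"chain_break {self.chain_break} out of range (0, {n})")

    @property
    def size(self) -> int:
        return self.e.shape[0]


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _normalize_residues(raw: str, *, sid: str, aligned: bool) -> str:
    """Uppercase, map ambiguity codes to X; '.' gaps only legal when aligned."""
    s = raw.upper()
    if "." in s:
        if not aligned:
            raise FormatError(f"sequence {sid!r}: '.' gap in unaligned input")
        s = s.replace(".", "-")
    mapped = []
    warned = False
    for c in s:
        if c in AMBIGUOUS_TO_X:
            if not warned:
                warnings.warn(
                    f"sequence {sid!r}: ambiguity code(s) mapped to X", stacklevel=3
                )
                warned = True
            mapped.append("X")
        else:
            mapped.append(c)
    return "".join(mapped)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read unaligned protein FASTA into validated :class:`ProteinSequence`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = _normalize_residues(str(rec.seq), sid=rec.id, aligned=False)
        if not residues:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        if "-" in residues:
            raise FormatError(f"{path}: gap character in unaligned record {rec.id!r}")
        seqs.append(ProteinSequence(id=rec.id, residues=residues))
    return seqs


def write_fasta(seqs: Sequence[ProteinSequence], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(str(rec.seq[i : i + width]) + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned FASTA; '.' and lowercase normalized, row lengths checked."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    dup = _first_duplicate(ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate id {dup!r}")
    rows = [
        _normalize_residues(str(r.seq), sid=r.id, aligned=True) for r in records
    ]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        offending = [(i, len(r)) for i, r in zip(ids, rows)]
        raise FormatError(f"{path}: ragged alignment rows {offending}")
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Traits, secondary structure, PAE
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path) -> dict[str, float]:
    """Read a tip->value TSV (header ``tip\\tvalue`` optional)."""
    traits: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields")
            tip, raw = parts
            if lineno == 1 and tip == "tip" and raw == "value":
                continue
            try:
                value = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric trait value {raw!r} for {tip!r}"
                ) from None
            if not np.isfinite(value):
                raise FormatError(f"{path}:{lineno}: non-finite trait for {tip!r}")
            if tip in traits:
                raise FormatError(f"{path}:{lineno}: duplicate tip {tip!r}")
            traits[tip] = value
    if not traits:
        raise FormatError(f"{path}: empty trait table")
    return traits


def write_trait_table(traits: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tip\tvalue\n")
        for tip, value in traits.items():
            fh.write(f"{tip}\t{value:.10g}\n")


def read_ss_annotation(path: str | Path) -> dict[str, str]:
    """Read an id -> secondary-structure-string TSV (alphabet H/E/C)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields")
            sid, ss = parts
            if lineno == 1 and sid == "id" and ss == "ss":
                continue
            if set(ss) - set("HEC"):
                raise FormatError(f"{path}:{lineno}: bad ss characters for {sid!r}")
            if sid in out:
                raise FormatError(f"{path}:{lineno}: duplicate id {sid!r}")
            out[sid] = ss
    return out


def read_pae(path: str | Path, chain_break: int | None = None) -> list[PaeMatrix]:
    """Read one or more PAE matrices from ColabFold-style JSON.

    Accepts either a single object or a list of objects; each object carries
    the matrix under ``predicted_aligned_error`` or ``pae``. The chain
    boundary is taken from a ``chain_break`` key in the object, or from the
    ``chain_break`` argument (a sidecar/CLI value) when the file lacks one.
    """
    with open(path) as fh:
        payload = json.load(fh)
    objects = payload if isinstance(payload, list) else [payload]
    out: list[PaeMatrix] = []
    for i, obj in enumerate(objects):
        if not isinstance(obj, dict):
            raise FormatError(f"{path}: entry {i} is not a JSON object")
        matrix = obj.get("predicted_aligned_error", obj.get("pae"))
        if matrix is None:
            raise FormatError(
                f"{path}: entry {i} has neither 'predicted_aligned_error' nor 'pae'"
            )
        e = np.asarray(matrix, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise FormatError(f"{path}: entry {i}: PAE matrix not square ({e.shape})")
        cb = obj.get("chain_break", chain_break)
        if cb is None:
            raise FormatError(
                f"{path}: entry {i}: no chain_break in file and none supplied"
            )
        model_id = str(obj.get("model_id", f"{Path(path).stem}:{i}"))
        out.append(PaeMatrix(e=e, chain_break=int(cb), model_id=model_id))
    return out


def write_pae(matrices: Sequence[PaeMatrix], path: str | Path) -> None:
    payload = [
        {
            "model_id": m.model_id,
            "chain_break": int(m.chain_break),
            "predicted_aligned_error": m.e.tolist(),
        }
        for m in matrices
    ]
    with open(path, "w") as fh:
        json.dump(payload if len(payload) != 1 else payload[0], fh)
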