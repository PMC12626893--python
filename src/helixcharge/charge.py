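"""Net charge of residue segments at a fixed pH.

Each ionizable group contributes a Henderson-Hasselbalch partial charge:
+1 / (1 + 10^(pH - pKa)) for a basic group and -1 / (1 + 10^(pKa - pH)) for
an acidic one. The headline statistic is the length-normalized net charge
q_norm = q_net / L (elementary charges per residue), computed at pH 7 on
N-terminal helix segments longer than a minimum length.

Two pKa tables ship: "bjellqvist" (the constants used by Biopython's
charge-at-pH routine) and an EMBOSS-style alternative; the table id is
recorded in every result row so outputs are self-describing. Terminal groups
default to off because the analyzed segments are protein fragments and the
N-terminal/internal comparison should treat both symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .io import STANDARD_AA

_RESIDUE_ALPHABET = frozenset(STANDARD_AA + "X-")


@dataclass(frozen=True)
class PkaTable:
    """Side-chain (and terminal) pKa values with their charge signs."""

    table_id: str
    pka: Mapping[str, float]       # side chains, subset of {D,E,C,Y,H,K,R}
    sign: Mapping[str, int]        # +1 basic, -1 acidic, per side chain
    pka_nterm: float               # alpha-amino group (basic)
    pka_cterm: float               # alpha-carboxyl group (acidic)

    def __post_init__(self) -> None:
        if set(self.pka) != set(self.sign):
            raise ValueError("pKa table and sign map must cover the same groups")
        for g, v in self.pka.items():
            if not (0 < v < 14):
                raise ValueError(f"pKa({g}) = {v} outside (0, 14)")
        for g, s in self.sign.items():
            if s not in (+1, -1):
                raise ValueError(f"sign({g}) must be +1 or -1")


#: Bjellqvist-style constants, as used by Biopython's IsoelectricPoint /
#: charge-at-pH machinery.
BJELLQVIST = PkaTable(
    table_id="bjellqvist",
    pka={"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0},
    sign={"D": -1, "E": -1, "C": -1, "Y": -1, "H": +1, "K": +1, "R": +1},
    pka_nterm=7.5,
    pka_cterm=3.55,
)

#: EMBOSS iep defaults, shipped as the alternative table.
EMBOSS = PkaTable(
    table_id="emboss",
    pka={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5},
    sign={"D": -1, "E": -1, "C": -1, "Y": -1, "H": +1, "K": +1, "R": +1},
    pka_nterm=8.6,
    pka_cterm=3.6,
)

TABLES = {t.table_id: t for t in (BJELLQVIST, EMBOSS)}


@dataclass
class ChargeResult:
    """Net charge of one segment at a stated pH."""

    q_net: float
    L: int
    pH: float
    table_id: str

    @property
    def q_norm(self) -> float:
        return self.q_net / self.L


def _hh_term(pka: float, sign: int, pH: float) -> float:
    if sign > 0:
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    return -1.0 / (1.0 + 10.0 ** (pka - pH))


def residue_charge(aa: str, pH: float, table: PkaTable = BJELLQVIST) -> float:
    """Partial charge of a single residue's side chain at ``pH``.

    Non-ionizable residues, X and '-' contribute zero; unknown characters
    are an error.
    """
    if aa not in _RESIDUE_ALPHABET:
        raise ValueError(f"unknown residue {aa!r}")
    if aa in table.pka:
        return _hh_term(table.pka[aa], table.sign[aa], pH)
    return 0.0


def net_charge(
    segment: str,
    pH: float = 7.0,
    table: PkaTable = BJELLQVIST,
    include_termini: bool = False,
) -> ChargeResult:
    """Sum of per-residue Henderson-Hasselbalch terms over a segment.

    L counts standard residues only (X and gaps excluded), and q_norm is
    q_net / L. Terminal alpha-amino/alpha-carboxyl terms are added only when
    ``include_termini`` is set.
    """
    q = 0.0
    L = 0
    for aa in segment:
        q += residue_charge(aa, pH, table)
        if aa in STANDARD_AA:
            L += 1
    if L == 0:
        raise ValueError("segment has no countable residues")
    if include_termini:
        q += _hh_term(table.pka_nterm, +1, pH)
        q += _hh_term(table.pka_cterm, -1, pH)
    return ChargeResult(q_net=q, L=L, pH=pH, table_id=table.table_id)


def charge_profiles(
    segments: Mapping[str, tuple[str, str]],
    families: Mapping[str, str],
    *,
    pH: float = 7.0,
    min_len: int = 100,
    table: PkaTable = BJELLQVIST,
    include_termini: bool = False,
) -> list[dict]:
    """One row per (sequence, region) surviving the length filter.

    ``segments`` maps id -> (nterm, internal); segments of length <= min_len
    are excluded (strictly "more than min_len residues").
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    rows: list[dict] = []
    for sid, (nterm, internal) in segments.items():
        for region, seg in (("nterm", nterm), ("internal", internal)):
            L = sum(c in STANDARD_AA for c in seg)
            if L <= min_len:
                continue
            res = net_charge(seg, pH=pH, table=table, include_termini=include_termini)
            rows.append(
                {
                    "id": sid,
                    "family": families.get(sid, "other"),
                    "region": region,
                    "L": res.L,
                    "q_net": res.q_net,
                    "q_norm": res.q_norm,
                    "pH": pH,
                    "table_id": res.table_id,
                }
            )
    return rows
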