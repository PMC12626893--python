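"""Interchain predicted-aligned-error (PEAK) scoring and per-pair aggregation.

The PEAK score of one predicted multimer model is the mean predicted aligned
error over all residue pairs that span the two chains — both off-diagonal
blocks of the PAE matrix, so asymmetric matrices are handled by averaging
rather than symmetrizing (equivalent for the mean). Lower PEAK means a more
confident predicted interface. Scores from several models of the same pair
are aggregated by mean or max, together with the models' ipTM values (ipTM is
read from prediction metadata, never recomputed from coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PaeMatrix


@dataclass
class InteractionScore:
    pair_id: str
    peak_per_model: list[float]
    iptm_per_model: list[float]
    peak_agg: float
    iptm_agg: float
    agg_mode: str


def peak_score(pae: PaeMatrix) -> float:
    """Mean PAE over the two interchain blocks (Angstrom)."""
    b = pae.chain_break
    ab = pae.e[:b, b:]
    ba = pae.e[b:, :b]
    return float((ab.sum() + ba.sum()) / (ab.size + ba.size))


def peak_score_min(pae: PaeMatrix) -> float:
    """Minimum interchain PAE entry — the alternative summary column."""
    b = pae.chain_break
    return float(min(pae.e[:b, b:].min(), pae.e[b:, :b].min()))


def aggregate_models(
    pair_id: str,
    peak_per_model: Sequence[float],
    iptm_per_model: Sequence[float],
    mode: str = "mean",
) -> InteractionScore:
    """Aggregate per-model PEAK and ipTM values (mode: mean or max)."""
    if len(peak_per_model) == 0:
        raise ValueError("no models to aggregate")
    if len(peak_per_model) != len(iptm_per_model):
        raise ValueError("peak and iptm lists differ in length")
    if any(p < 0 for p in peak_per_model):
        raise ValueError("PEAK scores must be >= 0")
    if any(not (0 <= t <= 1) for t in iptm_per_model):
        raise ValueError("ipTM values must lie in [0, 1]")
    if mode == "mean":
        agg = (float(np.mean(peak_per_model)), float(np.mean(iptm_per_model)))
    elif mode == "max":
        agg = (float(np.max(peak_per_model)), float(np.max(iptm_per_model)))
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return InteractionScore(
        pair_id=pair_id,
        peak_per_model=list(map(float, peak_per_model)),
        iptm_per_model=list(map(float, iptm_per_model)),
        peak_agg=agg[0],
        iptm_agg=agg[1],
        agg_mode=mode,
    )
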