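"""Synthetic three-family datasets with the statistical structure the
pipeline assumes.

The generator emulates a clade of paralogue families on one rooted tree:

* a pure-birth (Yule) phylogeny per family, the three families joined at the
  root by stem branches of length 1;
* a continuous charge trait (q_norm, elementary charges per residue) evolving
  by Brownian motion from an uncharged root, with a negative jump on the
  family-II stem branch;
* protein sequences whose N-terminal segment realizes each tip's charge
  (at pH 7 each D/E contributes about -1 and each K/R about +1, so the
  charged-residue fractions solve f_KR - f_DE = q_norm), while the internal
  region is drawn from one conserved profile shared by all families.

Paralogue families are clades, so each family carries its own background
residue preferences (a Dirichlet perturbation of a shared global background)
and a founder sequence from which its tips deviate by substitution noise;
family II is additionally more variable, mirroring the empirical observation
that the diverged family's N terminus is the most diverse. Without this
family-level structure the non-shifted families would be statistically
identical and no composition classifier could separate them.

All randomness flows from a single seed through named substreams (tree,
trait, sequence, pae), so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .io import (
    Alignment,
    PaeMatrix,
    ProteinSequence,
    write_alignment,
    write_fasta,
    write_trait_table,
)
from .tree import Node, PhyloTree, write_newick

_SUBSTREAM = {"tree": 0, "trait": 1, "sequence": 2, "pae": 3}

#: Global background amino-acid frequencies (rounded database-wide averages),
#: renormalized over the 16 non-charged residues where needed.
BACKGROUND = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039, "G": 0.071,
    "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097, "M": 0.024, "N": 0.040,
    "P": 0.047, "Q": 0.039, "R": 0.055, "S": 0.066, "T": 0.053, "V": 0.069,
    "W": 0.011, "Y": 0.029,
}

CHARGED = ("D", "E", "K", "R")
NONCHARGED = tuple(a for a in sorted(BACKGROUND) if a not in CHARGED)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    The first block states the headline conditions (family sizes, trait
    process, family-II compositional shift); the second block holds the
    sequence-realism knobs documented in the methods note.
    """

    n_per_family: int = 120
    birth_rate: float = 1.0
    sigma2: float = 0.002          # q_norm^2 per unit branch length
    root_qnorm: float = 0.0
    shift_delta: float = -0.25     # jump on the family-II stem
    nterm_len_mean: float = 120.0
    nterm_len_sd: float = 15.0
    nterm_len_min: int = 101       # the >100-residue length filter passes by construction
    internal_len: int = 450
    de_enrichment: float = 0.08    # family-II absolute composition deltas,
    kr_depletion: float = 0.08     # used when the trait coupling is off
    seed: int = 0

    couple_to_trait: bool = True   # charged content follows the simulated trait
    charged_fraction: float = 0.30     # baseline f_DE + f_KR of N-terminal helices
    nterm_sub_rate: float = 0.12       # within-family substitution rate, families I/III
    family2_sub_rate: float = 0.30     # family II N terminus is the most diverse
    internal_sub_rate: float = 0.05
    family_profile_concentration: float = 150.0
    indel_rate: float = 0.0            # geometric-gap mode, trimming tests only
    indel_mean_len: float = 5.0

    def __post_init__(self) -> None:
        if self.n_per_family < 4:
            raise ValueError("n_per_family must be >= 4")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.nterm_len_min <= 100:
            raise ValueError("nterm_len_min must exceed 100")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _SUBSTREAM[stream]])


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    tree: PhyloTree
    traits: dict[str, float]              # tip -> simulated q_norm
    true_node_states: dict[str, float]    # every node, for recovery tests
    sequences: list[ProteinSequence]
    alignment: Alignment
    families: dict[str, str]              # tip -> family label
    segments: dict[str, tuple[str, str]]  # tip -> (nterm, internal)
    nterm_cols: tuple[int, int]           # alignment column range of the N-terminal block


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    *,
    scale_height: float | None = None,
) -> PhyloTree:
    """Pure-birth tree with ``n`` tips and exponential waiting times.

    Tips are labeled t1..tn in postorder. Deterministic given the seed.
    With ``scale_height`` set, every branch is rescaled so the (ultrametric)
    root-to-tip height equals that value.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    birth_time = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        parent.length = None if parent.parent is None else t - birth_time[id(parent)]
        # record split time on the parent; children inherit it as birth time
        birth_time[id(parent)] = t
        for _ in range(2):
            child = parent.add_child(Node())
            birth_time[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for node in active:
        node.length = t_end - birth_time[id(node)]
    if scale_height is not None:
        # root-to-tip height excludes the root edge (no parent branch)
        height = t_end - birth_time[id(root)]
        if root.children:
            height = t_end - min(birth_time[id(c)] for c in root.children)
        if height <= 0:
            raise ValueError("degenerate tree of zero height")
        factor = scale_height / height
        stack = [root]
        while stack:
            node = stack.pop()
            if node.length is not None:
                node.length *= factor
            stack.extend(node.children)
    # label tips t1..tn in left-to-right (postorder) order before validation
    counter = 0
    stack = [root]
    order: list[Node] = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(node.children)
    for node in reversed(order):
        if not node.children:
            counter += 1
            node.label = f"t{counter}"
    return PhyloTree(root)


def build_family_tree(config: SyntheticConfig) -> PhyloTree:
    """Rooted tree with three monophyletic family clades (I, II, III).

    Each family is a Yule tree on ``n_per_family`` tips, rescaled to unit
    height so the duplication stems (fixed length 1) are commensurate with
    the family radiations, and attached to the root by those stems. Stems are
    labeled stemI/stemII/stemIII and tip labels carry the family prefix
    (e.g. ``II_t7``).
    """
    rng = config.rng("tree")
    root = Node(label="root")
    for fam in ("I", "II", "III"):
        sub = simulate_yule_tree(
            config.n_per_family, config.birth_rate, rng, scale_height=1.0
        )
        stem = sub.root
        stem.label = f"stem{fam}"
        stem.length = 1.0
        for tip in sub.tips():
            tip.label = f"{fam}_{tip.label}"
        # family subtree keeps its own internal labels out of the way
        for node in sub.internal_nodes():
            if node is not stem:
                node.label = None
        root.add_child(stem)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def simulate_bm_trait(
    tree: PhyloTree,
    sigma2: float,
    root_state: float,
    jumps: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Preorder Brownian simulation with optional per-branch jumps.

    ``jumps`` maps a node label to a deterministic shift added on the branch
    leading to that node. Returns (tip traits, every node's true state).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jumps = dict(jumps or {})
    unknown = set(jumps) - {n.label for n in tree.preorder()}
    if unknown:
        raise KeyError(f"jump on unknown branch(es): {sorted(unknown)}")
    states: dict[str, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            states[node.label] = float(root_state)
            continue
        parent_state = states[node.parent.label]
        step = rng.normal(0.0, math.sqrt(sigma2 * node.length)) if sigma2 > 0 else 0.0
        states[node.label] = parent_state + step + jumps.get(node.label, 0.0)
    tips = {t.label: states[t.label] for t in tree.tips()}
    return tips, states


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _charged_fractions(q_target: float, baseline: float) -> tuple[float, float]:
    """Solve f_KR - f_DE = q_target with total charged fraction >= baseline."""
    if abs(q_target) > 0.6:
        raise ValueError(
            f"q_norm target {q_target:+.3f} unrealizable without degenerate "
            "composition (|q| > 0.6)"
        )
    total = max(baseline, abs(q_target))
    f_de = (total - q_target) / 2.0
    f_kr = (total + q_target) / 2.0
    return f_de, f_kr


def _draw_lengths(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            L = int(round(rng.normal(config.nterm_len_mean, config.nterm_len_sd)))
            if L >= config.nterm_len_min:
                out[i] = L
                break
    return out


def realize_sequences(
    tree: PhyloTree,
    traits: Mapping[str, float] | None,
    config: SyntheticConfig,
) -> tuple[list[ProteinSequence], Alignment, dict[str, str], dict[str, tuple[str, str]], tuple[int, int]]:
    """Sequences, alignment, family labels and segments for every tip.

    With ``traits`` supplied, each tip's D/E and K/R content is set so the
    measured length-normalized charge matches the simulated trait. Without
    traits, families I and III sit at the charge-balanced baseline and family
    II receives the configured absolute D/E enrichment and K/R depletion.

    The alignment is constructed by design: N-terminal segments left-aligned
    with trailing gaps to the widest N terminus, then the equal-length
    internal block (no indels unless ``indel_rate`` > 0).
    """
    rng = config.rng("sequence")
    tips = tree.tip_labels
    families = {t: t.split("_", 1)[0] for t in tips}
    fam_names = sorted(set(families.values()))

    bg_noncharged = np.array([BACKGROUND[a] for a in NONCHARGED])
    bg_noncharged = bg_noncharged / bg_noncharged.sum()

    # family-level composition preferences and founder skeletons
    conc = config.family_profile_concentration
    profiles = {
        fam: rng.dirichlet(conc * bg_noncharged) for fam in fam_names
    }
    lengths = {t: L for t, L in zip(tips, _draw_lengths(config, len(tips), rng))}
    l_cap = max(lengths.values())
    founders = {
        fam: rng.choice(len(NONCHARGED), size=l_cap, p=profiles[fam])
        for fam in fam_names
    }

    # shared conserved internal profile: one dominant residue per column
    all_aa = sorted(BACKGROUND)
    bg_all = np.array([BACKGROUND[a] for a in all_aa])
    bg_all = bg_all / bg_all.sum()
    internal_profile = rng.choice(len(all_aa), size=config.internal_len, p=bg_all)

    sequences: list[ProteinSequence] = []
    segments: dict[str, tuple[str, str]] = {}
    nterm_rows: dict[str, str] = {}
    internal_rows: dict[str, str] = {}

    for tip in tips:
        fam = families[tip]
        L = int(lengths[tip])
        if traits is not None:
            q_target = float(traits[tip])
            f_de, f_kr = _charged_fractions(q_target, config.charged_fraction)
        else:
            f_de = config.charged_fraction / 2.0
            f_kr = config.charged_fraction / 2.0
            if fam == "II":
                f_de += config.de_enrichment
                f_kr -= config.kr_depletion
                if f_kr < 0:
                    raise ValueError("kr_depletion exceeds the charged baseline")
        n_de = int(round(f_de * L))
        n_kr = int(round(f_kr * L))
        charged_pos = rng.choice(L, size=n_de + n_kr, replace=False)
        residues = np.empty(L, dtype="U1")
        is_charged = np.zeros(L, dtype=bool)
        is_charged[charged_pos] = True
        de_pos, kr_pos = charged_pos[:n_de], charged_pos[n_de:]
        residues[de_pos] = rng.choice(["D", "E"], size=n_de)
        residues[kr_pos] = rng.choice(["K", "R"], size=n_kr)

        sub_rate = config.family2_sub_rate if fam == "II" else config.nterm_sub_rate
        open_pos = np.flatnonzero(~is_charged)
        founder_idx = founders[fam][open_pos].copy()
        substituted = rng.random(open_pos.size) < sub_rate
        if substituted.any():
            founder_idx[substituted] = rng.choice(
                len(NONCHARGED), size=int(substituted.sum()), p=profiles[fam]
            )
        residues[open_pos] = np.array(NONCHARGED, dtype="U1")[founder_idx]
        nterm = "".join(residues)

        keep_int = rng.random(config.internal_len) >= config.internal_sub_rate
        internal_res = np.array(
            [all_aa[i] for i in internal_profile], dtype="U1"
        )
        n_sub = int(np.sum(~keep_int))
        if n_sub:
            internal_res[~keep_int] = rng.choice(all_aa, size=n_sub, p=bg_all)
        internal = "".join(internal_res)
        internal_row = internal
        if config.indel_rate > 0 and rng.random() < config.indel_rate:
            start = int(rng.integers(0, config.internal_len))
            gap_len = 1 + int(rng.geometric(1.0 / config.indel_mean_len))
            end = min(config.internal_len, start + gap_len)
            internal = internal[:start] + internal[end:]
            internal_row = internal_row[:start] + "-" * (end - start) + internal_row[end:]

        segments[tip] = (nterm, internal)
        nterm_rows[tip] = nterm
        internal_rows[tip] = internal_row
        sequences.append(
            ProteinSequence(
                id=tip,
                residues=nterm + internal,
                family=fam,
                ss="H" * len(nterm) + "C" * len(internal),
            )
        )

    width = max(len(r) for r in nterm_rows.values())
    rows = [nterm_rows[t].ljust(width, "-") + internal_rows[t] for t in tips]
    alignment = Alignment(ids=list(tips), rows=rows)
    return sequences, alignment, families, segments, (0, width)


# ---------------------------------------------------------------------------
# PAE fixtures
# ---------------------------------------------------------------------------

def simulate_pae_fixture(
    chain_lengths: tuple[int, int],
    intra_level: float,
    inter_level: float,
    noise: float = 0.0,
    seed: int | np.random.Generator = 0,
    model_id: str = "synthetic",
) -> PaeMatrix:
    """Block-structured synthetic PAE matrix (a test fixture, not a predictor).

    Intrachain blocks sit at ``intra_level``, interchain blocks at
    ``inter_level``, plus additive uniform noise on [0, noise).
    """
    if intra_level < 0 or inter_level < 0 or noise < 0:
        raise ValueError("levels and noise must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    la, lb = chain_lengths
    n = la + lb
    e = np.full((n, n), intra_level, dtype=float)
    e[:la, la:] = inter_level
    e[la:, :la] = inter_level
    if noise > 0:
        e += rng.uniform(0.0, noise, size=(n, n))
    return PaeMatrix(e=e, chain_break=la, model_id=model_id)


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------

def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full dataset: tree, trait, sequences, alignment, labels."""
    tree = build_family_tree(config)
    jumps = {"stemII": config.shift_delta}
    tip_traits, node_states = simulate_bm_trait(
        tree,
        config.sigma2,
        config.root_qnorm,
        jumps=jumps,
        seed=config.rng("trait"),
    )
    coupling = tip_traits if config.couple_to_trait else None
    sequences, alignment, families, segments, nterm_cols = realize_sequences(
        tree, coupling, config
    )
    return SyntheticDataset(
        config=config,
        tree=tree,
        traits=tip_traits,
        true_node_states=node_states,
        sequences=sequences,
        alignment=alignment,
        families=families,
        segments=segments,
        nterm_cols=nterm_cols,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset to disk in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sequences": outdir / "sequences.fasta",
        "alignment": outdir / "alignment.fasta",
        "ss": outdir / "ss.tsv",
        "tree": outdir / "tree.nwk",
        "traits": outdir / "traits_true.tsv",
        "families": outdir / "families.tsv",
    }
    write_fasta(dataset.sequences, paths["sequences"])
    write_alignment(dataset.alignment, paths["alignment"])
    with open(paths["ss"], "w") as fh:
        fh.write("id\tss\n")
        for seq in dataset.sequences:
            fh.write(f"{seq.id}\t{seq.ss}\n")
    write_newick(dataset.tree, paths["tree"])
    write_trait_table(dataset.traits, paths["traits"])
    with open(paths["families"], "w") as fh:
        fh.write("id\tfamily\n")
        for tip, fam in dataset.families.items():
            fh.write(f"{tip}\t{fam}\n")
    return paths
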