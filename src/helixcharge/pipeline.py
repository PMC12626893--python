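"""End-to-end orchestration: simulate or load, extract, entropy, LDA, charge,
ancestral reconstruction, report.

Every stage communicates through its declared output files under the run
directory, and the machine-readable summary (summary.json) contains only
numbers reproducible from those files. Identical config + seed yields a
byte-identical summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ancestral import ancestral_states_fast, prepare_tree, shift_summary
from .charge import TABLES, charge_profiles
from .entropy import compare_entropy_groups, entropy_profiles
from .io import Alignment, read_alignment
from .lda import composition_matrix, split_fit_evaluate
from .prep import SegmentSpec, extract_segments, trim_by_gap_threshold
from .simulate import SyntheticConfig, generate, write_dataset
from .tree import read_newick

logger = logging.getLogger("helixcharge")


@dataclass
class PipelineConfig:
    """One structured config drives the whole run; CLI flags override keys."""

    # either simulate ...
    simulate: SyntheticConfig | None = None
    # ... or load from files
    alignment_path: str | None = None
    tree_path: str | None = None
    families_path: str | None = None
    ss_path: str | None = None

    # segment boundary (alignment columns, 0-based half-open)
    col_start: int = 0
    col_end: int | None = None     # None = use the generator's N-terminal block

    gt: float = 0.75               # gap threshold for region trimming
    min_n_eff: int = 4
    alpha: float = 0.01
    letters_from: str = "tukey"

    train_frac: float = 0.3
    split_seed: int = 20240131
    ridge: float = 1e-6

    ph: float = 7.0
    min_len: int = 100
    pka_table: str = "bjellqvist"
    include_termini: bool = False

    clade_label: str = "stemII"

    @staticmethod
    def from_toml(path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = raw.pop("simulate", None)
        cfg = PipelineConfig(**raw)
        if sim is not None:
            cfg.simulate = SyntheticConfig(**sim)
        return cfg


def _family_region_alignments(
    aln: Alignment,
    families: dict[str, str],
    col_range: tuple[int, int],
    gt: float,
) -> dict[tuple[str, str], Alignment]:
    """Split the alignment into per-(family, region) blocks, then trim each
    block at the gap threshold (trim-after-split)."""
    lo, hi = col_range
    out: dict[tuple[str, str], Alignment] = {}
    for fam in sorted(set(families.values())):
        ids = [sid for sid in aln.ids if families.get(sid) == fam]
        if not ids:
            continue
        rows = [aln.row(sid) for sid in ids]
        nterm = Alignment(ids=ids, rows=[r[lo:hi] for r in rows])
        internal = Alignment(ids=ids, rows=[r[:lo] + r[hi:] for r in rows])
        out[(fam, "nterm")], _ = trim_by_gap_threshold(nterm, gt)
        out[(fam, "internal")], _ = trim_by_gap_threshold(internal, gt)
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in fixed order; returns the summary dict.

    Outputs: stage TSVs plus summary.json under ``outdir``. Any stage error
    aborts the run with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__}
    stage = "inputs"
    try:
        if config.simulate is not None:
            dataset = generate(config.simulate)
            write_dataset(dataset, outdir / "inputs")
            aln = dataset.alignment
            tree = dataset.tree
            families = dataset.families
            col_range = dataset.nterm_cols if config.col_end is None else (
                config.col_start, config.col_end,
            )
            summary["seed"] = dataset.config.seed
            logger.info(
                "simulated dataset: %d tips, N-terminal block [%d, %d)",
                tree.n_tips, *col_range,
            )
        else:
            if config.alignment_path is None or config.tree_path is None:
                raise ValueError("need alignment_path and tree_path (or a simulate block)")
            aln = read_alignment(config.alignment_path)
            tree = read_newick(config.tree_path)
            if config.families_path:
                fam_df = pd.read_csv(config.families_path, sep="\t")
                families = dict(zip(fam_df["id"], fam_df["family"]))
            else:
                families = {sid: sid.split("_", 1)[0] for sid in aln.ids}
            if config.col_end is None:
                raise ValueError("col_end is required for loaded alignments")
            col_range = (config.col_start, config.col_end)

        stage = "extract"
        spec = SegmentSpec(source="column_range", col_start=col_range[0], col_end=col_range[1])
        segments = extract_segments(aln, spec)

        stage = "entropy"
        blocks = _family_region_alignments(aln, families, col_range, config.gt)
        profiles = entropy_profiles(blocks, min_n_eff=config.min_n_eff)
        comparison = compare_entropy_groups(
            profiles, alpha=config.alpha, letters_from=config.letters_from
        )
        ent_rows = [
            {"family": p.family, "region": p.region, "column": c, "H_bits": h}
            for p in profiles
            for c, h in zip(p.columns, p.H)
        ]
        pd.DataFrame(ent_rows).to_csv(outdir / "entropy_columns.tsv", sep="\t", index=False)
        cmp_rows = [
            {
                "pair": f"{g1}|{g2}",
                "p_tukey": comparison.p_tukey[(g1, g2)],
                "p_bonferroni": comparison.p_bonferroni[(g1, g2)],
            }
            for i, g1 in enumerate(comparison.groups)
            for g2 in comparison.groups[i + 1 :]
        ]
        pd.DataFrame(cmp_rows).to_csv(outdir / "entropy_comparison.tsv", sep="\t", index=False)
        summary["entropy_letters"] = comparison.letters
        summary["entropy_means"] = {g: round(m, 6) for g, m in comparison.means.items()}

        stage = "lda"
        nterm_segments = {sid: seg[0] for sid, seg in segments.items() if seg[0]}
        ids, X = composition_matrix(nterm_segments)
        y = np.array([families[sid] for sid in ids])
        result = split_fit_evaluate(
            X, y, train_frac=config.train_frac, seed=config.split_seed, ridge=config.ridge
        )
        model = result["model"]
        proj = model.transform(X)
        pd.DataFrame(
            {"id": ids, "family": y, "ld1": proj[:, 0], "ld2": proj[:, 1] if proj.shape[1] > 1 else np.nan}
        ).to_csv(outdir / "lda_projection.tsv", sep="\t", index=False)
        pred = model.predict(X[result["test_idx"]])
        truth = y[result["test_idx"]]
        confusion = pd.crosstab(
            pd.Series(truth, name="truth"), pd.Series(pred, name="predicted")
        )
        confusion.to_csv(outdir / "lda_confusion.tsv", sep="\t")
        contrib = model.feature_contributions()
        pd.DataFrame(
            {"residue": list("ACDEFGHIKLMNPQRSTVWY"), "contribution": contrib}
        ).to_csv(outdir / "lda_contributions.tsv", sep="\t", index=False)
        summary["lda_accuracy_heldout"] = round(result["accuracy_heldout"], 6)
        summary["lda_accuracy_resubstitution"] = round(result["accuracy_resubstitution"], 6)
        logger.info("LDA ridge=%g split seed=%d", config.ridge, config.split_seed)

        stage = "charge"
        table = TABLES[config.pka_table]
        rows = charge_profiles(
            segments,
            families,
            pH=config.ph,
            min_len=config.min_len,
            table=table,
            include_termini=config.include_termini,
        )
        charge_df = pd.DataFrame(rows)
        charge_df.to_csv(outdir / "charge.tsv", sep="\t", index=False)
        mean_q = (
            charge_df.groupby(["family", "region"])["q_norm"].mean().round(6)
        )
        summary["mean_q_norm"] = {
            f"{fam}:{region}": v for (fam, region), v in mean_q.items()
        }
        logger.info("charge table=%s pH=%g termini=%s", table.table_id, config.ph, config.include_termini)

        stage = "ancestral"
        traits = {
            r["id"]: r["q_norm"] for r in rows if r["region"] == "nterm"
        }
        prepared, used, dropped = prepare_tree(tree, traits)
        recon = ancestral_states_fast(prepared, used)
        pd.DataFrame(recon.as_rows()).to_csv(
            outdir / "ancestral_states.tsv", sep="\t", index=False
        )
        summary["ancestral_sigma2"] = round(recon.fit.sigma2_ml, 8)
        summary["ancestral_root_state"] = round(recon.fit.root_state, 6)
        if config.clade_label in recon.states:
            shift = shift_summary(recon, config.clade_label)
            summary["clade_shift"] = {k: round(v, 6) for k, v in shift.items()}
        summary["ancestral_dropped_tips"] = len(dropped)

        stage = "report"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
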