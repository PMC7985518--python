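"""End-to-end orchestration of the hierarchical target analysis.

Stage order: motif affinities on open chromatin -> evidence flags ->
primary/secondary classification and upset summary -> sparse logistic
regression on the secondary DEGs -> directed TF network.  All
intermediate tables are persisted as tab-separated files, and every stage
is a pure function of (inputs, config, seed) so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pyfaidx

from . import affinity_model as am
from . import dynamite as dyn
from . import target_classifier as tc
from . import tf_network as net
from .config import PipelineConfig, save_config
from .genomic_core import (
    extract_sequence,
    read_bed,
    read_deg_table,
    read_gene_annotation,
    read_rem_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineError",
    "PipelineResult",
    "run_pipeline",
    "config_for_bundle",
]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: PipelineConfig
    thresholds: dict[str, float]
    scores_control: am.TFGeneScoreMatrix
    scores_treated: am.TFGeneScoreMatrix
    scores_treated_thresholded: am.TFGeneScoreMatrix
    flags: pd.DataFrame
    classification: pd.DataFrame
    upset: tc.UpsetSummary
    importances: list[dyn.TFImportance]
    dynamite_meta: dict
    network: "net.nx.DiGraph"
    counts: dict = field(default_factory=dict)


def config_for_bundle(bundle, outdir: str | Path, **overrides) -> PipelineConfig:
    """Pipeline config wired to the files of a simulated input bundle."""
    paths = bundle.paths
    sim = bundle.config
    settings = dict(
        genes_gtf=str(paths["genes"]),
        peaks_bed=str(paths["peaks"]),
        genome_fasta=str(paths["genome"]),
        motifs=str(paths["motifs"]),
        open_chromatin={
            "control": str(paths["open_control"]),
            "treated": str(paths["open_treated"]),
        },
        rem_table=str(paths["rems"]),
        deg_tables={tp: str(paths[f"deg_{tp}"]) for tp in sim.timepoints},
        tf_genes=str(paths["tf_genes"]),
        outdir=str(outdir),
        half_width=sim.half_width,
        decay_constant=sim.decay_constant,
        early_timepoints=list(sim.early_timepoints),
        late_timepoints=list(sim.late_timepoints),
        root_tf=sim.root_tf,
        seed=sim.seed,
    )
    settings.update(overrides)
    return PipelineConfig(**settings)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and persist results under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    save_config(config, outdir / "run_config.yaml")
    counts: dict[str, float] = {}
    stage = "load_inputs"
    try:
        genes = read_gene_annotation(config.genes_gtf)
        peaks = read_bed(config.peaks_bed)
        open_regions = {
            cond: read_bed(path) for cond, path in sorted(config.open_chromatin.items())
        }
        rems = read_rem_table(config.rem_table) if config.rem_table else []
        deg_tables = {
            tp: read_deg_table(path) for tp, path in sorted(config.deg_tables.items())
        }
        motifs = am.parse_motifs(config.motifs, pseudocount=config.pseudocount)
        fasta = pyfaidx.Fasta(str(config.genome_fasta))
        tf_gene_map: dict[str, str] = {}
        if config.tf_genes:
            tf_df = pd.read_csv(config.tf_genes, sep="\t")
            tf_gene_map = dict(zip(tf_df["tf_name"], tf_df["gene_id"]))
        counts["n_genes"] = len(genes)
        counts["n_peaks"] = len(peaks)
        counts["n_rems"] = len(rems)
        for cond, regs in open_regions.items():
            counts[f"n_open_{cond}"] = len(regs)
        logger.info(
            "loaded %d genes, %d peaks, %d REMs, %d motifs",
            len(genes), len(peaks), len(rems), len(motifs),
        )

        stage = "affinity"
        energy = {
            pwm.motif_id or pwm.tf_name: am.pwm_to_energy_matrix(
                pwm,
                lambda_param=config.trap_lambda,
                r0_slope=config.trap_r0_slope,
                r0_intercept=config.trap_r0_intercept,
            )
            for pwm in motifs
        }
        motif_to_tf = {
            pwm.motif_id or pwm.tf_name: pwm.tf_name for pwm in motifs
        }
        rng = np.random.default_rng(config.seed)
        treated_seqs = [
            extract_sequence(fasta, r) for r in open_regions["treated"]
        ]
        background = am.make_background(
            treated_seqs, config.n_random_sequences, rng
        )
        thresholds: dict[str, float] = {}
        for motif_id, em in energy.items():
            tf = motif_to_tf[motif_id]
            thr = am.calibrate_threshold(em, background, config.threshold_p_value)
            thresholds[tf] = max(thresholds.get(tf, 0.0), thr)
        region_aff = {
            cond: am.compute_region_affinities(energy, regs, fasta)
            for cond, regs in open_regions.items()
        }
        score_kwargs = dict(
            genes=genes,
            half_width=config.half_width,
            decay_constant=config.decay_constant,
            motif_to_tf=motif_to_tf,
            variant_agg=config.variant_agg,
        )
        scores = {
            cond: am.compute_gene_tf_scores(
                open_regions[cond], region_aff[cond], condition=cond, **score_kwargs
            )
            for cond in open_regions
        }
        scores_thr = am.compute_gene_tf_scores(
            open_regions["treated"],
            region_aff["treated"],
            thresholds=thresholds,
            condition="treated_thresholded",
            **score_kwargs,
        )
        pd.Series(thresholds, name="threshold").rename_axis("tf_name").to_csv(
            outdir / "thresholds.tsv", sep="\t"
        )
        for cond, mat in scores.items():
            mat.to_tsv(outdir / f"scores_{cond}.tsv")
        scores_thr.to_tsv(outdir / "scores_treated_thresholded.tsv")

        stage = "classify"
        window_flags = tc.flag_window_targets(peaks, genes, config.half_width)
        rem_flags = tc.flag_rem_targets(
            peaks, rems, known_genes=[g.gene_id for g in genes]
        )
        motif_flags = tc.flag_motif_targets(scores_thr, config.root_tf)
        flags = tc.combine_flags(
            [g.gene_id for g in genes],
            window_peak=window_flags,
            rem_overlap=rem_flags,
            motif_open_chromatin=motif_flags,
        )
        classification = tc.classify_degs(
            deg_tables,
            flags,
            early_timepoints=config.early_timepoints,
            late_timepoints=config.late_timepoints,
            k_methods=config.k_methods,
            padj_cutoff=config.padj_cutoff,
        )
        upset = tc.summarize_upset(classification, flags)
        flags.to_csv(outdir / "flags.tsv", sep="\t")
        classification.to_csv(outdir / "classification.tsv", sep="\t")
        upset.to_frame().to_csv(outdir / "upset.tsv", sep="\t", index=False)
        with open(outdir / "upset.json", "w") as fh:
            json.dump(upset.to_dict(), fh, indent=1, sort_keys=True)
        proportions = []
        for timing in ("early", "late"):
            n_deg = int((classification["timing"] == timing).sum())
            n_primary = int(
                (
                    (classification["timing"] == timing)
                    & classification["is_primary"]
                ).sum()
            )
            pct = tc.percentage(n_primary, n_deg) if n_deg else 0.0
            proportions.append(
                {
                    "timing": timing,
                    "n_degs": n_deg,
                    "n_primary": n_primary,
                    "percent_primary": pct,
                }
            )
            counts[f"n_{timing}_degs"] = n_deg
            counts[f"n_{timing}_primary"] = n_primary
            logger.info(
                "%s DEGs: %d, predicted primary: %d (%.1f%%)",
                timing, n_deg, n_primary, pct,
            )
        pd.DataFrame(proportions).to_csv(
            outdir / "proportions.tsv", sep="\t", index=False
        )

        stage = "dynamite"
        late_tp = config.late_timepoints[0]
        late_deg = deg_tables[late_tp]
        if config.restrict_to_secondary:
            selected = classification[
                (classification["timing"] == "late")
                & ~classification["is_primary"]
            ].index.tolist()
        else:
            selected = classification.index.tolist()
        features, labels = dyn.build_feature_matrix(
            scores["control"],
            scores["treated"],
            late_deg,
            labeled_genes=selected,
            epsilon=config.epsilon,
            kind=config.feature_kind,
        )
        counts["n_regression_genes"] = len(labels)
        if len(labels) and labels.nunique() == 2:
            raw, meta = dyn.fit_sparse_classifier(
                features,
                labels,
                penalty_grid=config.penalty_grid,
                n_outer_folds=config.n_outer_folds,
                n_inner_folds=config.n_inner_folds,
                l1_ratio=config.l1_ratio,
                seed=config.seed,
            )
            importances = dyn.normalize_and_rank(raw)
        else:
            logger.warning(
                "regression skipped: %d labeled genes, %d classes",
                len(labels), labels.nunique() if len(labels) else 0,
            )
            importances, meta = [], {"skipped": True}
        dyn.importance_table(importances).to_csv(
            outdir / "tf_importance.tsv", sep="\t", index=False
        )
        with open(outdir / "dynamite_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

        stage = "network"
        primary_tfs: dict[str, str] = {}
        for tf in sorted(tf_gene_map):
            if tf == config.root_tf:
                continue
            gene_id = tf_gene_map[tf]
            if gene_id in classification.index and bool(
                classification.at[gene_id, "is_primary"]
            ):
                primary_tfs[tf] = classification.at[gene_id, "timing"]
        edge_threshold = (
            thresholds
            if config.network_edge_threshold == "calibrated"
            else float(config.network_edge_threshold)
        )
        network = net.build_tf_network(
            primary_tfs,
            scores["treated"].scores,
            tf_gene_ids=tf_gene_map,
            edge_threshold=edge_threshold,
            root=config.root_tf,
            half_width=config.half_width,
        )
        counts["n_network_nodes"] = network.number_of_nodes()
        counts["n_network_edges"] = network.number_of_edges()
        counts["n_binding_edges"] = sum(
            1
            for _, _, d in network.edges(data=True)
            if d["evidence"] == net.PREDICTED_BINDING
        )
        net.export_network(network, outdir / "network", fmt="tsv")
        net.export_network(network, outdir / "network", fmt="graphml")
        net.export_network(network, outdir / "network", fmt="dot")

        with open(outdir / "counts.json", "w") as fh:
            json.dump(counts, fh, indent=1, sort_keys=True)
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc

    return PipelineResult(
        config=config,
        thresholds=thresholds,
        scores_control=scores["control"],
        scores_treated=scores["treated"],
        scores_treated_thresholded=scores_thr,
        flags=flags,
        classification=classification,
        upset=upset,
        importances=importances,
        dynamite_meta=meta,
        network=network,
        counts=counts,
    )
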