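"""Config-driven orchestration of the full discovery pipeline.

Stage order: activation differential expression -> rank-aggregation
meta-analysis -> ChIP direct-target filter -> per-cohort regression
networks -> dependency-screen GSEA classification -> cohort LOF/survival
statistics.  Each stage writes a self-describing TSV under the run
directory, and a machine-readable summary records the candidate counts
after every filter.  Re-running with the same configuration and seed
reproduces identical outputs; the master seed fans out to per-stage
seeds by stable hashing of stage names.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import __version__
from .chip import annotate_tss_binding, direct_target_filter
from .config import PipelineConfig, derive_seed, validate_config
from .cohort import lof_meta_combine, survival_scan
from .depgsea import classify_lncrna, gsea_batch, summarize_across_lines
from .diffexpr import differential_expression, rank_split
from .exceptions import ConfigurationError
from .meta_rank import select_consistent, stability_aggregate
from .network import AssociationNetwork, build_network, p53lof_diffexp
from .synthetic import (
    generate_activation_datasets,
    generate_annotation,
    generate_chip_datasets,
    generate_cohorts,
    generate_dependency_screens,
    make_truth,
    read_study,
    write_study,
)

__all__ = ["run_pipeline", "simulate_study", "classify_candidates"]

logger = logging.getLogger(__name__)


def simulate_study(config: PipelineConfig, outdir=None):
    """Generate every synthetic input layer; optionally write the bundle."""
    sim = config.simulation
    annotation = generate_annotation(sim)
    truth = make_truth(annotation, sim)
    datasets = generate_activation_datasets(annotation, truth, sim)
    peaks = generate_chip_datasets(annotation, truth, sim)
    cohorts = generate_cohorts(annotation, truth, sim)
    screens = generate_dependency_screens(annotation, truth, sim)
    if outdir is not None:
        write_study(outdir, annotation, truth, datasets, peaks, cohorts, screens)
    return annotation, truth, datasets, peaks, cohorts, screens


def _meta_stage(datasets, config: PipelineConfig):
    """Differential expression, ranking and stabilized aggregation."""
    up_lists, down_lists, detected = [], [], {}
    for cm in datasets:
        table = differential_expression(cm)
        up, down = rank_split(table, dataset_id=cm.dataset_id)
        up_lists.append(up)
        down_lists.append(down)
        detected[cm.dataset_id] = set(table.index)
    agg_up = stability_aggregate(up_lists, detected=detected)
    agg_down = stability_aggregate(down_lists, detected=detected)
    sel_up = select_consistent(agg_up, config.meta_fdr, config.consistency_fraction)
    sel_down = select_consistent(agg_down, config.meta_fdr, config.consistency_fraction)
    return agg_up, agg_down, sel_up, sel_down


def classify_candidates(
    networks: list[AssociationNetwork],
    screens,
    candidates: set[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """GSEA-classify each candidate lncRNA on every cell line.

    For each cohort's network, each screen type and cell line, the
    candidate's positive and negative association sets are scored
    together in one batch (shared permutation null and pooled FDR), then
    labelled suppressive/oncogenic/excluded/unclassified.
    """
    rows = []
    for net in networks:
        sets: dict[str, set] = {}
        owners: dict[str, str] = {}
        for lnc in sorted(candidates):
            pos = net.gene_set(lnc, "positive")
            neg = net.gene_set(lnc, "negative")
            if len(pos) >= 2 and len(neg) >= 2:
                sets[f"{lnc}|pos"] = set(pos)
                sets[f"{lnc}|neg"] = set(neg)
                owners[lnc] = net.cancer_type
        if not sets:
            continue
        for screen in screens:
            for cl in screen.cell_lines:
                seed = derive_seed(config.seed, f"gsea:{net.cancer_type}:{screen.screen_type}:{cl}")
                results = {
                    r.set_id: r
                    for r in gsea_batch(
                        screen.scores[cl],
                        sets,
                        weight_p=config.gsea_weight,
                        n_perm=config.gsea_n_perm,
                        seed=seed,
                    )
                }
                for lnc in owners:
                    label = classify_lncrna(
                        results[f"{lnc}|pos"], results[f"{lnc}|neg"], fdr_cut=config.gsea_fdr
                    )
                    rows.append(
                        {
                            "cancer_type": net.cancer_type,
                            "screen_type": screen.screen_type,
                            "cell_line": cl,
                            "lncrna_id": lnc,
                            "label": label,
                            "pos_nes": results[f"{lnc}|pos"].nes,
                            "pos_fdr": results[f"{lnc}|pos"].fdr,
                            "neg_nes": results[f"{lnc}|neg"].nes,
                            "neg_fdr": results[f"{lnc}|neg"].fdr,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "screen_type", "cell_line", "lncrna_id", "label",
            "pos_nes", "pos_fdr", "neg_nes", "neg_fdr",
        ],
    )


def run_pipeline(config: PipelineConfig, input_dir=None, write_inputs: bool = False) -> dict:
    """Run all stages end to end; returns the report bundle as a dict.

    With ``input_dir`` the study is read from a previously written bundle
    (all referenced paths are checked before any computation); otherwise
    the synthetic study is generated from ``config.simulation``.  Writes
    per-stage TSVs, ``summary.json`` and ``run.log`` under
    ``config.output_dir``.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("corelnc")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("corelnc %s | python %s", __version__, sys.version.split()[0])
        logger.info("seed=%d thresholds: meta_fdr=%g consistency=%g window=%d "
                    "chip_min=%d reg_fdr=%g top_k=%d gsea_fdr=%g |z|>%g",
                    config.seed, config.meta_fdr, config.consistency_fraction,
                    config.tss_window_bp, config.chip_min_datasets, config.regression_fdr,
                    config.network_top_k, config.gsea_fdr, config.survival_z_threshold)

        if input_dir is not None:
            input_dir = Path(input_dir)
            manifest = input_dir / "manifest.yaml"
            if not manifest.exists():
                raise ConfigurationError(f"study manifest not found: {manifest}")
            annotation, truth, datasets, peaks, cohorts, screens = read_study(input_dir)
        else:
            annotation, truth, datasets, peaks, cohorts, screens = simulate_study(
                config, outdir / "inputs" if write_inputs else None
            )
        lnc_ids = set(annotation.loc[annotation["biotype"] == "lncRNA", "gene_id"])

        # --- meta-analysis ---------------------------------------------
        agg_up, agg_down, sel_up, sel_down = _meta_stage(datasets, config)
        agg_up.to_csv(outdir / "meta_up.tsv", sep="\t")
        agg_down.to_csv(outdir / "meta_down.tsv", sep="\t")
        meta_lncs = sel_up & lnc_ids
        logger.info("meta stage: %d up / %d down selected; %d up-lncRNAs",
                    len(sel_up), len(sel_down), len(meta_lncs))

        # --- ChIP direct-target filter ---------------------------------
        profile = annotate_tss_binding(peaks, annotation, window_bp=config.tss_window_bp)
        profile.summary.to_csv(outdir / "chip_profile.tsv", sep="\t")
        direct = direct_target_filter(profile, min_datasets=config.chip_min_datasets)
        candidates = meta_lncs & direct
        logger.info("chip stage: %d direct targets; %d candidates after intersection",
                    len(direct), len(candidates))

        # --- regression networks ---------------------------------------
        networks = []
        for cohort in cohorts:
            net = build_network(
                cohort,
                fdr_cut=config.regression_fdr,
                top_k=config.network_top_k,
                log_transform=config.log_transform_expression,
            )
            networks.append(net)
            edges = []
            for sign, side in (("positive", net.positive), ("negative", net.negative)):
                for lnc, df in side.items():
                    for mrna, row in df.iterrows():
                        edges.append({"lncrna_id": lnc, "mrna_id": mrna, "sign": sign,
                                      "beta_lnc": row["beta_lnc"], "fdr": row["fdr"]})
            pd.DataFrame(edges, columns=["lncrna_id", "mrna_id", "sign", "beta_lnc", "fdr"]).to_csv(
                outdir / f"network_{cohort.cancer_type}.tsv", sep="\t", index=False
            )
            logger.info("network stage %s: %d edge rows", cohort.cancer_type, len(edges))

        # --- dependency GSEA classification ----------------------------
        labels = classify_candidates(networks, screens, candidates, config)
        labels.to_csv(outdir / "depgsea_labels.tsv", sep="\t", index=False)
        summary_lines = summarize_across_lines(labels) if len(labels) else None

        # --- cohort statistics -----------------------------------------
        lof_p = {}
        surv_tables = {}
        for cohort in cohorts:
            lof = p53lof_diffexp(cohort.lnc_expr, cohort.p53_status)
            lof.to_csv(outdir / f"lof_{cohort.cancer_type}.tsv", sep="\t")
            lof_p[cohort.cancer_type] = lof["p_down" if config.lof_meta_direction == "down" else "pvalue"]
            feats = sorted(candidates) if candidates else []
            if feats:
                scan = survival_scan(
                    cohort.survival, cohort.lnc_expr.loc[feats], z_threshold=config.survival_z_threshold
                )
                scan.to_csv(outdir / f"survival_{cohort.cancer_type}.tsv", sep="\t")
                surv_tables[cohort.cancer_type] = scan
        lof_meta = lof_meta_combine(pd.DataFrame(lof_p))
        lof_meta.to_csv(outdir / "lof_meta.tsv", sep="\t")

        # --- final candidate table -------------------------------------
        cand_rows = []
        for lnc in sorted(candidates):
            row = {
                "lncrna_id": lnc,
                "meta_fdr": agg_up.loc[lnc, "fdr"],
                "n_consistent": int(agg_up.loc[lnc, "n_consistent"]),
                "n_detected": int(agg_up.loc[lnc, "n_detected"]),
                "n_chip_bound": int(profile.summary.loc[lnc, "n_datasets_bound"]),
                "min_tss_distance": profile.summary.loc[lnc, "min_tss_distance"],
                "lof_combined_p": lof_meta.loc[lnc, "combined_p"] if lnc in lof_meta.index else float("nan"),
                "lof_fdr": lof_meta.loc[lnc, "fdr"] if lnc in lof_meta.index else float("nan"),
            }
            if len(labels):
                mine = labels[labels["lncrna_id"] == lnc]
                row["n_suppressive_lines"] = int((mine["label"] == "suppressive").sum())
                row["n_oncogenic_lines"] = int((mine["label"] == "oncogenic").sum())
            else:
                row["n_suppressive_lines"] = row["n_oncogenic_lines"] = 0
            for ct, scan in surv_tables.items():
                row[f"survival_z_{ct}"] = scan.loc[lnc, "z"] if lnc in scan.index else float("nan")
            cand_rows.append(row)
        cand_table = pd.DataFrame(cand_rows)
        cand_table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

        report = {
            "version": __version__,
            "seed": config.seed,
            "counts": {
                "genes": int(len(annotation)),
                "lncrnas": int(len(lnc_ids)),
                "meta_selected_up": int(len(sel_up)),
                "meta_selected_down": int(len(sel_down)),
                "meta_selected_up_lncrnas": int(len(meta_lncs)),
                "chip_direct_targets": int(len(direct)),
                "candidates": int(len(candidates)),
            },
            "rank_sum_p_suppressive_vs_oncogenic": (
                summary_lines["rank_sum_p"] if summary_lines else None
            ),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        report["candidate_table"] = cand_table
        report["labels"] = labels
        report["networks"] = networks
        report["truth"] = truth
        report["candidate_set"] = candidates
        report["meta_up"] = agg_up
        report["profile"] = profile
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
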