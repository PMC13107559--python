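"""Single-process orchestration: simulate -> qc -> annotate -> classify ->
diff -> atac -> integrate, with a validated config, per-stage record-count
logging and a summary report.  Re-running with the same config and seed
reproduces every output byte for byte."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import annotation, atac, differential, expression, qc, topology
from . import io as lio
from .core import Interval, loop_span, union_coverage
from .simulate import CONDITIONS, SimConfig, simulate_study, write_study

REQUIRED_KEYS = {
    "qc": ("min_distance", "min_count", "rule"),
    "classify": ("slack", "span_mode"),
    "diff": ("pre", "post", "alpha", "min_lfc", "pseudocount"),
    "atac": ("alpha", "min_lfc"),
    "expression": ("alpha", "min_lfc", "rescue_tolerance"),
}


class ConfigError(ValueError):
    pass


def validate_config(cfg: dict) -> dict:
    """Validate the pipeline config; errors name the key and its section."""
    if "seed" not in cfg:
        raise ConfigError("missing config key 'seed' (top level)")
    for section, keys in REQUIRED_KEYS.items():
        if section not in cfg:
            raise ConfigError(f"missing config section {section!r}")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigError(
                    f"missing config key {key!r} in section {section!r}")
    if cfg["qc"]["min_distance"] < 0:
        raise ConfigError("qc.min_distance must be >= 0")
    if cfg["classify"]["span_mode"] not in ("midpoint", "outer"):
        raise ConfigError("classify.span_mode must be 'midpoint' or 'outer'")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def default_config(seed: int = 7, sim_overrides: dict | None = None) -> dict:
    cfg = {
        "seed": seed,
        "sim": dict(sim_overrides or {}),
        "qc": {"min_distance": 10_000, "min_count": 4, "rule": "max"},
        "classify": {"slack": 0, "span_mode": "midpoint"},
        "diff": {"pre": "untreated", "post": "IAA", "alpha": 0.05,
                 "min_lfc": 1.0, "pseudocount": 1.0},
        "atac": {"alpha": 0.05, "min_lfc": 1.0},
        "expression": {"alpha": 0.05, "min_lfc": 1.0, "rescue_tolerance": 0.5},
    }
    return validate_config(cfg)


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage into ``outdir``; returns the summary dict."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = lio.config_hash(config)
    log: dict = {"stages": {}}

    sim_cfg = SimConfig.from_dict({"seed": config["seed"], **config.get("sim", {})})
    study = simulate_study(sim_cfg)
    write_study(study, outdir / "sim")
    log["stages"]["simulate"] = {
        "ctcf_loops": len(study.ctcf_loops),
        "h3k27ac_interactions": len(study.h3k27ac_interactions),
        "genes": len(study.gene_models), "atac_windows": len(study.atac_windows)}

    # ---- QC -------------------------------------------------------------
    qcc = config["qc"]
    promw = annotation.promoter_windows(study.gene_models, genome=sim_cfg.genome)
    elements = [(f"enh_{i}", iv) for i, iv in enumerate(study.enhancers)]
    elements += [(str(r.gene_id), Interval(r.chrom, int(r.start), int(r.end)))
                 for r in promw.itertuples(index=False)]
    qclog: dict = {}
    kept = qc.run_qc(study.h3k27ac_interactions, elements,
                     min_distance=qcc["min_distance"], min_count=qcc["min_count"],
                     condition_rule=qcc["rule"], conditions=list(CONDITIONS),
                     log=qclog)
    log["stages"]["qc"] = qclog
    lio.write_bedpe(kept, outdir / "qc.bedpe", CONDITIONS, h)

    # ---- annotation ----------------------------------------------------
    prom_ivs = annotation.windows_to_intervals(promw)
    ann = annotation.annotate_interactions(
        kept, study.all_ctcf_peaks, study.enhancers, prom_ivs)
    lio.write_table(ann, outdir / "annotated.tsv", h)
    n_loop, n_sites, frac = annotation.looping_fraction(
        study.h3k27ac_peaks, kept)
    cov_ctcf = union_coverage([loop_span(l, "outer") for l in study.ctcf_loops],
                              sim_cfg.genome)
    cov_h3k = union_coverage([loop_span(l, "outer") for l in kept], sim_cfg.genome)

    # ---- topology -------------------------------------------------------
    cls = config["classify"]
    labels = topology.classify_all(kept, study.ctcf_loops,
                                   slack=cls["slack"], span_mode=cls["span_mode"])
    lab_df = topology.labels_to_frame(labels)
    lio.write_table(lab_df, outdir / "topology.tsv", h)
    dist = topology.category_distribution(labels)
    lio.write_table(dist, outdir / "category_distribution.tsv", h)

    # ---- differential interactions -------------------------------------
    dcf = config["diff"]
    norm = differential.normalize_and_fold_change(
        kept, dcf["pre"], dcf["post"], pseudocount=dcf["pseudocount"])
    diff = differential.call_differential(norm, alpha=dcf["alpha"],
                                          min_lfc=dcf["min_lfc"])
    lio.write_table(diff, outdir / "diff.tsv", h)
    class_resp = differential.class_response_report(lab_df, diff)
    lio.write_table(class_resp, outdir / "class_response.tsv", h)
    strata = differential.stratify_by_ctcf_strength(lab_df, diff, which="cross")
    lio.write_table(strata, outdir / "strata_cross.tsv", h)
    balance = differential.contain_cross_balance(lab_df, diff)
    lio.write_table(balance, outdir / "contain_cross_balance.tsv", h)
    n_sig = int((diff["call"] != "unchanged").sum())

    # ---- accessibility -------------------------------------------------
    acf = config["atac"]
    atac_res = atac.call_differential_accessibility(
        study.atac_windows, dcf["pre"], dcf["post"],
        alpha=acf["alpha"], min_lfc=acf["min_lfc"])
    lio.write_table(atac_res, outdir / "atac_diff.tsv", h)
    down_sites = atac_res[atac_res["call"] == "down"]
    g1, g2, ctcf_frac, g2_motif = atac.partition_by_ctcf_overlap(
        down_sites, study.all_ctcf_peaks, study.all_ctcf_motifs)
    n_prom_sites, prom_genes = atac.promoter_fraction_of_down_sites(down_sites, promw)
    pc_genes = study.truth.genes.loc[
        study.truth.genes["promoter_ctcf"], "gene_id"].tolist()
    _, motif_summary = atac.motif_tss_distance(
        study.all_ctcf_motifs, study.gene_models, gene_subset=pc_genes)

    # ---- expression integration ----------------------------------------
    ecf = config["expression"]
    degs = expression.call_degs(study.expression_counts, study.design,
                                dcf["pre"], dcf["post"],
                                alpha=ecf["alpha"], min_lfc=ecf["min_lfc"])
    lio.write_table(degs, outdir / "deg.tsv", h)
    deg_down = degs.loc[degs["deg_status"] == "down", "gene_id"].tolist()
    rescue = expression.classify_rescue(
        study.expression_counts, study.design, deg_down,
        tolerance=ecf["rescue_tolerance"])
    lio.write_table(rescue.rename_axis("gene_id").reset_index(),
                    outdir / "rescue.tsv", h)
    pc_flags, _ = expression.flag_promoter_ctcf(
        deg_down, promw, study.all_ctcf_peaks)
    down_ep_pp = expression.genes_with_down_interactions(
        diff, ann, kept, promw)
    partition = expression.partition_deg_by_mechanism(deg_down, pc_flags, down_ep_pp)
    lio.write_table(partition, outdir / "mechanism_partition.tsv", h)

    # ---- summary --------------------------------------------------------
    pct_sig, pct_sig_str = expression.percent_report(n_sig, len(diff), 2) \
        if len(diff) else (float("nan"), "n/a")
    pct_loop, pct_loop_str = expression.percent_report(n_loop, n_sites, 1) \
        if n_sites else (float("nan"), "n/a")
    n_pc = int(pc_flags.sum()) if len(pc_flags) else 0
    pct_pc, pct_pc_str = (expression.percent_report(n_pc, len(deg_down), 1)
                          if deg_down else (float("nan"), "n/a"))
    summary = {
        "config_hash": h,
        "seed": config["seed"],
        "stages": log["stages"],
        "interactions_after_qc": len(kept),
        "category_distribution": dist.to_dict(orient="list"),
        "differential": {"n_total": len(diff), "n_significant": n_sig,
                         "percent_affected": pct_sig,
                         "percent_affected_str": pct_sig_str},
        "looping": {"n_looping": n_loop, "n_sites": n_sites,
                    "percent": pct_loop, "percent_str": pct_loop_str},
        "coverage": {"ctcf_loops": cov_ctcf, "h3k27ac_interactions": cov_h3k},
        "atac": {"n_down": int(len(down_sites)),
                 "n_up": int((atac_res["call"] == "up").sum()),
                 "ctcf_overlap_fraction": ctcf_frac,
                 "group2_motif_fraction": g2_motif,
                 "n_promoter_down_sites": n_prom_sites,
                 "n_promoter_genes_hit": len(prom_genes),
                 "motif_tss_median": motif_summary["median"]},
        "expression": {"n_deg_down": len(deg_down),
                       "promoter_ctcf_percent": pct_pc,
                       "promoter_ctcf_percent_str": pct_pc_str,
                       "rescue_counts": rescue.value_counts().to_dict(),
                       "mechanism_counts":
                           partition["bucket"].value_counts().to_dict()},
    }
    lio.write_json(summary, outdir / "summary.json", h)
    return summary


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
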