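"""End-to-end pipeline driver over a synthetic scenario or file inputs.

Runs the stages in dependency order, writes one output file per stage
under the run directory, and records a manifest (seed, parameters,
stage list) so a run can be replayed to byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .bioid import (build_bait_network, dotplot_data, filter_high_confidence,
                    merge_engine_counts, select_top_replicates)
from .contrasts import (assign_gene_clusters, assign_peak_clusters,
                        assign_relaxed_clusters, contrast_stats,
                        filter_low_expression)
from .enhancers import rank_super_enhancers, stitch_enhancers
from .genome import annotate_peaks
from .links import build_links, link_enrichment_test
from .motifs import motif_enrichment
from .permtest import breadth_compare, category_enrichment_test, mark_overlap_test
from .proximity import tss_enrichment_curve, tss_meta_profile
from .survival import build_signature, km_logrank, score_samples, stratify
from .synth import SyntheticScenario, gen_chip, gen_counts, gen_genome, gen_links_data, gen_peaks, gen_saint, gen_survival


@dataclass
class PipelineConfig:
    """Thresholds and sizes for a pipeline run. Unknown keys are rejected
    by :meth:`from_dict`."""

    seed: int = 0
    outdir: str = "epimaf_run"
    stat_threshold: float = 2.0
    relaxed_threshold: float = 1.5
    breadth_min: float = 3.0
    max_gap: int = 100
    promoter_window: int = 2000
    stitch_dist: int = 12_500
    link_max_dist: int = 500_000
    link_fdr: float = 0.05
    bfdr_max: float = 0.02
    fc_min: float = 3.0
    n_iter_enrichment: int = 1000
    n_perm_curve: int = 100
    n_iter_links: int = 10_000
    max_tss_distance: int = 20_000   # strict peak clustering pre-filter
    scenario: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("stat_threshold", "relaxed_threshold", "breadth_min",
                     "max_gap", "promoter_window", "stitch_dist",
                     "link_max_dist", "bfdr_max", "fc_min"):
            if getattr(cfg, name) < 0:
                raise ValueError(f"config value {name} must be non-negative")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the synthetic scenario and write per-stage
    outputs plus ``manifest.json``. Returns the result bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = SyntheticScenario(seed=config.seed, **config.scenario)
    results: dict = {"seed": config.seed}
    stages: list[str] = []

    genome = gen_genome(sc)
    eio.write_gene_tsv(genome.genes, out / "genes.tsv")
    stages.append("genome")

    # --- RNA-seq-like: contrasts + gene clusters -------------------------
    counts, design, gene_truth = gen_counts(sc)
    retained = filter_low_expression(counts)
    gt = contrast_stats(retained, design)
    gt.table.to_csv(out / "gene_contrasts.tsv", sep="\t", index_label="gene_id")
    gclust = assign_gene_clusters(gt, threshold=config.stat_threshold)
    gclust.to_csv(out / "gene_clusters.tsv", sep="\t", index_label="gene_id")
    merged = gclust.join(gene_truth)
    plt = merged[merged["true_cluster"] != "none"]
    results["gene_cluster_recovery"] = float(
        (plt["label"] == plt["true_cluster"]).mean()) if len(plt) else float("nan")
    stages.append("gene_contrasts")

    # --- ATAC-like: peaks, contrasts, clusters ---------------------------
    peaks, pcounts, pdesign, peak_truth = gen_peaks(sc, genome)
    pt = contrast_stats(pcounts, pdesign)
    near = peaks["tss_distance"].abs() <= config.max_tss_distance
    pt_near = type(pt)(table=pt.table.loc[near], size_factors=pt.size_factors)
    pclust = assign_peak_clusters(pt_near, threshold=config.stat_threshold)
    pclust.to_csv(out / "peak_clusters.tsv", sep="\t", index_label="peak_id")
    relaxed = assign_relaxed_clusters(pt, peaks, threshold=config.relaxed_threshold,
                                      breadth_min=config.breadth_min)
    relaxed.to_csv(out / "peak_clusters_relaxed.tsv", sep="\t", index_label="peak_id")
    merged = assign_peak_clusters(pt, threshold=config.stat_threshold).join(peak_truth)
    pl = merged[merged["true_cluster"] != "none"]
    results["peak_cluster_recovery"] = float(
        (pl["label"] == pl["true_cluster"]).mean()) if len(pl) else float("nan")
    stages.append("peak_contrasts")

    # --- permutation enrichment ------------------------------------------
    chip_sets, chip_truth = gen_chip(sc, genome, peaks, peak_truth)
    cluster_peaks = peaks.loc[merged.index[merged["true_cluster"] != "none"]]
    cat = category_enrichment_test(cluster_peaks, peaks, "promoter-TSS",
                                   n_iter=config.n_iter_enrichment,
                                   seed=config.seed)
    mark = mark_overlap_test(cluster_peaks, peaks,
                             [chip_sets["H3K27ac"], chip_sets["H3K4me3"]],
                             n_iter=config.n_iter_enrichment,
                             seed=config.seed, max_gap=config.max_gap)
    w_stat, w_p = breadth_compare(peaks[peaks["category"] == "promoter-TSS"],
                                  peaks[peaks["category"] == "intergenic"])
    results["promoter_enrichment"] = cat.to_dict()
    results["mark_overlap_enrichment"] = mark.to_dict()
    results["breadth_wilcoxon_p"] = w_p
    eio.write_json({"category": cat.to_dict(), "mark_overlap": mark.to_dict(),
                    "breadth_p": w_p}, out / "enrichment.json")
    stages.append("perm_enrichment")

    # --- proximity curve + meta profile ----------------------------------
    target = chip_truth["er_target_genes"]
    pool = sorted(set(genome.genes["gene_id"]) - set(target))
    curve = tss_enrichment_curve(chip_sets["ER_MAFE2"], target, pool, genome,
                                 n_perm=config.n_perm_curve, seed=config.seed)
    curve.to_frame().to_csv(out / "proximity_curve.tsv", sep="\t", index=False)
    results["proximity_observed_100kb"] = float(curve.observed[-1])
    results["proximity_envelope_100kb"] = float(curve.permutation_envelope[-1])
    profile = tss_meta_profile(pcounts, peaks, pdesign, pt.size_factors)
    profile.to_csv(out / "tss_meta_profile.tsv", sep="\t", index_label="bin_center")
    stages.append("proximity")

    # --- enhancer links ---------------------------------------------------
    peak_signal, expression, link_peaks, link_truth = gen_links_data(sc, genome, peaks)
    links = build_links(peak_signal, expression, link_peaks, genome,
                        max_dist=config.link_max_dist, fdr=config.link_fdr)
    links.to_csv(out / "links.tsv", sep="\t", index=False)
    true_pairs = {(p, g) for p, g in link_truth["linked_pairs"]}
    found_pairs = set(zip(links["peak_id"], links["gene_id"]))
    results["link_sensitivity"] = float(
        len(true_pairs & found_pairs) / len(true_pairs))
    candidates = sorted({p for p, _ in true_pairs})
    targets = sorted({g for _, g in true_pairs})
    enr = link_enrichment_test(candidates, targets, links, list(link_peaks.index),
                               n_iter=config.n_iter_links, seed=config.seed)
    results["link_enrichment"] = enr.to_dict()
    stages.append("links")

    # --- motif + super-enhancers -----------------------------------------
    rng = np.random.default_rng(config.seed)
    genome_bp = genome.total_size()
    n_matches = 2000
    match_pos = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in rng.integers(0, sc.n_chrom, size=n_matches)],
        "pos": rng.integers(0, sc.chrom_size, size=n_matches)})
    mot = motif_enrichment(peaks, match_pos, genome_bp)
    eio.write_json(mot.to_dict(), out / "motif.json")
    results["motif"] = mot.to_dict()
    stitched = stitch_enhancers(chip_sets["H3K27ac"], genome,
                                stitch_dist=config.stitch_dist,
                                promoter_exclusion=config.promoter_window)
    target_sig = rng.gamma(2.0, 50.0, size=len(stitched)) * stitched["n_constituents"].to_numpy()
    input_sig = rng.gamma(2.0, 10.0, size=len(stitched))
    ranked = rank_super_enhancers(stitched, target_sig, input_sig)
    ranked.drop(columns=["constituents"]).to_csv(out / "super_enhancers.tsv",
                                                 sep="\t", index=False)
    results["n_stitched"] = int(len(ranked))
    results["n_super"] = int(ranked["is_super"].sum())
    stages.append("chromatin_scores")

    # --- BioID ------------------------------------------------------------
    s_counts, s_stats, s_truth = gen_saint(sc)
    merged_counts = merge_engine_counts(s_counts)
    top = select_top_replicates(merged_counts, k=3)
    sets = filter_high_confidence(s_stats, bfdr_max=config.bfdr_max,
                                  fc_min=config.fc_min)
    sets = {b: s for b, s in sets.items() if b != "control"}
    net = build_bait_network(sets)
    eio.write_json(net.sizes(), out / "bioid_network.json")
    dots = dotplot_data(top[top["bait"] != "control"], s_stats,
                        sorted(net.network))
    dots.to_csv(out / "bioid_dotplot.tsv", sep="\t", index=False)
    results["bioid"] = net.sizes()
    true_all = {p for ps in s_truth["true_preys"].values() for p in ps}
    found = set.union(*net.per_bait.values())
    results["bioid_true_recovered"] = float(
        len(true_all & found) / len(true_all))
    stages.append("bioid")

    # --- survival ---------------------------------------------------------
    surv_expr, cohort, surv_truth = gen_survival(sc)
    scores = score_samples(surv_expr, surv_truth["signature_genes"])
    groups = stratify(scores)
    res = km_logrank(cohort, groups, signature=set(surv_truth["signature_genes"]),
                     scores=scores)
    results["survival_logrank_p"] = res.p_value
    results["survival_n_low"] = int((groups == "low").sum())
    pd.concat({k: v for k, v in res.km_curves.items()}, names=["group"]).to_csv(
        out / "km_curves.tsv", sep="\t")
    stages.append("survival")

    cfg_json = json.dumps(asdict(config), sort_keys=True)
    manifest = {"stages": stages, "seed": config.seed,
                "config": asdict(config),
                "param_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16]}
    eio.write_json(manifest, out / "manifest.json")
    eio.write_json(results, out / "results.json")
    return results
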