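"""Synthetic data generators with planted, recoverable structure.

Every input the pipeline consumes can be generated here, sized so a full
scenario builds in well under a minute: a genome with uniformly placed
genes, negative-binomial count matrices under the 2x2 mock/MAF x HD/E2
design with planted cluster-specific effects, peak sets with planted
annotation-category and histone-mark-overlap enrichment, correlated
peak-signal/expression pairs within 500 kb, SAINT-style bait-prey tables
with planted true interactors, and survival cohorts with a planted
signature hazard effect. Each generator returns its ground truth
alongside the data so recovery tests need no external files.

The negative binomial is parameterized by mean and dispersion alpha with
Var = mu + alpha * mu^2. Survival times are exponential with a
proportional-hazards effect for the planted low-signature group and
independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .contrasts import CONDITIONS
from .genome import GenomeModel, annotate_peaks

__all__ = ["SyntheticScenario", "gen_genome", "gen_counts", "gen_peaks",
           "gen_chip", "gen_links_data", "gen_saint", "gen_survival",
           "write_scenario"]

GENE_CLUSTERS = ("1", "2", "3", "4", "5", "6")
PEAK_CLUSTERS = ("A", "B", "C", "D", "E", "F")

# which conditions carry the planted (multiplicative) effect per cluster
_EFFECT_CONDITIONS = {
    "1": ("MAF", "MAFE2"), "2": ("MAF", "MAFE2"),
    "3": ("mockE2", "MAFE2"), "4": ("mockE2", "MAFE2"),
    "5": ("MAFE2",), "6": ("MAFE2",),
}
_EFFECT_SIGN = {"1": +1, "2": -1, "3": +1, "4": -1, "5": +1, "6": -1}
_PEAK_OF_GENE = {"1": "A", "2": "B", "3": "C", "4": "D", "5": "E", "6": "F"}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a full synthetic study. Defaults are the standard
    desk-scale conditions (2,000 genes, 5,000 peaks, 3 replicates per
    condition)."""

    seed: int = 0
    # genome
    n_chrom: int = 4
    chrom_size: int = 50_000_000
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    # 2x2 count design
    n_reps: int = 3
    lfc: float = 2.0                 # planted log2 fold change
    dispersion: float = 0.1          # NB alpha, Var = mu + alpha mu^2
    genes_per_cluster: int = 50
    base_mean_log: float = np.log(100.0)
    base_mean_sd: float = 1.0
    depth_range: tuple[float, float] = (0.7, 1.3)
    # peaks
    n_peaks: int = 5000
    peaks_per_cluster: int = 100
    peak_width_log: float = np.log(600.0)
    peak_width_sd: float = 0.55
    promoter_frac_cluster: float = 0.8
    promoter_frac_background: float = 0.2
    genebody_frac: float = 0.15      # of the non-promoter remainder's split
    peak_base_mean_log: float = np.log(200.0)
    # ChIP / histone marks
    mark_overlap_cluster: float = 0.7
    mark_overlap_background: float = 0.2
    n_er_target_genes: int = 30
    n_chip_noise_peaks: int = 300
    # links
    n_link_samples: int = 50
    n_linked_pairs: int = 100
    n_link_peaks: int = 500
    n_link_genes: int = 500
    link_rho: float = 0.7
    # SAINT / BioID
    n_common_all_preys: int = 40
    n_s_only_preys: int = 15
    n_l_only_preys: int = 20
    n_single_bait_preys: int = 10
    n_background_preys: int = 250
    saint_true_mean: float = 20.0
    saint_ctrl_mean: float = 1.0
    saint_n_reps: int = 4
    # survival
    n_cohort: int = 200
    n_signature_genes: int = 20
    n_noise_genes: int = 180
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 60.0   # per month
    censor_max: float = 120.0             # months; uniform censoring

    def with_(self, **kwargs) -> "SyntheticScenario":
        return dc_replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible RNG stream per generator."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _nb_draw(rng, mean, alpha):
    """NB draws with Var = mu + alpha mu^2 (gamma-Poisson mixture).
    alpha = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 0:
        raise ValueError("dispersion must be non-negative")
    if alpha == 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def gen_genome(scenario: SyntheticScenario | None = None, *,
               n_chrom=None, chrom_size=None, n_genes=None,
               seed=None) -> GenomeModel:
    """Reproducible genome with uniformly placed, randomly stranded genes."""
    sc = scenario or SyntheticScenario()
    if seed is not None:
        sc = sc.with_(seed=seed)
    n_chrom = n_chrom if n_chrom is not None else sc.n_chrom
    chrom_size = chrom_size if chrom_size is not None else sc.chrom_size
    n_genes = n_genes if n_genes is not None else sc.n_genes
    lo, hi = sc.gene_length_range
    if n_genes * lo > 0.8 * n_chrom * chrom_size:
        raise ValueError("gene density infeasible for this genome size")
    rng = sc.rng(1)
    chrom_sizes = {f"chr{i + 1}": chrom_size for i in range(n_chrom)}
    if n_genes == 0:
        return GenomeModel(chrom_sizes=chrom_sizes)
    chroms = rng.integers(0, n_chrom, size=n_genes)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    starts = (rng.random(n_genes) * (chrom_size - lengths)).astype(int)
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n_genes)],
        "chrom": [f"chr{c + 1}" for c in chroms],
        "start": starts,
        "end": starts + lengths,
        "strand": strands,
    })
    return GenomeModel(chrom_sizes=chrom_sizes, genes=genes)


def _planted_condition_means(base_mean: np.ndarray, labels: np.ndarray,
                             lfc: float, cluster_names) -> dict[str, np.ndarray]:
    """Per-condition expected normalized counts given planted labels."""
    fold = 2.0 ** lfc
    means = {c: base_mean.copy() for c in CONDITIONS}
    for name in cluster_names:
        mask = labels == name
        if not mask.any():
            continue
        factor = fold if _EFFECT_SIGN[name] > 0 else 1.0 / fold
        for cond in _EFFECT_CONDITIONS[name]:
            means[cond][mask] *= factor
    return means


def _sample_design_counts(rng, ids, means: dict[str, np.ndarray],
                          n_reps: int, alpha: float,
                          depth_range) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols, data, design_rows = [], [], []
    for cond in CONDITIONS:
        for rep in range(1, n_reps + 1):
            depth = rng.uniform(*depth_range)
            cols.append(f"{cond}_{rep}")
            design_rows.append((f"{cond}_{rep}", cond))
            data.append(_nb_draw(rng, means[cond] * depth, alpha))
    counts = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    design = pd.DataFrame(design_rows, columns=["sample", "condition"])
    return counts, design


def gen_counts(scenario: SyntheticScenario | None = None):
    """RNA-seq-like count matrix under the 2x2 design with planted gene
    clusters 1-6.

    Returns (counts, design, truth) where ``truth`` is a DataFrame with
    the true cluster label per gene ('none' for null genes).
    """
    sc = scenario or SyntheticScenario()
    if sc.dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if sc.n_reps < 2:
        raise ValueError("need >=2 replicates per condition")
    rng = sc.rng(2)
    n = sc.n_genes
    ids = [f"g{i:05d}" for i in range(n)]
    labels = np.full(n, "none", dtype=object)
    k = sc.genes_per_cluster
    if 6 * k > n:
        raise ValueError("too many planted genes for n_genes")
    planted = rng.choice(n, size=6 * k, replace=False)
    for j, name in enumerate(GENE_CLUSTERS):
        labels[planted[j * k:(j + 1) * k]] = name
    base = np.exp(rng.normal(sc.base_mean_log, sc.base_mean_sd, size=n))
    base = np.clip(base, 10.0, None)  # keep planted genes detectably expressed
    means = _planted_condition_means(base, labels, sc.lfc, GENE_CLUSTERS)
    counts, design = _sample_design_counts(rng, ids, means, sc.n_reps,
                                           sc.dispersion, sc.depth_range)
    truth = pd.DataFrame({"true_cluster": labels}, index=ids)
    return counts, design, truth


def _place_peak(rng, genome: GenomeModel, category: str, width: int):
    """One candidate interval intended to annotate as ``category``."""
    genes = genome.genes
    chrom_names = list(genome.chrom_sizes)
    if category == "promoter-TSS":
        g = genes.iloc[rng.integers(len(genes))]
        mid = int(g["tss"] + rng.integers(-1800, 1801))
    elif category == "gene-body":
        g = genes.iloc[rng.integers(len(genes))]
        lo, hi = int(g["start"]) + 2500, int(g["end"]) - 100
        if hi <= lo:
            lo, hi = int(g["start"]), int(g["end"])
        mid = int(rng.integers(lo, hi))
    else:
        chrom = chrom_names[rng.integers(len(chrom_names))]
        mid = int(rng.integers(5_000, genome.chrom_sizes[chrom] - 5_000))
        start = max(mid - width // 2, 0)
        return chrom, start, start + width
    chrom = str(g["chrom"])
    start = max(mid - width // 2, 0)
    return chrom, start, start + width


def gen_peaks(scenario: SyntheticScenario | None = None,
              genome: GenomeModel | None = None):
    """Consensus ATAC-like peak set with planted clusters A-F, planted
    annotation-category enrichment, and an accompanying count matrix.

    Cluster peaks are promoter-TSS with probability
    ``promoter_frac_cluster`` (default 0.8), background peaks with
    ``promoter_frac_background`` (default 0.2). Placement is
    rejection-sampled against the annotation rule so intended and
    annotated categories agree.

    Returns (peaks, counts, design, truth); ``peaks`` is annotated
    (category / nearest_gene / tss_distance) and indexed by peak id;
    ``truth`` carries true_cluster and true_category.
    """
    sc = scenario or SyntheticScenario()
    genome = genome or gen_genome(sc)
    if genome.n_genes == 0:
        raise ValueError("peak generation requires a genome with genes")
    rng = sc.rng(3)
    n = sc.n_peaks
    k = sc.peaks_per_cluster
    if 6 * k > n:
        raise ValueError("too many planted peaks for n_peaks")
    labels = np.full(n, "none", dtype=object)
    planted = rng.choice(n, size=6 * k, replace=False)
    for j, name in enumerate(PEAK_CLUSTERS):
        labels[planted[j * k:(j + 1) * k]] = name

    widths = np.exp(rng.normal(sc.peak_width_log, sc.peak_width_sd, size=n))
    widths = np.clip(widths, 150, 20_000).astype(int)

    is_cluster = labels != "none"
    p_prom = np.where(is_cluster, sc.promoter_frac_cluster, sc.promoter_frac_background)
    u = rng.random(n)
    # remainder splits genebody_frac : (1 - genebody_frac) between
    # gene-body and intergenic
    categories = np.where(
        u < p_prom, "promoter-TSS",
        np.where(u < p_prom + (1 - p_prom) * sc.genebody_frac,
                 "gene-body", "intergenic"))

    rows = []
    for i in range(n):
        want = categories[i]
        for _attempt in range(200):
            chrom, start, end = _place_peak(rng, genome, want, int(widths[i]))
            got = annotate_peaks(pd.DataFrame({"chrom": [chrom], "start": [start],
                                               "end": [end]}), genome)["category"].iloc[0]
            if got == want:
                break
        rows.append((chrom, start, end))
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"],
                         index=[f"peak{i:05d}" for i in range(n)])
    peaks = annotate_peaks(peaks, genome)

    rng_counts = sc.rng(4)
    base = np.exp(rng_counts.normal(sc.peak_base_mean_log, 0.6, size=n))
    base = np.clip(base, 20.0, None)
    gene_labels = np.array([{"A": "1", "B": "2", "C": "3", "D": "4",
                             "E": "5", "F": "6"}.get(l, "none") for l in labels],
                           dtype=object)
    means = _planted_condition_means(base, gene_labels, sc.lfc, GENE_CLUSTERS)
    counts, design = _sample_design_counts(rng_counts, peaks.index, means,
                                           sc.n_reps, sc.dispersion, sc.depth_range)
    truth = pd.DataFrame({"true_cluster": labels, "true_category": categories},
                         index=peaks.index)
    return peaks, counts, design, truth


def gen_chip(scenario: SyntheticScenario | None = None,
             genome: GenomeModel | None = None,
             peaks: pd.DataFrame | None = None,
             truth: pd.DataFrame | None = None):
    """ChIP-like peak sets with planted structure.

    Histone marks (H3K27ac, H3K4me3): intervals overlapping a fraction
    ``mark_overlap_cluster`` of cluster peaks and
    ``mark_overlap_background`` of background peaks, plus noise peaks.
    ER sets (ER_MAF, ER_MAFE2): peaks at the TSS of planted target genes
    (present in BOTH sets) plus per-set noise, for signature recovery.

    Returns (chip_sets: dict name -> peak DataFrame, chip_truth: dict).
    """
    sc = scenario or SyntheticScenario()
    genome = genome or gen_genome(sc)
    if peaks is None or truth is None:
        peaks, _, _, truth = gen_peaks(sc, genome)
    rng = sc.rng(5)
    is_cluster = (truth["true_cluster"] != "none").to_numpy()

    def mark_set(name: str) -> pd.DataFrame:
        p = np.where(is_cluster, sc.mark_overlap_cluster, sc.mark_overlap_background)
        chosen = rng.random(len(peaks)) < p
        sub = peaks.loc[chosen]
        jitter = rng.integers(-200, 201, size=len(sub))
        width = rng.integers(400, 1200, size=len(sub))
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2 + jitter
        start = np.clip(mid - width // 2, 0, None)
        df = pd.DataFrame({"chrom": sub["chrom"].to_numpy(),
                           "start": start, "end": start + width},
                          index=[f"{name}_{i:05d}" for i in range(len(sub))])
        return df, set(sub.index)

    k27, k27_src = mark_set("K27ac")
    k4, k4_src = mark_set("K4me3")

    genes = genome.genes
    target_idx = rng.choice(len(genes), size=sc.n_er_target_genes, replace=False)
    target_genes = genes.iloc[target_idx]

    def er_set(name: str) -> pd.DataFrame:
        rows = []
        for _, g in target_genes.iterrows():
            width = int(rng.integers(300, 800))
            mid = int(g["tss"] + rng.integers(-800, 801))
            rows.append((g["chrom"], max(mid - width // 2, 0)))
            rows[-1] = (*rows[-1], rows[-1][1] + width)
        for _ in range(sc.n_chip_noise_peaks):
            chrom = f"chr{rng.integers(sc.n_chrom) + 1}"
            width = int(rng.integers(300, 800))
            start = int(rng.integers(0, genome.chrom_sizes[chrom] - width))
            rows.append((chrom, start, start + width))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"],
                            index=[f"{name}_{i:05d}" for i in range(len(rows))])

    chip_sets = {"H3K27ac": k27, "H3K4me3": k4,
                 "ER_MAF": er_set("ERMAF"), "ER_MAFE2": er_set("ERMAFE2")}
    chip_truth = {
        "k27ac_source_peaks": sorted(k27_src),
        "k4me3_source_peaks": sorted(k4_src),
        "er_target_genes": sorted(target_genes["gene_id"]),
        "mark_overlap_cluster": sc.mark_overlap_cluster,
        "mark_overlap_background": sc.mark_overlap_background,
    }
    return chip_sets, chip_truth


def gen_links_data(scenario: SyntheticScenario | None = None,
                   genome: GenomeModel | None = None,
                   peaks: pd.DataFrame | None = None):
    """Paired peak-signal and expression matrices with planted correlated
    (peak, gene) pairs within 500 kb.

    Returns (peak_signal, expression, link_peaks, truth) where ``truth``
    lists the planted pairs and the planted correlation.
    """
    from .links import _candidate_pairs

    sc = scenario or SyntheticScenario()
    genome = genome or gen_genome(sc)
    if peaks is None:
        peaks, _, _, _ = gen_peaks(sc, genome)
    rng = sc.rng(6)
    link_peaks = peaks.iloc[:sc.n_link_peaks][["chrom", "start", "end"]]
    gene_ids = genome.genes["gene_id"].to_numpy()
    expr_genes = pd.Index(sorted(rng.choice(gene_ids, size=sc.n_link_genes, replace=False)))

    prow, grow, _ = _candidate_pairs(link_peaks, genome, 500_000)
    cand = pd.DataFrame({"peak": link_peaks.index.to_numpy()[prow],
                         "gene": gene_ids[grow]})
    cand = cand[cand["gene"].isin(expr_genes)]
    cand = cand.drop_duplicates("peak").drop_duplicates("gene")
    if len(cand) < sc.n_linked_pairs:
        raise ValueError("not enough candidate (peak, gene) pairs within 500 kb")
    chosen = cand.iloc[sorted(rng.choice(len(cand), size=sc.n_linked_pairs,
                                         replace=False))]

    ns = sc.n_link_samples
    samples = [f"T{i:03d}" for i in range(ns)]
    sig = rng.normal(size=(len(link_peaks), ns))
    expr = rng.normal(size=(len(expr_genes), ns))
    noise_sd = float(np.sqrt(1.0 / sc.link_rho - 1.0))
    peak_pos = link_peaks.index.get_indexer(chosen["peak"])
    gene_pos = expr_genes.get_indexer(chosen["gene"])
    latent = rng.normal(size=(len(chosen), ns))
    sig[peak_pos] = latent + rng.normal(scale=noise_sd, size=(len(chosen), ns))
    expr[gene_pos] = latent + rng.normal(scale=noise_sd, size=(len(chosen), ns))

    peak_signal = pd.DataFrame(sig, index=link_peaks.index, columns=samples)
    expression = pd.DataFrame(expr, index=expr_genes, columns=samples)
    truth = {"linked_pairs": [(p, g) for p, g in zip(chosen["peak"], chosen["gene"])],
             "link_rho": sc.link_rho}
    return peak_signal, expression, link_peaks, truth


def gen_saint(scenario: SyntheticScenario | None = None):
    """SAINT-style bait-prey table with planted true interactors.

    True interactors have high spectral counts in their baits (mean
    ``saint_true_mean``) and low BFDR; background preys track the control
    counts. BFDR and fold change are written from a simple planted model
    (the upstream scorer's probability model is consumed, not
    reimplemented).

    Returns (counts, stats, truth) where ``truth['true_preys']`` maps
    bait -> planted prey list.
    """
    from .bioid import BAITS

    sc = scenario or SyntheticScenario()
    rng = sc.rng(7)
    preys = {}
    idx = 0

    def take(n, tag):
        nonlocal idx
        out = [f"prey{idx + i:04d}_{tag}" for i in range(n)]
        idx += n
        return out

    common_all = take(sc.n_common_all_preys, "all")
    s_only = take(sc.n_s_only_preys, "s")
    l_only = take(sc.n_l_only_preys, "l")
    singles = {b: take(sc.n_single_bait_preys, f"x{i}") for i, b in enumerate(BAITS)}
    background = take(sc.n_background_preys, "bg")

    true_preys = {b: set(common_all) for b in BAITS}
    for b in ("MAF-S-N", "MAF-S-C"):
        true_preys[b] |= set(s_only)
    for b in ("MAF-L-N", "MAF-L-C"):
        true_preys[b] |= set(l_only)
    for b in BAITS:
        true_preys[b] |= set(singles[b])
    all_preys = common_all + s_only + l_only + sum(singles.values(), []) + background

    rows = []
    for bait in list(BAITS) + ["control"]:
        for prey in all_preys:
            is_true = bait != "control" and prey in true_preys[bait]
            mean = sc.saint_true_mean if is_true else sc.saint_ctrl_mean
            for rep in range(1, sc.saint_n_reps + 1):
                for engine in ("PD", "MQ"):
                    scale = rng.uniform(0.7, 1.0)  # engines quantify slightly differently
                    rows.append((bait, prey, rep, engine,
                                 int(_nb_draw(rng, np.array([mean * scale]),
                                              sc.dispersion)[0])))
    counts = pd.DataFrame(rows, columns=["bait", "prey", "replicate", "engine", "count"])

    from .bioid import merge_engine_counts, select_top_replicates
    merged = merge_engine_counts(counts)
    top = select_top_replicates(merged, k=3)
    avg = top.groupby(["bait", "prey"])["count"].mean()
    ctrl = avg.loc["control"]
    stats_rows = []
    for bait in BAITS:
        for prey in all_preys:
            a = float(avg.loc[(bait, prey)])
            fc = a / max(float(ctrl.loc[prey]), 0.4)
            is_true = prey in true_preys[bait]
            bfdr = rng.uniform(0.0, 0.018) if is_true else rng.uniform(0.03, 0.95)
            stats_rows.append((bait, prey, a, fc, bfdr))
    stats = pd.DataFrame(stats_rows,
                         columns=["bait", "prey", "avg_spec", "fold_change", "bfdr"])
    truth = {"true_preys": {b: sorted(s) for b, s in true_preys.items()},
             "background_preys": background}
    return counts, stats, truth


def gen_survival(scenario: SyntheticScenario | None = None):
    """Survival cohort with a planted signature hazard effect.

    A latent signature activity s ~ N(0,1) drives the expression of the
    signature genes; samples with s below mean - 1 SD form the planted
    low group, whose event hazard is multiplied by ``hazard_ratio``
    (so low signature expression = higher risk when HR > 1). Times are
    exponential, censoring independent uniform on (0, censor_max].

    Returns (expression, cohort, truth).
    """
    sc = scenario or SyntheticScenario()
    if sc.hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    rng = sc.rng(8)
    n = sc.n_cohort
    samples = [f"pt{i:03d}" for i in range(n)]
    sig_genes = [f"sig{i:03d}" for i in range(sc.n_signature_genes)]
    noise_genes = [f"bg{i:03d}" for i in range(sc.n_noise_genes)]
    s = rng.normal(size=n)
    expr_sig = s[None, :] + rng.normal(scale=0.7, size=(len(sig_genes), n))
    expr_noise = rng.normal(size=(len(noise_genes), n))
    expression = pd.DataFrame(np.vstack([expr_sig, expr_noise]),
                              index=sig_genes + noise_genes, columns=samples)
    low = s < (s.mean() - s.std(ddof=1))
    hazard = sc.baseline_hazard * np.where(low, sc.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, sc.censor_max, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    cohort = pd.DataFrame({"sample": samples,
                           "time": np.clip(time, 1e-3, None),
                           "event": event,
                           "her2": rng.integers(0, 2, size=n),
                           "stage": rng.integers(1, 4, size=n)})
    truth = {"signature_genes": sig_genes, "planted_low": [samples[i] for i in np.flatnonzero(low)],
             "hazard_ratio": sc.hazard_ratio}
    return expression, cohort, truth


def write_scenario(scenario: SyntheticScenario, outdir) -> dict:
    """Generate every dataset of a scenario and write it in the formats the
    pipeline reads, plus a ground-truth JSON sidecar per dataset.
    Returns the manifest of written paths."""
    from pathlib import Path

    from . import io as eio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = gen_genome(scenario)
    eio.write_gene_tsv(genome.genes, out / "genes.tsv")

    counts, design, truth_genes = gen_counts(scenario)
    eio.write_matrix_tsv(counts, out / "gene_counts.tsv", index_label="gene_id")
    design.to_csv(out / "design.tsv", sep="\t", index=False)
    eio.write_json({"true_cluster": truth_genes["true_cluster"].to_dict()},
                   out / "gene_counts.truth.json")

    peaks, pcounts, pdesign, truth_peaks = gen_peaks(scenario, genome)
    bed = peaks.reset_index().rename(columns={"index": "name"})
    eio.write_bed(bed.assign(score=0, strand=".")[["chrom", "start", "end", "name",
                                                   "score", "strand"]], out / "peaks.bed")
    eio.write_matrix_tsv(pcounts, out / "peak_counts.tsv", index_label="peak_id")
    pdesign.to_csv(out / "peak_design.tsv", sep="\t", index=False)
    eio.write_json({"true_cluster": truth_peaks["true_cluster"].to_dict(),
                    "true_category": truth_peaks["true_category"].to_dict()},
                   out / "peaks.truth.json")

    chip_sets, chip_truth = gen_chip(scenario, genome, peaks, truth_peaks)
    for name, df in chip_sets.items():
        eio.write_bed(df.reset_index().rename(columns={"index": "name"})
                      .assign(score=0, strand=".")[["chrom", "start", "end", "name",
                                                    "score", "strand"]],
                      out / f"chip_{name}.bed")
    eio.write_json(chip_truth, out / "chip.truth.json")

    peak_signal, expression, link_peaks, link_truth = gen_links_data(scenario, genome, peaks)
    eio.write_matrix_tsv(peak_signal, out / "link_peak_signal.tsv", index_label="peak_id")
    eio.write_matrix_tsv(expression, out / "link_expression.tsv", index_label="gene_id")
    eio.write_json(link_truth, out / "links.truth.json")

    counts_saint, stats_saint, truth_saint = gen_saint(scenario)
    counts_saint.rename(columns={"bait": "Bait", "prey": "Prey", "replicate": "Replicate",
                                 "engine": "Engine", "count": "Spec"}).to_csv(
        out / "saint_counts.tsv", sep="\t", index=False)
    stats_saint.rename(columns={"bait": "Bait", "prey": "Prey", "avg_spec": "AvgSpec",
                                "fold_change": "FoldChange", "bfdr": "BFDR"}).to_csv(
        out / "saint_stats.tsv", sep="\t", index=False)
    eio.write_json(truth_saint, out / "saint.truth.json")

    surv_expr, cohort, truth_surv = gen_survival(scenario)
    eio.write_matrix_tsv(surv_expr, out / "cohort_expression.tsv", index_label="gene_id")
    cohort.to_csv(out / "cohort_survival.tsv", sep="\t", index=False)
    eio.write_json(truth_surv, out / "survival.truth.json")

    return {"outdir": str(out), "seed": scenario.seed,
            "files": sorted(p.name for p in out.iterdir())}
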