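"""Promoter-enhancer links from peak-signal / gene-expression correlation.

A candidate link is any (peak, gene) pair whose peak midpoint lies within
500 kb of the gene's TSS. Spearman correlation of the peak's
accessibility signal with the gene's expression across shared samples is
computed for every candidate pair, Benjamini-Hochberg adjusted over all
tested pairs, and pairs with positive correlation passing the FDR cutoff
are retained as links.

``link_enrichment_test`` then asks whether a candidate peak set (e.g.
MAF/ER-bound peaks) is linked to target-gene promoters more often than
equally sized random peak selections (default 10,000 iterations).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import GenomeModel, midpoint

MAX_DIST_DEFAULT = 500_000
MAX_EXHAUSTIVE = 500_000


@dataclass
class LinkEnrichmentResult:
    observed_percent: float
    null_values: np.ndarray
    n_iter: int
    p_value: float
    seed: int | None
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {"observed_percent": float(self.observed_percent),
                "p_value": float(self.p_value), "n_iter": int(self.n_iter),
                "null_mean": float(np.mean(self.null_values)),
                "seed": self.seed, "exhaustive": self.exhaustive}


def _candidate_pairs(peaks: pd.DataFrame, genome: GenomeModel, max_dist: int):
    """(peak position index, gene position index, signed distance) for all
    pairs with |peak midpoint - TSS| <= max_dist."""
    genes = genome.genes
    peak_rows, gene_rows, dists = [], [], []
    gene_pos_by_chrom = {c: sub.index.to_numpy() for c, sub in genes.groupby("chrom")}
    mids_all = midpoint(peaks["start"].to_numpy(), peaks["end"].to_numpy())
    for chrom, sub_idx in peaks.groupby("chrom").groups.items():
        if chrom not in gene_pos_by_chrom:
            continue
        gpos = gene_pos_by_chrom[chrom]
        tss = genes.loc[gpos, "tss"].to_numpy()
        order = np.argsort(tss)
        tss_sorted, gpos_sorted = tss[order], gpos[order]
        ploc = peaks.index.get_indexer(sub_idx)
        mids = mids_all[ploc]
        lo = np.searchsorted(tss_sorted, mids - max_dist, side="left")
        hi = np.searchsorted(tss_sorted, mids + max_dist, side="right")
        for p, m, a, b in zip(ploc, mids, lo, hi):
            for g in range(a, b):
                peak_rows.append(p)
                gene_rows.append(gpos_sorted[g])
                dists.append(int(m - tss_sorted[g]))
    return np.array(peak_rows, dtype=int), np.array(gene_rows, dtype=int), np.array(dists, dtype=int)


def build_links(peak_signal: pd.DataFrame,
                expression: pd.DataFrame,
                peaks: pd.DataFrame,
                genome: GenomeModel,
                max_dist: int = MAX_DIST_DEFAULT,
                fdr: float = 0.05) -> pd.DataFrame:
    """Build the promoter-enhancer link table.

    Parameters
    ----------
    peak_signal
        Peaks-by-samples signal matrix (index matching ``peaks``).
    expression
        Genes-by-samples expression matrix.
    peaks
        Peak interval table (chrom/start/end), index = peak ids.
    max_dist
        Maximum |peak midpoint - TSS| for a pair to be tested (bp).
    fdr
        BH-adjusted p cutoff; only positively correlated pairs are kept.

    Returns
    -------
    DataFrame with columns peak_id, gene_id, distance, rho, pvalue, padj.
    """
    shared = peak_signal.columns.intersection(expression.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between signal and expression")
    if len(shared) < 8:
        raise ValueError(f"need >=8 shared samples for stable correlation, got {len(shared)}")
    sig = peak_signal[shared]
    expr = expression[shared]
    prow, grow, dist = _candidate_pairs(peaks, genome, max_dist)
    genes = genome.genes
    # drop pairs whose gene has no expression row
    gene_ids_all = genes["gene_id"].to_numpy()
    has_expr = pd.Index(gene_ids_all[grow]).isin(expr.index)
    prow, grow, dist = prow[has_expr], grow[has_expr], dist[has_expr]
    if len(prow) == 0:
        return pd.DataFrame(columns=["peak_id", "gene_id", "distance", "rho", "pvalue", "padj"])

    n = len(shared)
    sig_rank = np.apply_along_axis(sps.rankdata, 1, sig.to_numpy(float))
    expr_rank = np.apply_along_axis(sps.rankdata, 1, expr.to_numpy(float))
    sig_rank -= sig_rank.mean(axis=1, keepdims=True)
    expr_rank -= expr_rank.mean(axis=1, keepdims=True)
    sig_norm = np.sqrt((sig_rank ** 2).sum(axis=1))
    expr_norm = np.sqrt((expr_rank ** 2).sum(axis=1))
    expr_pos = expr.index.get_indexer(gene_ids_all[grow])

    num = np.einsum("ij,ij->i", sig_rank[prow], expr_rank[expr_pos])
    den = sig_norm[prow] * expr_norm[expr_pos]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    # asymptotic t-test for Spearman rho, as in scipy.stats.spearmanr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1.0 - rho ** 2, 1e-300, None))
    pvalue = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    padj = sps.false_discovery_control(pvalue, method="bh")
    table = pd.DataFrame({
        "peak_id": peaks.index.to_numpy()[prow],
        "gene_id": gene_ids_all[grow],
        "distance": dist,
        "rho": rho,
        "pvalue": pvalue,
        "padj": padj,
    })
    return table[(table["padj"] <= fdr) & (table["rho"] > 0)].reset_index(drop=True)


def link_enrichment_test(candidate_peaks,
                         target_promoters,
                         links: pd.DataFrame,
                         all_peaks,
                         n_iter: int = 10_000,
                         seed: int | None = None,
                         exhaustive: bool = False) -> LinkEnrichmentResult:
    """Percentage of candidate peaks linked to a target-gene promoter,
    against random equally sized peak selections (without replacement).

    One-tailed; sampled p uses the add-one convention, exhaustive mode
    enumerates all subsets exactly.
    """
    all_peaks = np.asarray(sorted(set(all_peaks)))
    candidates = sorted(set(candidate_peaks))
    if len(candidates) == 0:
        raise ValueError("empty candidate peak set")
    if not set(candidates) <= set(all_peaks.tolist()):
        raise ValueError("candidate peaks must be a subset of all peaks")
    targets = set(target_promoters)
    linked_peaks = set(links.loc[links["gene_id"].isin(targets), "peak_id"])
    indicator = np.isin(all_peaks, list(linked_peaks))
    cand_pos = np.isin(all_peaks, candidates)
    observed = 100.0 * indicator[cand_pos].mean()
    k = len(candidates)
    n = len(all_peaks)
    if exhaustive:
        total = comb(n, k)
        if total > MAX_EXHAUSTIVE:
            raise ValueError(f"{total} subsets exceed enumeration limit")
        null = np.array([100.0 * indicator[list(sub)].mean()
                         for sub in combinations(range(n), k)])
        p = float(np.mean(null >= observed - 1e-12))
        return LinkEnrichmentResult(observed, null, len(null), p, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n, size=k, replace=False)
        null[i] = 100.0 * indicator[idx].mean()
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_iter)
    return LinkEnrichmentResult(observed, null, n_iter, float(p), seed)
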