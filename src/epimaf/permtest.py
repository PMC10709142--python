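"""One-tailed permutation tests for peak-set enrichment.

The null model draws random subsets of the consensus peak universe of the
same size as the tested cluster and recomputes the statistic (a category
percentage or a histone-mark overlap percentage). Sampling is without
replacement, so real consensus peaks — and therefore their widths and
genomic context — make up every null draw.

Sampled p-values use the add-one convention p = (1 + #{null >= obs}) /
(1 + n_iter), which is never zero. When the number of distinct subsets is
small, ``exhaustive=True`` enumerates them all and returns the exact
p-value #{subsets >= obs} / n_subsets (the observed cluster is itself one
of the enumerated subsets, so p > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import peaks_overlapping_any

MAX_EXHAUSTIVE = 500_000


@dataclass
class PermutationResult:
    observed_value: float      # percentage, 0..100
    null_values: np.ndarray
    n_iter: int
    p_value: float
    seed: int | None
    exhaustive: bool = False

    def to_dict(self) -> dict:
        return {
            "observed": float(self.observed_value),
            "p_value": float(self.p_value),
            "n_iter": int(self.n_iter),
            "null_mean": float(np.mean(self.null_values)),
            "seed": self.seed,
            "exhaustive": self.exhaustive,
        }


def _subset_percentage_test(indicator: np.ndarray, cluster_size: int,
                            observed: float, n_iter: int,
                            seed: int | None, exhaustive: bool) -> PermutationResult:
    n = len(indicator)
    if cluster_size > n:
        raise ValueError("cluster larger than consensus universe")
    if exhaustive:
        total = comb(n, cluster_size)
        if total > MAX_EXHAUSTIVE:
            raise ValueError(
                f"{total} subsets exceed the exhaustive-enumeration limit")
        null = np.array([
            100.0 * indicator[list(sub)].mean()
            for sub in combinations(range(n), cluster_size)
        ])
        # strict float comparisons are safe: every value is (100*k)/size
        p = float(np.mean(null >= observed - 1e-12))
        return PermutationResult(observed, null, len(null), p, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(n, size=cluster_size, replace=False)
        null[i] = 100.0 * indicator[idx].mean()
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + n_iter)
    return PermutationResult(observed, null, n_iter, float(p), seed)


def _cluster_positions(cluster_peaks: pd.DataFrame, consensus_peaks: pd.DataFrame) -> np.ndarray:
    """Indices of cluster peaks inside the consensus table (by shared index)."""
    pos = consensus_peaks.index.get_indexer(cluster_peaks.index)
    if (pos < 0).any():
        raise ValueError("cluster peaks must be a subset of consensus peaks "
                         "(shared index ids)")
    return pos


def category_enrichment_test(cluster_peaks: pd.DataFrame,
                             consensus_peaks: pd.DataFrame,
                             category: str,
                             n_iter: int = 1000,
                             seed: int | None = None,
                             exhaustive: bool = False) -> PermutationResult:
    """Is the cluster's percentage of peaks in ``category`` higher than in
    random consensus subsets of equal size? One-tailed (enrichment).

    Both peak tables must be annotated (``category`` column) and the
    cluster must be an index-subset of the consensus.
    """
    if "category" not in consensus_peaks.columns:
        raise ValueError("consensus peaks must be annotated")
    pos = _cluster_positions(cluster_peaks, consensus_peaks)
    indicator = (consensus_peaks["category"] == category).to_numpy()
    observed = 100.0 * indicator[pos].mean()
    return _subset_percentage_test(indicator, len(pos), observed, n_iter, seed,
                                   exhaustive)


def mark_overlap_test(cluster_peaks: pd.DataFrame,
                      consensus_peaks: pd.DataFrame,
                      mark_peaks: pd.DataFrame | list[pd.DataFrame],
                      n_iter: int = 1000,
                      seed: int | None = None,
                      max_gap: int = 100,
                      exhaustive: bool = False) -> PermutationResult:
    """Is the cluster's percentage of peaks overlapping a histone-mark peak
    (within ``max_gap`` bp, default 100) enriched over consensus subsets?

    ``mark_peaks`` may be one peak table or a list (e.g. H3K27ac and
    H3K4me3 together); a peak counts as overlapping if it overlaps any.
    """
    marks = mark_peaks if isinstance(mark_peaks, list) else [mark_peaks]
    if not marks or all(len(m) == 0 for m in marks):
        raise ValueError("empty mark peak set")
    pos = _cluster_positions(cluster_peaks, consensus_peaks)
    indicator = np.zeros(len(consensus_peaks), dtype=bool)
    for m in marks:
        indicator |= peaks_overlapping_any(consensus_peaks, m, max_gap=max_gap)
    observed = 100.0 * indicator[pos].mean()
    return _subset_percentage_test(indicator, len(pos), observed, n_iter, seed,
                                   exhaustive)


def breadth_compare(peaks_group1: pd.DataFrame, peaks_group2: pd.DataFrame):
    """Two-sided Wilcoxon rank-sum test on peak breadth (log10 width).

    Normal approximation with tie correction. Returns (statistic, p).
    """
    if len(peaks_group1) == 0 or len(peaks_group2) == 0:
        raise ValueError("both peak groups must be non-empty")
    b1 = np.log10((peaks_group1["end"] - peaks_group1["start"]).to_numpy())
    b2 = np.log10((peaks_group2["end"] - peaks_group2["start"]).to_numpy())
    pooled = np.concatenate([b1, b2])
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    res = sps.mannwhitneyu(b1, b2, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)
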