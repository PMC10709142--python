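"""Super-enhancer identification by stitch-and-rank.

H3K27ac peaks are stitched single-linkage within 12.5 kb (peaks fully
contained in a promoter window, TSS +/- 2 kb, are excluded from
stitching), the stitched enhancers are scored by target signal minus
input signal (floored at 0), and super-enhancers are called by the
classic tangent rule on the ranked score curve: with ranks and scores
both scaled to [0, 1], the cutoff is the point where a slope-1 line is
tangent to the curve from below; enhancers scoring above it are super.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel

STITCH_DIST_DEFAULT = 12_500
PROMOTER_EXCLUSION_DEFAULT = 2_000


@dataclass
class StitchedEnhancer:
    chrom: str
    start: int
    end: int
    constituents: tuple
    score: float = float("nan")
    is_super: bool = False


def _promoter_contained(peaks: pd.DataFrame, genome: GenomeModel,
                        window: int) -> np.ndarray:
    """True for peaks fully contained in some TSS +/- window interval
    (window inclusive at both edges)."""
    contained = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in peaks.groupby("chrom"):
        gsub = genome.genes[genome.genes["chrom"] == chrom]
        if len(gsub) == 0:
            continue
        tss = np.sort(gsub["tss"].to_numpy())
        loc = peaks.index.get_indexer(sub.index)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # containment in [t - w, t + w] (inclusive) for some t:
        # start >= t - w  and  end - 1 <= t + w
        # -> exists tss in [end - 1 - w, start + w]
        lo = np.searchsorted(tss, ends - 1 - window, side="left")
        hi = np.searchsorted(tss, starts + window, side="right")
        contained[loc] = hi > lo
    return contained


def stitch_enhancers(mark_peaks: pd.DataFrame,
                     genome: GenomeModel | None = None,
                     stitch_dist: int = STITCH_DIST_DEFAULT,
                     promoter_exclusion: int = PROMOTER_EXCLUSION_DEFAULT) -> pd.DataFrame:
    """Stitch mark peaks into enhancer regions.

    Peaks whose gap (start of next minus end of previous) is <=
    ``stitch_dist`` are chained; 12,500 bp apart stitches, 12,501 does
    not. If a genome is supplied, peaks fully contained in TSS +/-
    ``promoter_exclusion`` are dropped before stitching.

    Returns a DataFrame (chrom, start, end, constituents, n_constituents)
    with constituents the tuple of stitched peak ids.
    """
    peaks = mark_peaks
    if genome is not None and genome.n_genes > 0:
        keep = ~_promoter_contained(peaks, genome, promoter_exclusion)
        peaks = peaks.loc[keep]
    rows = []
    for chrom, sub in peaks.groupby("chrom"):
        srt = sub.sort_values(["start", "end"], kind="mergesort")
        starts = srt["start"].to_numpy()
        ends = srt["end"].to_numpy()
        ids = srt.index.to_numpy()
        i = 0
        while i < len(srt):
            j = i
            cur_end = ends[i]
            while j + 1 < len(srt) and starts[j + 1] - cur_end <= stitch_dist:
                j += 1
                cur_end = max(cur_end, ends[j])
            rows.append((chrom, int(starts[i]), int(cur_end), tuple(ids[i:j + 1]), j - i + 1))
            i = j + 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "constituents",
                                      "n_constituents"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def rank_super_enhancers(stitched: pd.DataFrame,
                         target_signal: np.ndarray,
                         input_signal: np.ndarray | None = None) -> pd.DataFrame:
    """Rank stitched enhancers and flag super-enhancers.

    Score = max(target - input, 0). With enhancers sorted by ascending
    score and both axes scaled to [0, 1], the cutoff score is taken at the
    point minimizing (scaled score - scaled rank) — the tangent point of a
    slope-1 line — and enhancers scoring strictly above it are flagged.
    The flags are invariant to uniform rescaling of the signal.
    """
    if len(stitched) < 3:
        raise ValueError("need >=3 stitched enhancers to place a cutoff")
    target = np.asarray(target_signal, dtype=float)
    inp = np.zeros_like(target) if input_signal is None else np.asarray(input_signal, dtype=float)
    if len(target) != len(stitched) or len(inp) != len(stitched):
        raise ValueError("signal length must match number of stitched enhancers")
    score = np.clip(target - inp, 0.0, None)
    out = stitched.copy()
    out["score"] = score
    out["rank"] = score.argsort().argsort()  # ascending rank, 0-based
    smax = score.max()
    if smax <= 0:
        out["is_super"] = False
        return out
    order = np.argsort(score, kind="mergesort")
    y = score[order] / smax
    x = np.arange(len(score)) / (len(score) - 1)
    tangent_idx = int(np.argmin(y - x))
    cutoff = score[order][tangent_idx]
    out["is_super"] = score > cutoff
    return out
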