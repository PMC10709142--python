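"""Motif overrepresentation statistics for peak regions.

Motif scanning itself (position-weight-matrix matching) is out of scope:
match genome positions are an input. Given X observed matches inside the
regions, the expected count in an equally sized sample of the genome is
modelled binomially — matches assumed uniformly distributed, each falling
in the regions with probability p = region_bp / genome_bp:

    E = n * p,   S = sqrt(n * p * (1 - p)),
    fold = X / E,   z = (X - E - 0.5) / S   (continuity corrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MotifEnrichment:
    X: int
    E: float
    S: float
    fold: float
    z: float
    region_total_bp: int
    genome_total_bp: int
    genome_match_count: int
    sequences_with_match: int | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("X", "E", "S", "fold", "z", "region_total_bp",
                 "genome_total_bp", "genome_match_count", "sequences_with_match")}


def expected_matches(region_total_bp: int, genome_total_bp: int,
                     genome_match_count: int) -> tuple[float, float]:
    """Binomial expectation and SD of the in-region match count."""
    if genome_total_bp <= 0:
        raise ValueError("genome size must be positive")
    if not (0 < region_total_bp <= genome_total_bp):
        raise ValueError("region size must be in (0, genome size]")
    if genome_match_count < 0:
        raise ValueError("genome match count must be non-negative")
    p = region_total_bp / genome_total_bp
    E = genome_match_count * p
    S = float(np.sqrt(genome_match_count * p * (1.0 - p)))
    return float(E), S


def motif_zscore(X: float, E: float, S: float) -> float:
    """Continuity-corrected overrepresentation z-score (X - E - 0.5) / S."""
    if S <= 0:
        raise ValueError("S must be positive; for S = 0 use an exact binomial test")
    return float((X - E - 0.5) / S)


def motif_fold(X: float, E: float) -> float:
    """Fold overrepresentation X / E."""
    if E <= 0:
        raise ValueError("E must be positive")
    return float(X / E)


def count_motif_matches(regions: pd.DataFrame, matches: pd.DataFrame) -> tuple[int, int]:
    """Count motif matches inside regions.

    Parameters
    ----------
    regions
        Peak table (chrom/start/end, half-open).
    matches
        Match positions: DataFrame with ``chrom`` and ``pos`` columns.

    Returns
    -------
    (X, sequences_with_match): total matches falling inside at least one
    region (each match counted once), and the number of regions containing
    at least one match.
    """
    X = 0
    with_match = 0
    match_by_chrom = {c: np.sort(sub["pos"].to_numpy())
                      for c, sub in matches.groupby("chrom")}
    for chrom, sub in regions.groupby("chrom"):
        pos = match_by_chrom.get(chrom)
        if pos is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        with_match += int((hi > lo).sum())
        # count each match once even if regions overlap
        covered = np.zeros(len(pos), dtype=bool)
        for a, b in zip(lo, hi):
            covered[a:b] = True
        X += int(covered.sum())
    return X, with_match


def motif_enrichment(regions: pd.DataFrame, matches: pd.DataFrame,
                     genome_total_bp: int,
                     genome_match_count: int | None = None) -> MotifEnrichment:
    """Full overrepresentation summary for one motif over a region set.

    ``genome_match_count`` defaults to the number of supplied match
    positions (i.e. the input is the genome-wide match list).
    """
    X, seqs = count_motif_matches(regions, matches)
    region_total_bp = int((regions["end"] - regions["start"]).sum())
    n = len(matches) if genome_match_count is None else genome_match_count
    E, S = expected_matches(region_total_bp, genome_total_bp, n)
    return MotifEnrichment(X=X, E=E, S=S, fold=motif_fold(X, E) if E > 0 else float("nan"),
                           z=motif_zscore(X, E, S) if S > 0 else float("nan"),
                           region_total_bp=region_total_bp,
                           genome_total_bp=genome_total_bp,
                           genome_match_count=n, sequences_with_match=seqs)


def scan_exact_string(sequences: dict[str, str], motif: str) -> pd.DataFrame:
    """Toy exact-string motif scanner for tests: returns match start
    positions of ``motif`` (forward strand only) per sequence."""
    rows = []
    m = motif.upper()
    for chrom, seq in sequences.items():
        s = seq.upper()
        start = s.find(m)
        while start != -1:
            rows.append((chrom, start))
            start = s.find(m, start + 1)
    return pd.DataFrame(rows, columns=["chrom", "pos"])
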