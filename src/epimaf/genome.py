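"""Genomic interval arithmetic and peak-to-gene annotation.

All coordinates are 0-based half-open (``start`` inclusive, ``end``
exclusive), the BED convention. Peaks are represented by their midpoint for
annotation and distance purposes. Three broad annotation categories are
used throughout the pipeline:

``promoter-TSS``
    peak midpoint within +/- 2 kb of any transcription start site;
``gene-body``
    midpoint inside a gene span but outside every promoter window;
``intergenic``
    everything else.

Signed TSS distances follow gene orientation: positive values lie
downstream of the TSS (into the gene for the nearest gene), negative
values upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROMOTER_WINDOW = 2000  # bp each side of the TSS, inclusive at both edges

CATEGORY_PROMOTER = "promoter-TSS"
CATEGORY_GENE_BODY = "gene-body"
CATEGORY_INTERGENIC = "intergenic"
CATEGORIES = (CATEGORY_PROMOTER, CATEGORY_GENE_BODY, CATEGORY_INTERGENIC)

GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


class GenomeError(ValueError):
    """Raised for unusable genome models (no genes, bad coordinates)."""


@dataclass
class GenomeModel:
    """A chromosome-size map plus a gene table.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``.
        A ``tss`` column is derived on construction: ``start`` for ``+``
        genes and ``end - 1`` for ``-`` genes.
    """

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(GENE_COLUMNS)))

    def __post_init__(self) -> None:
        g = self.genes.copy()
        missing = [c for c in GENE_COLUMNS if c not in g.columns]
        if missing:
            raise GenomeError(f"gene table missing columns: {missing}")
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise GenomeError(f"duplicate gene id: {dup!r}")
        if len(g):
            if (g["start"] >= g["end"]).any() or (g["start"] < 0).any():
                raise GenomeError("gene spans must satisfy 0 <= start < end")
            if not g["strand"].isin(["+", "-"]).all():
                raise GenomeError("gene strand must be '+' or '-'")
            for chrom, sub in g.groupby("chrom"):
                size = self.chrom_sizes.get(chrom)
                if size is None:
                    raise GenomeError(f"gene chromosome {chrom!r} absent from chrom_sizes")
                if int(sub["end"].max()) > size:
                    raise GenomeError(f"gene span exceeds chromosome {chrom!r} length")
            g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        else:
            g["tss"] = pd.Series(dtype=int)
        self.genes = g.reset_index(drop=True)
        self._index = _GeneIndex(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def total_size(self) -> int:
        return int(sum(self.chrom_sizes.values()))


class _GeneIndex:
    """Per-chromosome sorted TSS and span arrays for O(log n) queries."""

    def __init__(self, genes: pd.DataFrame):
        self.by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in genes.groupby("chrom"):
            # Collapse genes sharing a TSS position to the lexicographically
            # smallest id so equidistance ties resolve deterministically.
            rep = (sub.sort_values(["tss", "gene_id"], kind="mergesort")
                      .groupby("tss", as_index=False).first())
            span_sorted = sub.sort_values("start", kind="mergesort")
            self.by_chrom[chrom] = {
                "tss": rep["tss"].to_numpy(),
                "tss_gene": rep["gene_id"].to_numpy(),
                "tss_strand": rep["strand"].to_numpy(),
                "span_start": span_sorted["start"].to_numpy(),
                "span_end_cummax": np.maximum.accumulate(span_sorted["end"].to_numpy()),
            }


@dataclass(frozen=True)
class AnnotationLabel:
    """Annotation of a single peak: category, nearest gene, signed distance."""

    value: str
    nearest_gene: str | None
    tss_distance: float


def midpoint(start, end):
    """Integer midpoint of a half-open interval (floor division)."""
    return (np.asarray(start) + np.asarray(end)) // 2


def peak_breadth(start, end):
    """Peak breadth: log10 of the peak width in bp (width must be >= 1)."""
    width = np.asarray(end) - np.asarray(start)
    if np.any(width < 1):
        raise ValueError("peak width must be >= 1")
    return np.log10(width)


def overlaps(a: tuple, b: tuple, max_gap: int = 0) -> bool:
    """True iff two intervals are within ``max_gap`` bp of each other.

    Intervals are ``(chrom, start, end)`` triples, half-open. Overlapping
    or book-ended intervals have gap 0; different chromosomes never
    overlap. The gap between [100,200) and [300,400) is 100.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    chrom_a, start_a, end_a = a
    chrom_b, start_b, end_b = b
    if chrom_a != chrom_b:
        return False
    gap = max(start_b - end_a, start_a - end_b, 0)
    return gap <= max_gap


def _nearest_tss(genome: GenomeModel, chrom: str, mids: np.ndarray):
    """Nearest gene (by |midpoint - tss|, ties -> lexicographic id) and the
    orientation-signed distance, vectorized over midpoints on one chromosome.

    Returns (gene_ids: object array, signed_distance: float array). Midpoints
    on chromosomes without genes get (None, nan).
    """
    idx = genome._index.by_chrom.get(chrom)
    n = len(mids)
    if idx is None:
        return np.full(n, None, dtype=object), np.full(n, np.nan)
    tss = idx["tss"]
    names = idx["tss_gene"]
    strands = idx["tss_strand"]
    pos = np.searchsorted(tss, mids)
    left = np.clip(pos - 1, 0, len(tss) - 1)
    right = np.clip(pos, 0, len(tss) - 1)
    dl = np.abs(mids - tss[left])
    dr = np.abs(mids - tss[right])
    # Prefer the smaller distance; on an exact distance tie between distinct
    # TSS positions, take the lexicographically smaller gene id. Because the
    # index is sorted by (tss, gene_id), the first entry at a tied position
    # already carries the smallest id for that position.
    use_left = (dl < dr) | ((dl == dr) & (names[left] <= names[right]))
    best = np.where(use_left, left, right)
    # When the nearest distance is matched by the neighbouring TSS position on
    # the other side we must still honour the id tie-break; the where() above
    # already compared exactly the two candidates, so `best` is final.
    gene = names[best]
    strand = strands[best]
    raw = mids - tss[best]
    signed = np.where(strand == "+", raw, -raw).astype(float)
    return gene.astype(object), signed


def _in_gene_body(genome: GenomeModel, chrom: str, mids: np.ndarray) -> np.ndarray:
    idx = genome._index.by_chrom.get(chrom)
    if idx is None:
        return np.zeros(len(mids), dtype=bool)
    starts = idx["span_start"]
    end_cummax = idx["span_end_cummax"]
    pos = np.searchsorted(starts, mids, side="right")
    inside = np.zeros(len(mids), dtype=bool)
    has_left = pos > 0
    inside[has_left] = end_cummax[pos[has_left] - 1] > mids[has_left]
    return inside


def annotate_peaks(peaks: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Annotate a peak table with category, nearest gene and TSS distance.

    Parameters
    ----------
    peaks
        DataFrame with ``chrom, start, end`` columns (0-based half-open).
    genome
        Active genome model; must contain at least one gene.

    Returns
    -------
    Copy of ``peaks`` with ``category``, ``nearest_gene`` and
    ``tss_distance`` columns appended. The three categories partition the
    peak set.
    """
    if genome.n_genes == 0:
        raise GenomeError("genome model has no genes; annotation undefined")
    out = peaks.copy()
    n = len(out)
    category = np.full(n, CATEGORY_INTERGENIC, dtype=object)
    nearest = np.full(n, None, dtype=object)
    dist = np.full(n, np.nan)
    mids_all = midpoint(out["start"].to_numpy(), out["end"].to_numpy())
    for chrom, sub_idx in out.groupby("chrom").groups.items():
        loc = out.index.get_indexer(sub_idx)
        mids = mids_all[loc]
        gene, signed = _nearest_tss(genome, chrom, mids)
        nearest[loc] = gene
        dist[loc] = signed
        promoter = np.abs(signed) <= PROMOTER_WINDOW
        body = _in_gene_body(genome, chrom, mids) & ~promoter
        cat = np.where(promoter, CATEGORY_PROMOTER,
                       np.where(body, CATEGORY_GENE_BODY, CATEGORY_INTERGENIC))
        category[loc] = cat
    out["category"] = category
    out["nearest_gene"] = nearest
    out["tss_distance"] = dist
    return out


def annotate_peak(peak: tuple, genome: GenomeModel) -> AnnotationLabel:
    """Annotate a single ``(chrom, start, end)`` peak. See annotate_peaks."""
    chrom, start, end = peak
    df = pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]})
    row = annotate_peaks(df, genome).iloc[0]
    return AnnotationLabel(value=row["category"], nearest_gene=row["nearest_gene"],
                           tss_distance=float(row["tss_distance"]))


def distance_to_tss(peak: tuple, genome: GenomeModel) -> float:
    """Orientation-signed distance from the peak midpoint to the nearest TSS.

    Positive downstream of the TSS in gene orientation, negative upstream;
    0 at the TSS itself.
    """
    return annotate_peak(peak, genome).tss_distance


def peaks_overlapping_any(peaks: pd.DataFrame, others: pd.DataFrame,
                          max_gap: int = 0) -> np.ndarray:
    """Boolean array: does each peak lie within ``max_gap`` of any interval
    in ``others``? Vectorized equivalent of all-pairs :func:`overlaps`."""
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    hit = np.zeros(len(peaks), dtype=bool)
    by_chrom = {}
    for chrom, sub in others.groupby("chrom"):
        srt = sub.sort_values("start")
        by_chrom[chrom] = (srt["start"].to_numpy(),
                           np.maximum.accumulate(srt["end"].to_numpy()))
    for chrom, sub_idx in peaks.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        starts, end_cummax = by_chrom[chrom]
        loc = peaks.index.get_indexer(sub_idx)
        p_start = peaks["start"].to_numpy()[loc]
        p_end = peaks["end"].to_numpy()[loc]
        # candidate others: start <= peak_end + max_gap; among them need
        # max(end) >= peak_start - max_gap
        pos = np.searchsorted(starts, p_end + max_gap, side="right")
        ok = pos > 0
        sel = np.zeros(len(loc), dtype=bool)
        sel[ok] = end_cummax[pos[ok] - 1] >= p_start[ok] - max_gap
        hit[loc] = sel
    return hit
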