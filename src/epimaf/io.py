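"""Readers and writers for the plain-text formats the pipeline consumes.

All genomic coordinates are handled as 0-based half-open internally. BED
files are read/written natively; GTF gene lines (1-based inclusive) are
converted on read. Parse errors cite the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GENE_COLUMNS, GenomeModel


class ParseError(ValueError):
    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_lines(path):
    with open(path, "r", newline=None) as fh:  # universal newlines: CRLF ok
        for lineno, line in enumerate(fh, start=1):
            yield lineno, line.rstrip("\r\n")


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (chrom, start, end[, name, score, strand])."""
    rows = []
    ncols = None
    for lineno, line in _open_lines(path):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(path, lineno, "BED line has fewer than 3 fields")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
        if start < 0 or start >= end:
            raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
        row = [parts[0], start, end]
        if len(parts) >= 6:
            row += [parts[3], float(parts[4]), parts[5]]
        elif len(parts) >= 4:
            row += [parts[3]]
        rows.append(row)
        ncols = max(ncols or 0, len(row))
    columns = ["chrom", "start", "end", "name", "score", "strand"][: (ncols or 3)]
    df = pd.DataFrame([r + [None] * (len(columns) - len(r)) for r in rows], columns=columns)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gene_tsv(path) -> pd.DataFrame:
    """Gene model TSV: columns gene_id, chrom, start, end, strand (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene TSV missing columns {missing}")
    return df[list(GENE_COLUMNS)]


def write_gene_tsv(genes: pd.DataFrame, path) -> None:
    genes[list(GENE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gtf_genes(path) -> pd.DataFrame:
    """Minimal GTF reader: keeps ``gene`` feature lines only, converts the
    1-based inclusive coordinates to 0-based half-open."""
    rows = []
    for lineno, line in _open_lines(path):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ParseError(path, lineno, "GTF line has fewer than 9 fields")
        if parts[2] != "gene":
            continue
        try:
            start1, end1 = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer coordinate: {exc}") from exc
        attrs = parts[8]
        gene_id = None
        for chunk in attrs.split(";"):
            chunk = chunk.strip()
            if chunk.startswith("gene_id"):
                gene_id = chunk.split(" ", 1)[1].strip().strip('"')
                break
        if gene_id is None:
            raise ParseError(path, lineno, "gene line without gene_id attribute")
        rows.append([gene_id, parts[0], start1 - 1, end1, parts[6]])
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def genome_from_files(gene_path, chrom_sizes: dict[str, int] | None = None,
                      gtf: bool = False) -> GenomeModel:
    genes = read_gtf_genes(gene_path) if gtf else read_gene_tsv(gene_path)
    if chrom_sizes is None:
        chrom_sizes = {c: int(sub["end"].max()) + 10_000 for c, sub in genes.groupby("chrom")}
    return GenomeModel(chrom_sizes=chrom_sizes, genes=genes)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Feature-by-sample matrix TSV; first column is the feature id index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no sample columns")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


SAINT_COLUMNS = ["Bait", "Prey", "Replicate", "Engine", "Spec"]
SAINT_STATS_COLUMNS = ["Bait", "Prey", "AvgSpec", "FoldChange", "BFDR"]


def read_saint_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SAINT counts TSV missing columns {missing}")
    return df.rename(columns={"Bait": "bait", "Prey": "prey", "Replicate": "replicate",
                              "Engine": "engine", "Spec": "count"})


def read_saint_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAINT_STATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SAINT stats TSV missing columns {missing}")
    return df.rename(columns={"Bait": "bait", "Prey": "prey", "AvgSpec": "avg_spec",
                              "FoldChange": "fold_change", "BFDR": "bfdr"})


def read_survival_tsv(path) -> pd.DataFrame:
    """Survival table: sample, time, event (+ optional covariate columns)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: survival TSV missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: follow-up times must be positive")
    df["event"] = df["event"].astype(bool)
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
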