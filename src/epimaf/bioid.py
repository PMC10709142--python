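"""Post-processing of SAINT-style proximity-labeling (BioID) tables.

The upstream scoring tool compares bait and control spectral counts per
prey and emits a Bayesian FDR (BFDR) and fold change; this module covers
everything downstream: merging the two search-engine quantifications
(Proteome Discoverer / MaxQuant) by taking the per-replicate maximum,
keeping the top-k replicates by spectral count, applying the
high-confidence filter (BFDR <= 0.02 and fold change >= 3, boundaries
inclusive), and assembling the four-bait network:

    S_common = MAF-S-N  ∩ MAF-S-C        (short-isoform interactors)
    L_common = MAF-L-N  ∩ MAF-L-C        (long-isoform interactors)
    network  = S_common ∪ L_common       (high-confidence interactome)
    four_way = intersection of all four bait sets
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

BAITS = ("MAF-S-N", "MAF-S-C", "MAF-L-N", "MAF-L-C")
S_BAITS = ("MAF-S-N", "MAF-S-C")
L_BAITS = ("MAF-L-N", "MAF-L-C")

BFDR_MAX_DEFAULT = 0.02
FC_MIN_DEFAULT = 3.0


@dataclass
class BaitNetwork:
    per_bait: dict[str, set]
    s_common: set
    l_common: set
    network: set
    four_way: set

    def sizes(self) -> dict[str, int]:
        d = {bait: len(s) for bait, s in self.per_bait.items()}
        d.update(s_common=len(self.s_common), l_common=len(self.l_common),
                 network=len(self.network), four_way=len(self.four_way))
        return d


def merge_engine_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Per (bait, prey, replicate) spectral count: the maximum over search
    engines; a prey missing from one engine counts 0 there.

    ``counts`` columns: bait, prey, replicate, engine, count.
    """
    if (counts["count"] < 0).any():
        raise ValueError("spectral counts must be non-negative")
    merged = (counts.groupby(["bait", "prey", "replicate"], as_index=False)["count"]
              .max())
    return merged


def select_top_replicates(merged: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Keep, per (bait, prey), the k replicates with the highest counts
    (the '-R3' selection). Groups with fewer than k replicates pass
    through with a warning."""
    n_rep = merged.groupby(["bait", "prey"])["replicate"].nunique()
    if (n_rep < k).any():
        warnings.warn(f"some bait/prey groups have fewer than {k} replicates; "
                      "passing them through unchanged", stacklevel=2)
    out = (merged.sort_values("count", ascending=False, kind="mergesort")
           .groupby(["bait", "prey"], as_index=False, sort=False)
           .head(k))
    return out.sort_values(["bait", "prey", "replicate"]).reset_index(drop=True)


def filter_high_confidence(stats: pd.DataFrame,
                           bfdr_max: float = BFDR_MAX_DEFAULT,
                           fc_min: float = FC_MIN_DEFAULT) -> dict[str, set]:
    """High-confidence prey sets per bait: BFDR <= bfdr_max AND
    fold change >= fc_min, boundaries inclusive.

    ``stats`` columns: bait, prey, bfdr, fold_change.
    """
    if stats["bfdr"].isna().any():
        raise ValueError("missing BFDR values")
    if ((stats["bfdr"] < 0) | (stats["bfdr"] > 1)).any():
        raise ValueError("BFDR must lie in [0, 1]")
    keep = (stats["bfdr"] <= bfdr_max) & (stats["fold_change"] >= fc_min)
    sel = stats.loc[keep]
    out: dict[str, set] = {bait: set() for bait in stats["bait"].unique()}
    for bait, sub in sel.groupby("bait"):
        out[bait] = set(sub["prey"])
    return out


def build_bait_network(per_bait: dict[str, set]) -> BaitNetwork:
    """Assemble the bait network from four per-bait high-confidence sets.

    Inclusion-exclusion holds by construction:
    |network| = |S_common| + |L_common| - |S_common ∩ L_common|.
    """
    missing = [b for b in BAITS if b not in per_bait]
    if missing:
        raise ValueError(f"missing bait sets: {missing}")
    s_common = set(per_bait[S_BAITS[0]]) & set(per_bait[S_BAITS[1]])
    l_common = set(per_bait[L_BAITS[0]]) & set(per_bait[L_BAITS[1]])
    network = s_common | l_common
    four_way = set.intersection(*(set(per_bait[b]) for b in BAITS))
    return BaitNetwork(per_bait={b: set(per_bait[b]) for b in BAITS},
                       s_common=s_common, l_common=l_common,
                       network=network, four_way=four_way)


def dotplot_data(merged: pd.DataFrame, stats: pd.DataFrame,
                 selected_preys) -> pd.DataFrame:
    """Per (bait, prey) dot-plot quantities for selected preys: average
    spectral count over retained replicates, relative abundance across the
    four baits (max-normalized, 1 for the bait with the highest average,
    0 where unseen), and BFDR."""
    selected = set(selected_preys)
    sub = merged[merged["prey"].isin(selected)]
    avg = (sub.groupby(["bait", "prey"])["count"].mean()
           .unstack(fill_value=0.0).reindex(list(BAITS), fill_value=0.0))
    missing_preys = selected - set(avg.columns)
    for p in missing_preys:
        avg[p] = 0.0
    rel = avg.div(avg.max(axis=0).replace(0, 1.0), axis=1)
    long = (avg.stack().rename("avg_spec").to_frame()
            .join(rel.stack().rename("relative_abundance")))
    long = long.reset_index().rename(columns={"level_0": "bait", "level_1": "prey"})
    bfdr = stats.set_index(["bait", "prey"])["bfdr"]
    long["bfdr"] = [bfdr.get((b, p), float("nan"))
                    for b, p in zip(long["bait"], long["prey"])]
    return long.sort_values(["prey", "bait"]).reset_index(drop=True)
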