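# epimaf

Integrative regulatory-genomics toolkit for studying how a transcription
factor (MAF) reshapes the oestrogen-receptor (ERα) chromatin landscape in
breast-cancer cells, and how the resulting gene program relates to
metastatic risk. The package implements the downstream computational
stages of such a study — everything after read alignment and peak
calling — and ships a synthetic-data module that generates every input
with planted, recoverable structure, so the whole pipeline is testable
with no external downloads.

## What it computes

The experimental design is a 2×2 factor layout: mock vs
*MAF*-overexpressing cells, each hormone-deprived (HD) or
oestradiol-treated (E2). For each feature (gene or ATAC-seq consensus
peak) five condition contrasts are tested with a signed negative-binomial
Wald statistic (variance μ + αμ², method-of-moments dispersion per
feature):

> MAF vs mock, mockE2 vs mock, MAFE2 vs MAF, MAFE2 vs mockE2, MAFE2 vs mock

Features are assigned to regulation clusters by conjunction rules on the
statistics (cutoff |stat| > 2; a relaxed promoter-restricted variant uses
1.5 and requires broad peaks, log₁₀ width > 3, for the upregulated MAF
and MAF+E2 clusters):

| cluster | meaning | rule (both statistics) |
|---|---|---|
| A / 1 | MAF up | MAF vs mock > 2 and MAFE2 vs mockE2 > 2 |
| B / 2 | MAF down | both < −2 |
| C / 3 | E2 up | MAFE2 vs MAF > 2 and mockE2 vs mock > 2 |
| D / 4 | E2 down | both < −2 |
| E / 5 | MAF+E2 up | MAFE2 vs MAF > 2 and MAFE2 vs mockE2 > 2 |
| F / 6 | MAF+E2 down | both < −2 |

Around this core the package provides:

- **Peak annotation** — promoter-TSS (±2 kb of a TSS), gene-body,
  intergenic; signed distance to the nearest TSS; peak breadth
  (log₁₀ width); interval overlap with a `maxgap` allowance.
- **Permutation enrichment** (`permtest`) — one-tailed tests comparing a
  cluster's annotation-category percentage or histone-mark overlap
  (H3K27ac/H3K4me3, maxgap = 100) to random equal-sized subsets of the
  consensus peaks; Wilcoxon rank-sum comparison of peak breadth.
- **TSS-proximity curves** (`proximity`) — cumulative % of binding sites
  within 10…100 kb of a target gene set's TSSs, with a permutation
  envelope (5th-largest of 100 permutations); 25-bp binned TSS
  meta-profiles of normalized accessibility differenced against mock.
- **Promoter–enhancer links** (`links`) — Spearman correlation of peak
  signal with gene expression across samples within 500 kb, BH-adjusted;
  a 10,000-iteration random-peak-selection enrichment test.
- **Motif overrepresentation** (`motifs`) — binomial expectation for
  match counts in regions, fold = X/E and the continuity-corrected
  z = (X − E − 0.5)/S.
- **Super-enhancers** (`enhancers`) — stitch H3K27ac peaks within
  12.5 kb (promoter-contained peaks excluded), rank by target-minus-input
  signal, flag by the tangent-point cutoff on the ranked curve.
- **BioID interactome** (`bioid`) — merge dual-engine spectral counts by
  per-replicate maximum, keep the top-3 replicates, filter at
  BFDR ≤ 0.02 and fold change ≥ 3, and build the four-bait network
  (short/long MAF isoform, N/C-terminal tags).
- **Signature survival** (`survival`) — build a gene signature from
  MAF-upregulated genes with ER binding in both MAF and MAF+E2
  conditions, score cohorts by mean z-scored expression, stratify at
  mean − 1 SD, and compare groups by Kaplan–Meier / log-rank;
  gene–gene Spearman correlation and covariate residualization
  utilities.

## Worked example

Run the full pipeline on the default synthetic scenario (2,000 genes,
5,000 peaks, 3 replicates per condition, planted log₂ fold change 2):

```python
from epimaf import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, outdir="run1"))
print(res["gene_cluster_recovery"])                  # 0.94
print(res["promoter_enrichment"]["observed"])        # 83.0
print(res["promoter_enrichment"]["null_mean"])       # 27.873
print(res["promoter_enrichment"]["p_value"])         # 0.000999000999000999
print(res["survival_logrank_p"])                     # 2.5339173576640554e-06
```

94% of the planted cluster genes recover their true label from the
contrast statistics alone. The planted peak clusters are promoter-rich:
83% of cluster peaks are promoter-TSS against a 27.9% consensus
background, and no random subset among 1,000 permutations matches that
(p = 1/1001, the smallest value the add-one convention allows). In the
synthetic cohort, patients in the low-signature group (score below
mean − 1 SD) relapse earlier; the two-sided log-rank test rejects at
p ≈ 2.5 × 10⁻⁶.

The same stages are available from the shell (`epimaf --help`):

```sh
epimaf synth --seed 1 --outdir inputs/      # write all inputs + truth sidecars
epimaf all   --seed 1 --outdir run1/        # full pipeline, manifest.json
epimaf bioid --stats inputs/saint_stats.tsv --out net.json
```

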