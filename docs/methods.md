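# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would want to
know. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and annotation

All intervals are 0-based half-open (BED convention); GTF input is
converted on read. A peak is represented by its integer midpoint for
annotation and distance purposes — the upstream peak caller's summit is
not assumed to be available, and for the synthetic data midpoint and
summit coincide by construction.

Annotation is a three-way partition. A peak is **promoter-TSS** when its
midpoint lies within ±2,000 bp of any TSS (both edges inclusive),
**gene-body** when the midpoint falls inside some gene span but outside
every promoter window, and **intergenic** otherwise. Gene bodies are the
full gene span; exon/intron/UTR subdivisions are deliberately collapsed
because every downstream statistic only uses the three broad categories.
The nearest gene is the one minimizing |midpoint − TSS|, with exact ties
broken by lexicographic gene id so annotation is reproducible across
runs and platforms. Signed TSS distances are oriented by the gene:
positive downstream. Interval overlap takes a `max_gap` slack
(default 100 bp for histone-mark overlap): two intervals overlap when
the gap between them is at most `max_gap`, where touching or
intersecting intervals have gap 0.

## Contrast statistics

Counts are modelled as negative binomial with Var = μ + αμ². Per-sample
sequencing depth is removed by median-of-ratios size factors (geometric-
mean reference over features positive in all samples, median taken in
ratio space). The model is then fitted on the normalized counts — not on
raw counts with offsets — so the statistic depends on the data only
through the normalized matrix; rescaling a sample's depth together with
its factor leaves every statistic bitwise-stable, and fold-change
estimates are exactly scale-free even when factors are re-estimated.

Dispersion α is estimated per feature by method of moments from
residuals against the fitted condition means, with the residual sum
scaled by n/(n − p) (p = number of fitted mean parameters) — without
this correction dispersion is systematically underestimated at 3
replicates per condition and null tails inflate roughly threefold. No
shrinkage across features is applied; the statistic is deliberately a
transparent stand-in for heavier differential-expression machinery, and
a pre-computed contrast table can be supplied instead when an external
tool's statistics are preferred.

Means use a log-link GLM with cell-means condition coding (optional
additive batch columns), fitted by IRLS with weights μ/(1 + αμ). The
Wald ratio for a contrast is converted to a normal-scale statistic by
mapping its Student-t tail (df = n − p) through the normal quantile:
with 12 samples and 4 conditions the raw ratio is t₈-like, and a fixed
cutoff of 2 would otherwise not carry its nominal normal-tail meaning.
The sign always agrees with the log₂ fold change, and
p = 2·Φ(−|stat|) by construction.

**Cluster rules.** The conjunction rules (see README table) are applied
at |stat| > 2 (strict) or 1.5 (relaxed, promoter-TSS peaks only, with
breadth > 3 additionally required for the upregulated clusters A and E).
When several rules fire, one label is reported with priority
E/F > A/B > C/D — the interaction-specific clusters are the most
informative — and all satisfied rules are kept in a separate column.
Gene clusters 1–6 reuse the peak machinery via the 1↔A … 6↔F mapping;
the numeric cutoff for genes is an assumption made for symmetry with the
peak analysis. The pipeline driver restricts strict peak clustering to
peaks within 20 kb of a TSS; the library function itself imposes no
distance filter.

**Known limitation.** The two statistics inside the E/F conjunction
share the MAFE2 condition estimate and are therefore correlated
(ρ = 0.5 under the null). The fraction of null features passing any
conjunction is consequently higher than a bound computed from
independent events; per-feature dispersion estimation adds further
joint-tail dependence at 3 replicates per condition. Marginal tail
calibration (P(|stat| > 2) ≈ 0.0455) is verified by the test suite;
users should treat joint cluster membership as a selection rule, not as
a calibrated family-wise test.

## Permutation enrichment

The null model for category and mark-overlap enrichment draws subsets of
the consensus peak universe of the cluster's size, without replacement,
so peak widths and genomic context are preserved automatically. Sampled
p-values use the add-one convention p = (1 + #{null ≥ obs})/(1 + n_iter)
and are never zero; 1,000 iterations by default, all driven by an
explicit seed and bit-reproducible. When the number of distinct subsets
is small an exhaustive mode enumerates them all and returns the exact
tail probability. Peak-breadth comparisons use the two-sided Wilcoxon
rank-sum test with the tie-corrected normal approximation; two groups
with all-identical breadths short-circuit to p = 1.

## Proximity curves and meta-profiles

The cumulative curve reports the percentage of sites whose midpoint is
within d ∈ {10, 20, …, 100} kb of any target-gene TSS. Each of the 100
permutations redraws the target-set size from a comparison pool
(constitutively expressed genes in a real analysis; flat-expression
genes in synthetic runs — the pool is always an explicit input because
no universal selection rule exists). The envelope at each distance is
the k-th largest permuted value (k = 5, an empirical ~95% upper bound;
exposed as a parameter). TSS meta-profiles average log₂ size-factor-
normalized counts in 25-bp signed-distance bins (peaks within 25 kb of a
TSS only), per condition, differenced against mock; an optional
GCV-tuned cubic smoothing spline is display-only and raw bins are always
emitted.

## Promoter–enhancer links

Candidate pairs are all (peak, gene) with |midpoint − TSS| ≤ 500 kb.
Correlation is Spearman across shared samples (≥ 8 required), with the
asymptotic t approximation for p-values, Benjamini–Hochberg adjustment
over all tested pairs, and retention of positively correlated pairs at
FDR ≤ 0.05. All three choices (correlation type, adjustment, cutoff) are
configurable, and a pre-computed link table is accepted, because
published link catalogues derive from pipelines whose exact thresholds
vary. The enrichment test draws equal-sized random peak selections
without replacement (10,000 iterations) and shares the permutation
conventions above; its null mean equals the pool-wide linked fraction
(hypergeometric expectation), which the tests verify.

## Motif statistics

Match positions are an input; PWM scanning is out of scope (a toy
exact-string scanner is included for tests). With n genome-wide matches
assumed uniformly placed, the in-region count is Binomial(n, p) with
p = region_bp/genome_bp, giving E = np and S = √(np(1−p)) — the binomial
rather than Poisson form is exact under placement with a fixed total,
and the difference is negligible at genome scale. Overrepresentation is
fold = X/E and the continuity-corrected z = (X − E − 0.5)/S. The
correction biases the null mean of z by −0.5/S, which is why z should
not be used when S is small (S = 0 raises an error pointing to an exact
binomial test).

## Super-enhancers

H3K27ac peaks fully contained in a promoter window (TSS ± 2 kb) are
excluded; remaining peaks are chained single-linkage whenever the gap to
the next peak is ≤ 12,500 bp, and merged spans are emitted. Stitched
enhancers are scored by target signal minus input signal, floored at 0
(signal over a stitched span is summed, configurable). The super flag
uses the classic tangent rule: with ranks and scores both scaled to
[0, 1], the cutoff sits where a slope-1 line touches the ascending score
curve (argmin of scaled score minus scaled rank), and enhancers strictly
above the cutoff score are flagged. The flag is invariant to uniform
signal rescaling; all-equal scores produce no super-enhancers; fewer
than three stitched enhancers is an error because the cutoff is
undefined.

## BioID post-processing

The upstream interaction scorer's probability model is consumed, not
reimplemented: BFDR and fold change arrive in a SAINT-style table.
Per (bait, prey, replicate), the spectral count is the maximum over the
two search engines (a prey missing from one engine counts 0); per
(bait, prey) the three highest-count replicates are kept (fewer than
three passes through with a warning). High-confidence preys satisfy
BFDR ≤ 0.02 **and** fold change ≥ 3, both boundaries inclusive — where
sources disagree on strictness the inclusive reading is used and both
thresholds are parameters. The four-bait network is pure set algebra:
S-common and L-common are the N∩C intersections per isoform, the network
their union, and the four-way set the intersection of all four;
inclusion–exclusion holds identically.

## Signature survival

The signature is the set of MAF-upregulated (cluster-1) genes with an
annotated ER peak in both the MAF and MAF+E2 conditions (nearest-TSS
assignment, optional distance cap). Cohort samples are scored by the
mean of genewise z-scored log expression over signature genes — the mean
was chosen over the first principal component for interpretability and
robustness at small signatures; constant genes are excluded with a
warning. Stratification splits at mean − 1 SD of the scores (sample SD,
ddof = 1); the split is invariant to affine score transforms. Group
comparison uses Kaplan–Meier product-limit estimates and the two-sided
1-df log-rank test via lifelines; a group with zero events is reported
with a note rather than an error. Covariate adjustment is genewise
least-squares residualization (categoricals one-hot encoded, intercept
always included) recentred to gene means.

## Synthetic data

The generators define the study conditions for all tests; defaults build
a full scenario in well under a minute:

| quantity | default |
|---|---|
| genome | 4 chromosomes × 50 Mb, 2,000 genes, uniform TSS placement |
| design | 2×2 (mock/MAF × HD/E2), 3 replicates per condition |
| planted effect | log₂ fold change 2, 50 genes per cluster (×6) |
| NB dispersion α | 0.1 (Var = μ + αμ²) |
| peaks | 5,000; 100 per cluster (×6); widths log-normal around 600 bp |
| category enrichment | promoter fraction 0.8 (cluster) vs 0.2 (background) |
| mark overlap | 0.7 (cluster) vs 0.2 (background) |
| links | 50 samples, 100 planted pairs within 500 kb, Spearman ρ ≈ 0.7 |
| BioID | planted prey structure (40 common-all, 15 S-only, 20 L-only, 10 per single bait, 250 background) |
| survival | n = 200, exponential times, hazard ratio 3 for the planted low group, uniform censoring to ~60% events |

Counts are gamma-Poisson draws; per-sample depth varies uniformly in
[0.7, 1.3] to exercise normalization. Peak placement is rejection-
sampled against the annotation rule so intended and realized categories
agree exactly. Survival uses a latent activity s ~ N(0,1) driving
signature-gene expression; the planted low group (s below mean − 1 SD)
carries the hazard-ratio effect, so low signature expression means
higher risk. Every generator returns its ground truth, and
`write_scenario` saves a JSON sidecar next to each data file.

What the generators do **not** emulate: read-level data, GC and
fragment-length biases, correlated gene–gene expression structure,
batch effects (the design supports a batch column but the default
scenario plants none), informative censoring, and the heavy-tailed
spectral-count distributions of real proteomics. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
its stated model, not robustness to these real-data complications.

## Problem sizes and numerical choices

The default suite and the acceptance script use the scenario defaults
above; the survival power and type-I estimates use 500 simulated
cohorts each, and motif z-score calibration uses 10,000 uniform-
placement simulations. IRLS runs at most 25 iterations to 1e-8 with a
1e-10 ridge on the information matrix; dispersion is floored at 0;
percentage comparisons in permutation tests use a 1e-12 tolerance so
ties count as ≥. RNG streams are spawned per generator from
`SeedSequence([seed, stream])`, so adding a generator never perturbs the
draws of another.
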