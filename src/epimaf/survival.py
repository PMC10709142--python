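"""Gene-signature construction and survival stratification.

The signature is built from upregulated genes (expression cluster 1,
MAF-induced) that carry an ER binding site — a ChIP peak annotated to the
gene — in both the MAF and MAF+E2 conditions. Cohort samples are scored
by the mean z-scored expression of the signature genes, split at
mean - 1 SD of the scores into "low" and "mid-high" groups, and compared
by Kaplan-Meier curves with a two-sided log-rank test (bone
metastasis-free survival in the motivating cohorts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .genome import GenomeModel, annotate_peaks

GROUP_LOW = "low"
GROUP_MIDHIGH = "mid-high"


@dataclass
class SignatureResult:
    signature: set
    scores: pd.Series
    groups: pd.Series
    logrank_stat: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]
    note: str | None = None


def build_signature(cluster1_genes,
                    er_peaks_maf: pd.DataFrame,
                    er_peaks_mafe2: pd.DataFrame,
                    genome: GenomeModel,
                    max_tss_distance: float | None = None) -> set:
    """Genes from ``cluster1_genes`` with an annotated ER peak in BOTH
    conditions. Peak-to-gene assignment is nearest-TSS annotation;
    ``max_tss_distance`` optionally caps |midpoint - TSS| for a peak to
    count as associated."""
    cluster1 = set(cluster1_genes)
    if not cluster1:
        raise ValueError("empty cluster-1 gene set")

    def targets(peaks: pd.DataFrame) -> set:
        ann = annotate_peaks(peaks, genome)
        if max_tss_distance is not None:
            ann = ann[ann["tss_distance"].abs() <= max_tss_distance]
        return set(ann["nearest_gene"].dropna())

    return cluster1 & targets(er_peaks_maf) & targets(er_peaks_mafe2)


def score_samples(expression: pd.DataFrame, signature) -> pd.Series:
    """Per-sample signature score: mean of genewise z-scored (log)
    expression over the signature genes present in the matrix.
    Zero-variance genes are excluded with a warning."""
    genes = [g for g in sorted(set(signature)) if g in expression.index]
    if not genes:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expression.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant signature gene(s) "
                      "excluded from z-scoring", stacklevel=2)
        sub = sub.loc[~constant]
        sd = sd.loc[~constant]
        if sub.empty:
            raise ValueError("all signature genes are constant")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("score")


def stratify(scores: pd.Series) -> pd.Series:
    """Split samples at mean - 1 SD of the scores: ``low`` below the
    threshold, ``mid-high`` at or above. Location/scale invariant."""
    if len(scores) < 3:
        raise ValueError("need >=3 samples to stratify")
    sd = float(scores.std(ddof=1))
    if sd == 0:
        warnings.warn("zero score variance; all samples assigned mid-high",
                      stacklevel=2)
        return pd.Series(GROUP_MIDHIGH, index=scores.index, name="group")
    threshold = float(scores.mean()) - sd
    return pd.Series(np.where(scores < threshold, GROUP_LOW, GROUP_MIDHIGH),
                     index=scores.index, name="group")


def km_logrank(cohort: pd.DataFrame, groups: pd.Series,
               signature: set | None = None,
               scores: pd.Series | None = None) -> SignatureResult:
    """Kaplan-Meier estimates per group and a two-sided log-rank test.

    ``cohort`` needs ``time`` and ``event`` columns indexed by sample (or
    a ``sample`` column). Returns per-group KM tables (time, survival
    probability, at-risk counts) and the 1-df chi-square statistic.
    """
    if "sample" in cohort.columns:
        cohort = cohort.set_index("sample")
    cohort = cohort.loc[groups.index]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need two non-empty groups for the log-rank test")
    masks = {lab: (groups == lab) for lab in labels}
    note = None
    for lab, m in masks.items():
        if not cohort.loc[m, "event"].any():
            note = f"group {lab!r} has zero events; log-rank still defined"
    a, b = labels[0], labels[1]
    res = logrank_test(cohort.loc[masks[a], "time"], cohort.loc[masks[b], "time"],
                       event_observed_A=cohort.loc[masks[a], "event"],
                       event_observed_B=cohort.loc[masks[b], "event"])
    curves = {}
    for lab, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.loc[m, "time"], cohort.loc[m, "event"], label=str(lab))
        tbl = kmf.event_table
        curves[lab] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[str(lab)].to_numpy(),
            "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
        })
    return SignatureResult(signature=set(signature or ()), scores=scores if scores is not None else pd.Series(dtype=float),
                           groups=groups, logrank_stat=float(res.test_statistic),
                           p_value=float(res.p_value), km_curves=curves, note=note)


def gene_correlation(expression: pd.DataFrame, gene_a: str, gene_b: str):
    """Spearman correlation between two genes across samples, with the
    asymptotic two-sided p-value. Requires >=10 paired observations."""
    x = expression.loc[gene_a].to_numpy(dtype=float)
    y = expression.loc[gene_b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("need >=10 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant expression vector; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def adjust_expression(expression: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Genewise least-squares residualization against a covariate design,
    recentred to each gene's mean.

    ``covariates`` has one row per sample (aligned to expression columns);
    categorical columns are one-hot encoded (first level dropped),
    numeric columns enter as-is. An intercept is always included.
    """
    cov = covariates.loc[expression.columns]
    if cov.isna().any().any():
        cov = cov.dropna()
        expression = expression[cov.index]
    parts = [np.ones((len(cov), 1))]
    for col in cov.columns:
        s = cov[col]
        if s.dtype.kind in "biufc":
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            levels = pd.unique(s.astype(str))
            for lv in levels[1:]:
                parts.append((s.astype(str) == lv).to_numpy(float)[:, None])
    X = np.hstack(parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    Y = expression.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    resid += Y.mean(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=expression.index, columns=expression.columns)
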