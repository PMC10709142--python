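"""Per-feature contrast statistics on count matrices and cluster assignment.

The experiment is a 2x2 factor layout: mock / MAF-overexpressing cells,
each hormone-deprived or E2-treated, giving four conditions ``mock``,
``mockE2``, ``MAF``, ``MAFE2``. Five condition contrasts are tested per
feature (gene or ATAC peak):

    MAF_vs_mock, mockE2_vs_mock, MAFE2_vs_MAF, MAFE2_vs_mockE2, MAFE2_vs_mock

The statistic is a signed Wald statistic from a negative-binomial
log-linear model (``Var = mu + alpha * mu^2``) fitted on size-factor
normalized counts with a per-feature method-of-moments dispersion.
Because replicate counts are typically small, the raw Wald t-ratio is
mapped through Student-t tail probabilities onto normal quantiles so that
fixed cutoffs such as |stat| > 2 carry their nominal normal-tail meaning.

Cluster semantics (peaks A-F, genes 1-6 via A<->1 ... F<->6):

    A/B  MAF-regulated:     sign agrees in MAF_vs_mock  AND MAFE2_vs_mockE2
    C/D  E2-regulated:      sign agrees in MAFE2_vs_MAF AND mockE2_vs_mock
    E/F  MAF+E2-regulated:  sign agrees in MAFE2_vs_MAF AND MAFE2_vs_mockE2

with the first letter of each pair the upregulated direction. When several
rules fire, priority is E/F > A/B > C/D (the interaction clusters are the
most specific); all satisfied rules are also reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CONDITIONS = ("mock", "mockE2", "MAF", "MAFE2")

CONTRASTS: dict[str, tuple[str, str]] = {
    "MAF_vs_mock": ("MAF", "mock"),
    "mockE2_vs_mock": ("mockE2", "mock"),
    "MAFE2_vs_MAF": ("MAFE2", "MAF"),
    "MAFE2_vs_mockE2": ("MAFE2", "mockE2"),
    "MAFE2_vs_mock": ("MAFE2", "mock"),
}

# (cluster pair, contrasts whose statistics must jointly exceed the cutoff)
CLUSTER_RULES: dict[str, tuple[str, str]] = {
    "A": ("MAF_vs_mock", "MAFE2_vs_mockE2"),
    "B": ("MAF_vs_mock", "MAFE2_vs_mockE2"),
    "C": ("MAFE2_vs_MAF", "mockE2_vs_mock"),
    "D": ("MAFE2_vs_MAF", "mockE2_vs_mock"),
    "E": ("MAFE2_vs_MAF", "MAFE2_vs_mockE2"),
    "F": ("MAFE2_vs_MAF", "MAFE2_vs_mockE2"),
}
UP_CLUSTERS = ("A", "C", "E")
CLUSTER_PRIORITY = ("E", "F", "A", "B", "C", "D")
GENE_CLUSTER_OF = {"A": "1", "B": "2", "C": "3", "D": "4", "E": "5", "F": "6"}


@dataclass
class ContrastTable:
    """Per-feature statistics for the five named contrasts.

    ``table`` holds flat columns ``{contrast}.stat``, ``{contrast}.lfc``,
    ``{contrast}.pvalue`` indexed by feature id; ``size_factors`` is a
    per-sample Series.
    """

    table: pd.DataFrame
    size_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def stat(self, contrast: str) -> pd.Series:
        return self.table[f"{contrast}.stat"]

    def lfc(self, contrast: str) -> pd.Series:
        return self.table[f"{contrast}.lfc"]

    def pvalue(self, contrast: str) -> pd.Series:
        return self.table[f"{contrast}.pvalue"]

    @property
    def feature_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def filter_low_expression(counts: pd.DataFrame, min_mean: float = 5.0) -> pd.DataFrame:
    """Drop features whose mean count across all samples is <= ``min_mean``.

    A gene averaging exactly ``min_mean`` reads is removed.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = counts.mean(axis=1) > min_mean
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only features with strictly positive counts in every sample enter the
    median; scaling one sample's counts by c scales its factor by c.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors "
            "undefined — filter samples or supply factors explicitly")
    xp = x[positive]
    gm = np.exp(np.log(xp).mean(axis=1, keepdims=True))
    factors = np.median(xp / gm, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> np.ndarray:
    """Method-of-moments NB dispersion per feature from normalized counts.

    Residuals are taken against fitted group means, so the raw residual
    sum of squares estimates (n - p)/n of the variance; the n/(n - p)
    factor corrects that before solving
    sum[(y-mu)^2 - mu] = alpha * sum[mu^2] rowwise (floored at 0).
    """
    n = y.shape[1]
    scale = n / max(n - n_params, 1)
    resid2 = scale * (y - mu) ** 2
    num = (resid2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = num / den
    return np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, None)


def _fit_glm_row(y: np.ndarray, X: np.ndarray, alpha: float,
                 max_iter: int = 25, tol: float = 1e-8):
    """IRLS fit of a log-link NB-variance GLM for one feature.

    Returns (beta, cov) with cov the inverse Fisher information
    (XtWX)^-1, W = mu / (1 + alpha * mu).
    """
    eps = 1e-8
    mu = np.clip(y, 0.5, None)
    eta = np.log(mu)
    beta = np.linalg.lstsq(X, eta, rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = eta + (y - mu) / np.clip(mu, eps, None)
        xw = X * w[:, None]
        xtwx = X.T @ xw
        beta_new = np.linalg.solve(xtwx + np.eye(X.shape[1]) * 1e-10, xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    cov = np.linalg.inv(xtwx + np.eye(X.shape[1]) * 1e-10)
    return beta, cov


def _design_matrix(design: pd.DataFrame):
    """Cell-means condition coding plus additive batch columns (first batch
    level as reference). Returns (X, contrast row builder)."""
    cond = design["condition"].astype(str)
    unknown = set(cond) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions in design: {sorted(unknown)}")
    cols = {c: (cond == c).to_numpy(dtype=float) for c in CONDITIONS if (cond == c).any()}
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if "batch" in design.columns:
        levels = pd.unique(design["batch"].astype(str))
        for lv in levels[1:]:
            X = np.column_stack([X, (design["batch"].astype(str) == lv).to_numpy(float)])
            names.append(f"batch_{lv}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    def contrast_row(num: str, den: str) -> np.ndarray:
        c = np.zeros(X.shape[1])
        c[names.index(num)] = 1.0
        c[names.index(den)] = -1.0
        return c
    return X, names, contrast_row


def contrast_stats(counts: pd.DataFrame, design: pd.DataFrame,
                   contrasts: dict[str, tuple[str, str]] | None = None,
                   calibrate: bool = True,
                   precomputed_size_factors: pd.Series | None = None) -> ContrastTable:
    """Negative-binomial Wald statistics for the named condition contrasts.

    Parameters
    ----------
    counts
        Feature-by-sample integer count matrix.
    design
        One row per sample (indexed or with a ``sample`` column) with a
        ``condition`` column in {mock, mockE2, MAF, MAFE2} and an optional
        additive ``batch`` column.
    contrasts
        Mapping name -> (numerator condition, denominator condition);
        defaults to the five standard contrasts.
    calibrate
        Map the Wald t-ratio through Student-t(df = n - p) tails onto
        normal quantiles (recommended for small replicate numbers).

    Notes
    -----
    Counts are divided by median-of-ratios size factors before fitting, so
    the statistics are exactly invariant to per-sample depth rescaling.
    """
    if contrasts is None:
        contrasts = CONTRASTS
    if "sample" in design.columns:
        design = design.set_index("sample")
    design = design.loc[counts.columns]
    counts_by_cond = design.groupby("condition").size()
    if (counts_by_cond < 2).any():
        bad = counts_by_cond[counts_by_cond < 2].index.tolist()
        raise ValueError(f"need >=2 replicates per condition; short: {bad}")
    X, names, contrast_row = _design_matrix(design)

    sf = precomputed_size_factors if precomputed_size_factors is not None else size_factors(counts)
    y = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]

    # group means for the dispersion moment estimate (cell-means fit)
    cond = design["condition"].to_numpy()
    mu0 = np.empty_like(y)
    for c in CONDITIONS:
        mask = cond == c
        if mask.any():
            mu0[:, mask] = y[:, mask].mean(axis=1, keepdims=True)
    alpha = _mom_dispersion(y, np.clip(mu0, 1e-8, None),
                            n_params=int(counts_by_cond.shape[0]))

    n, p = X.shape
    df_resid = max(n - p, 1)
    rows = {name: contrast_row(*pair) for name, pair in contrasts.items()}
    out = {}
    stat = {name: np.empty(len(y)) for name in rows}
    lfc = {name: np.empty(len(y)) for name in rows}
    ln2 = np.log(2.0)
    for i in range(len(y)):
        beta, cov = _fit_glm_row(y[i], X, float(alpha[i]))
        for name, c in rows.items():
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            t = est / se if se > 0 else 0.0
            stat[name][i] = t
            lfc[name][i] = est / ln2
    for name in rows:
        t = stat[name]
        if calibrate:
            # two-sided tail-equivalent z-score, sign preserved
            tail = sps.t.sf(np.abs(t), df_resid)
            z = -sps.norm.ppf(np.clip(tail, 1e-300, 0.5))
            s = np.sign(t) * z
        else:
            s = t
        pval = 2.0 * sps.norm.sf(np.abs(s))
        out[f"{name}.stat"] = s
        out[f"{name}.lfc"] = lfc[name]
        out[f"{name}.pvalue"] = pval
    table = pd.DataFrame(out, index=counts.index)
    return ContrastTable(table=table, size_factors=sf)


def _rule_fires(table: ContrastTable, cluster: str, threshold: float) -> pd.Series:
    c1, c2 = CLUSTER_RULES[cluster]
    s1, s2 = table.stat(c1), table.stat(c2)
    if cluster in UP_CLUSTERS:
        return (s1 > threshold) & (s2 > threshold)
    return (s1 < -threshold) & (s2 < -threshold)


def assign_peak_clusters(table: ContrastTable, threshold: float = 2.0) -> pd.DataFrame:
    """Assign peaks to clusters A-F from their contrast statistics.

    Returns a DataFrame indexed by feature id with columns ``label``
    (single highest-priority cluster or ``none``), ``all_labels``
    (comma-joined satisfied rules) and ``rule_variant``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fired = {cl: _rule_fires(table, cl, threshold) for cl in CLUSTER_PRIORITY}
    label = pd.Series("none", index=table.feature_ids, dtype=object)
    for cl in reversed(CLUSTER_PRIORITY):  # earlier priority overwrites later
        label[fired[cl]] = cl
    all_labels = pd.Series(
        ["," .join(cl for cl in "ABCDEF" if fired[cl].iloc[i]) for i in range(len(table))],
        index=table.feature_ids)
    variant = "strict2.0" if threshold == 2.0 else f"threshold{threshold:g}"
    return pd.DataFrame({"label": label, "all_labels": all_labels,
                         "rule_variant": variant})


def assign_relaxed_clusters(table: ContrastTable, peaks: pd.DataFrame,
                            threshold: float = 1.5,
                            breadth_min: float = 3.0) -> pd.DataFrame:
    """Relaxed cluster assignment used for ATAC/RNA integration.

    Same conjunction rules at |stat| > 1.5, restricted to promoter-TSS
    peaks; clusters A and E additionally require broad peaks
    (log10 width > ``breadth_min``). ``peaks`` must be annotated
    (``category`` column) and share its index with the contrast table.
    """
    if "category" not in peaks.columns:
        raise ValueError("peaks must be annotated (missing 'category' column)")
    peaks = peaks.loc[table.feature_ids]
    promoter = peaks["category"] == "promoter-TSS"
    breadth = np.log10((peaks["end"] - peaks["start"]).to_numpy())
    broad = pd.Series(breadth > breadth_min, index=peaks.index)
    fired = {}
    for cl in CLUSTER_PRIORITY:
        f = _rule_fires(table, cl, threshold) & promoter
        if cl in ("A", "E"):
            f = f & broad
        fired[cl] = f
    label = pd.Series("none", index=table.feature_ids, dtype=object)
    for cl in reversed(CLUSTER_PRIORITY):
        label[fired[cl]] = cl
    all_labels = pd.Series(
        [",".join(cl for cl in "ABCDEF" if fired[cl].iloc[i]) for i in range(len(table))],
        index=table.feature_ids)
    return pd.DataFrame({"label": label, "all_labels": all_labels,
                         "rule_variant": "relaxed1.5"})


def assign_gene_clusters(table: ContrastTable, threshold: float = 2.0) -> pd.DataFrame:
    """Assign genes to clusters 1-6 (1 MAF up ... 6 MAF+E2 down).

    Identical machinery to :func:`assign_peak_clusters` with labels mapped
    A..F -> 1..6.
    """
    peaks = assign_peak_clusters(table, threshold=threshold)
    out = peaks.copy()
    out["label"] = out["label"].map(lambda v: GENE_CLUSTER_OF.get(v, "none"))
    out["all_labels"] = out["all_labels"].map(
        lambda s: ",".join(GENE_CLUSTER_OF[c] for c in s.split(",")) if s else "")
    return out
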