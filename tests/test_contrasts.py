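"""NB contrast statistics, size factors and cluster-rule assignment."""

import numpy as np
import pandas as pd
import pytest

from epimaf.contrasts import (CONDITIONS, ContrastTable, assign_gene_clusters,
                              assign_peak_clusters, assign_relaxed_clusters,
                              contrast_stats, filter_low_expression,
                              size_factors)
from epimaf.synth import SyntheticScenario, _nb_draw


def _design(n_reps=3, conditions=CONDITIONS):
    rows = [(f"{c}_{r}", c) for c in conditions for r in range(1, n_reps + 1)]
    return pd.DataFrame(rows, columns=["sample", "condition"])


def _table(stats: dict[str, list[float]], ids=None) -> ContrastTable:
    """Build a ContrastTable directly from per-contrast statistic lists."""
    n = len(next(iter(stats.values())))
    cols = {}
    for name, vals in stats.items():
        cols[f"{name}.stat"] = vals
        cols[f"{name}.lfc"] = vals
        cols[f"{name}.pvalue"] = [0.5] * n
    idx = ids or [f"f{i}" for i in range(n)]
    return ContrastTable(table=pd.DataFrame(cols, index=idx))


ZERO = {c: [0.0] for c in ["MAF_vs_mock", "mockE2_vs_mock", "MAFE2_vs_MAF",
                           "MAFE2_vs_mockE2", "MAFE2_vs_mock"]}


def _stats_row(**over):
    d = {k: list(v) for k, v in ZERO.items()}
    for k, v in over.items():
        d[k] = [v]
    return d


class TestFilter:
    def test_mean_boundary_is_exclusive(self):
        counts = pd.DataFrame({"s1": [5, 6], "s2": [5, 6], "s3": [5, 6], "s4": [5, 6]},
                              index=["at5", "at6"])
        kept = filter_low_expression(counts)
        assert list(kept.index) == ["at6"]

    def test_random_matrix_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 20, size=(50, 6)))
        kept = filter_low_expression(counts)
        expect = [i for i in counts.index if counts.loc[i].mean() > 5]
        assert list(kept.index) == expect

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            filter_low_expression(pd.DataFrame())


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, size=100)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        sf = size_factors(counts)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_identical_samples_give_unit_factors(self):
        a = np.arange(1, 51)
        counts = pd.DataFrame({"A": a, "B": a, "C": a})
        assert np.allclose(size_factors(counts), 1.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(200, 5)),
                              columns=list("abcde"))
        sf = size_factors(counts)
        # independent oracle: literal median-of-ratios with loops
        logs = np.log(counts.to_numpy(float))
        gm = logs.mean(axis=1)
        for j, col in enumerate(counts.columns):
            ratios = [counts.iloc[i, j] / np.exp(gm[i]) for i in range(len(counts))]
            assert sf[col] == pytest.approx(np.median(ratios), rel=1e-12)

    def test_no_allpositive_feature_errors(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.raises(ValueError, match="size factors"):
            size_factors(counts)


class TestContrastStats:
    def _simulate(self, rng, mu_by_cond, alpha=0.1, n_reps=3, n_features=100):
        design = _design(n_reps)
        data = {}
        for _, row in design.iterrows():
            mu = mu_by_cond[row["condition"]]
            data[row["sample"]] = _nb_draw(rng, np.full(n_features, mu), alpha)
        return pd.DataFrame(data), design

    def test_null_statistics_calibrated(self):
        """Null features: mean stat ~ 0 and P(|stat| > 2) near the normal
        tail 0.0455."""
        rng = np.random.default_rng(10)
        counts, design = self._simulate(rng, {c: 100.0 for c in CONDITIONS},
                                        n_features=2000)
        ct = contrast_stats(counts, design)
        s = ct.stat("MAF_vs_mock")
        assert abs(s.mean()) < 0.1
        assert (s.abs() > 2).mean() < 0.08

    def test_planted_lfc_detected_with_power(self):
        """log2FC = 2 at mean 100, alpha = 0.05, 6 vs 6 replicates:
        positive sign and |stat| > 2 in >= 90% of affected features
        (a minority of features carries the effect, so normalization
        does not absorb it)."""
        rng = np.random.default_rng(11)
        design = _design(6)
        n_features, n_affected = 300, 60
        data = {}
        for _, row in design.iterrows():
            mu = np.full(n_features, 100.0)
            if row["condition"] in ("MAF", "MAFE2"):
                mu[:n_affected] = 400.0
            data[row["sample"]] = _nb_draw(rng, mu, 0.05)
        counts = pd.DataFrame(data)
        ct = contrast_stats(counts, design)
        s = ct.stat("MAF_vs_mock")
        assert (s.iloc[:n_affected] > 2).mean() >= 0.90
        nonzero = ct.lfc("MAF_vs_mock") != 0
        assert (np.sign(ct.lfc("MAF_vs_mock")[nonzero])
                == np.sign(s[nonzero])).all()

    def test_depth_rescaling_absorbed_by_normalization(self):
        """The statistic depends on counts only through the size-factor
        normalized matrix: doubling one sample while doubling its factor
        leaves every statistic unchanged within 1e-6, and with
        re-estimated factors the log2FC estimates are still exactly
        scale-free."""
        from epimaf.contrasts import size_factors as sfn
        rng = np.random.default_rng(12)
        counts, design = self._simulate(rng, {c: 100.0 for c in CONDITIONS})
        sf = sfn(counts)
        ct1 = contrast_stats(counts, design, precomputed_size_factors=sf)
        scaled = counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 2
        sf2 = sf.copy()
        sf2.iloc[0] = sf2.iloc[0] * 2
        ct2 = contrast_stats(scaled, design, precomputed_size_factors=sf2)
        assert np.allclose(ct1.table.to_numpy(), ct2.table.to_numpy(), atol=1e-6)
        # re-estimated factors undo the doubling up to a global rescaling
        # of the normalized matrix, which cancels in every fold change
        ct3 = contrast_stats(scaled, design)
        for name in ["MAF_vs_mock", "MAFE2_vs_mock"]:
            assert np.allclose(ct1.lfc(name), ct3.lfc(name), atol=1e-9)

    def test_stat_and_pvalue_consistent(self):
        rng = np.random.default_rng(13)
        counts, design = self._simulate(rng, {c: 50.0 for c in CONDITIONS},
                                        n_features=20)
        ct = contrast_stats(counts, design)
        from scipy import stats as sps
        s = ct.stat("MAFE2_vs_mock").to_numpy()
        p = ct.pvalue("MAFE2_vs_mock").to_numpy()
        assert np.allclose(p, 2 * sps.norm.sf(np.abs(s)), atol=1e-12)

    def test_too_few_replicates_error(self):
        rng = np.random.default_rng(14)
        counts, design = self._simulate(rng, {c: 50.0 for c in CONDITIONS}, n_reps=2)
        counts = counts.drop(columns=["mock_2"])
        with pytest.raises(ValueError, match="replicates"):
            contrast_stats(counts, design[design["sample"] != "mock_2"])


class TestClusterRules:
    def test_rule_a(self):
        t = _table(_stats_row(MAF_vs_mock=3.0, MAFE2_vs_mockE2=2.5))
        assert assign_peak_clusters(t)["label"].iloc[0] == "A"

    def test_rule_f(self):
        t = _table(_stats_row(MAFE2_vs_MAF=-3.0, MAFE2_vs_mockE2=-2.2))
        assert assign_peak_clusters(t)["label"].iloc[0] == "F"

    def test_priority_ef_over_ab(self):
        t = _table(_stats_row(MAF_vs_mock=3.0, MAFE2_vs_mockE2=3.0,
                              MAFE2_vs_MAF=3.0))
        res = assign_peak_clusters(t)
        assert res["label"].iloc[0] == "E"
        assert set(res["all_labels"].iloc[0].split(",")) == {"A", "E"}

    def test_all_zero_gives_none(self):
        t = _table(ZERO)
        assert assign_peak_clusters(t)["label"].iloc[0] == "none"

    def test_gene_cluster_5_maps_from_e(self):
        t = _table(_stats_row(MAFE2_vs_MAF=4.0, MAFE2_vs_mockE2=4.0))
        assert assign_gene_clusters(t)["label"].iloc[0] == "5"

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            assign_peak_clusters(_table(ZERO), threshold=0)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        stats = {c: list(rng.normal(0, 2, size=50)) for c in ZERO}
        t = _table(stats)
        res = assign_peak_clusters(t)
        perm = rng.permutation(50)
        t2 = ContrastTable(table=t.table.iloc[perm])
        res2 = assign_peak_clusters(t2)
        pd.testing.assert_series_equal(res["label"].sort_index(),
                                       res2["label"].sort_index())


class TestRelaxedClusters:
    def _peaks(self, widths, categories):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": 1000,
            "end": [1000 + w for w in widths],
            "category": categories,
        }, index=[f"f{i}" for i in range(len(widths))])

    def test_breadth_boundary_for_cluster_a(self):
        stats = {k: [v, v] for k, v in
                 dict(MAF_vs_mock=2.0, mockE2_vs_mock=0.0, MAFE2_vs_MAF=0.0,
                      MAFE2_vs_mockE2=2.0, MAFE2_vs_mock=0.0).items()}
        t = _table(stats)
        peaks = self._peaks([1200, 900], ["promoter-TSS", "promoter-TSS"])
        res = assign_relaxed_clusters(t, peaks)
        assert res["label"].loc["f0"] == "A"      # log10(1200) = 3.079 > 3
        assert res["label"].loc["f1"] == "none"   # log10(900) = 2.95

    def test_gene_body_peak_excluded(self):
        t = _table(_stats_row(MAF_vs_mock=2.0, MAFE2_vs_mockE2=2.0))
        peaks = self._peaks([2000], ["gene-body"])
        assert assign_relaxed_clusters(t, peaks)["label"].iloc[0] == "none"

    def test_b_needs_no_breadth(self):
        t = _table(_stats_row(MAF_vs_mock=-2.0, MAFE2_vs_mockE2=-2.0))
        peaks = self._peaks([300], ["promoter-TSS"])
        assert assign_relaxed_clusters(t, peaks)["label"].iloc[0] == "B"

    def test_unannotated_peaks_error(self):
        t = _table(ZERO)
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]},
                             index=["f0"])
        with pytest.raises(ValueError, match="annotated"):
            assign_relaxed_clusters(t, peaks)

    def test_matches_bruteforce_rule_evaluation(self):
        rng = np.random.default_rng(4)
        n = 200
        stats = {c: list(rng.normal(0, 1.8, size=n)) for c in ZERO}
        t = _table(stats)
        widths = rng.integers(200, 4000, size=n)
        cats = rng.choice(["promoter-TSS", "gene-body", "intergenic"], size=n)
        peaks = self._peaks(list(widths), list(cats))
        res = assign_relaxed_clusters(t, peaks)
        rules = {"A": ("MAF_vs_mock", "MAFE2_vs_mockE2", +1),
                 "B": ("MAF_vs_mock", "MAFE2_vs_mockE2", -1),
                 "C": ("MAFE2_vs_MAF", "mockE2_vs_mock", +1),
                 "D": ("MAFE2_vs_MAF", "mockE2_vs_mock", -1),
                 "E": ("MAFE2_vs_MAF", "MAFE2_vs_mockE2", +1),
                 "F": ("MAFE2_vs_MAF", "MAFE2_vs_mockE2", -1)}
        for i, fid in enumerate(t.feature_ids):
            fired = []
            for cl in "EFABCD":
                c1, c2, sign = rules[cl]
                ok = (sign * stats[c1][i] > 1.5) and (sign * stats[c2][i] > 1.5)
                ok = ok and cats[i] == "promoter-TSS"
                if cl in "AE":
                    ok = ok and np.log10(widths[i]) > 3
                if ok:
                    fired.append(cl)
            expect = fired[0] if fired else "none"
            assert res["label"].loc[fid] == expect


def test_strict_promoter_broad_peaks_are_relaxed_subset(peaks1):
    """Every strict-A promoter-TSS broad peak also qualifies as relaxed-A."""
    peaks, counts, design, _ = peaks1
    ct = contrast_stats(counts, design)
    strict = assign_peak_clusters(ct)
    relaxed = assign_relaxed_clusters(ct, peaks)
    broad = np.log10(peaks["end"] - peaks["start"]) > 3
    promoter = peaks["category"] == "promoter-TSS"
    sel = (strict["label"] == "A") & broad & promoter
    assert (relaxed.loc[sel[sel].index, "label"] == "A").all()
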