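"""Signature construction, stratification, Kaplan-Meier and log-rank."""

import numpy as np
import pandas as pd
import pytest

from epimaf.genome import GenomeModel
from epimaf.survival import (adjust_expression, build_signature,
                             gene_correlation, km_logrank, score_samples,
                             stratify)

from conftest import peak_frame


def _genome():
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB", "gC"],
        "chrom": "chr1",
        "start": [100_000, 500_000, 900_000],
        "end": [110_000, 510_000, 910_000],
        "strand": "+",
    })
    return GenomeModel(chrom_sizes={"chr1": 2_000_000}, genes=genes)


class TestBuildSignature:
    def test_requires_peaks_in_both_conditions(self):
        g = _genome()
        near_a = peak_frame([("chr1", 99_500, 100_500)])
        near_b = peak_frame([("chr1", 499_500, 500_500)])
        both = pd.concat([near_a, near_b], ignore_index=True)
        sig = build_signature({"gA", "gB", "gC"}, near_a, both, g)
        assert sig == {"gA"}          # gB only in the second set

    def test_gene_in_both_included(self):
        g = _genome()
        near_a = peak_frame([("chr1", 99_500, 100_500)])
        assert build_signature({"gA"}, near_a, near_a, g) == {"gA"}

    def test_bruteforce_double_membership_oracle(self):
        g = _genome()
        rng = np.random.default_rng(0)
        mk = lambda: peak_frame([("chr1", int(p), int(p) + 400)
                                 for p in rng.integers(0, 1_500_000, size=30)])
        set1, set2 = mk(), mk()
        cluster1 = {"gA", "gB", "gC"}
        sig = build_signature(cluster1, set1, set2, g)
        from epimaf.genome import annotate_peaks
        t1 = set(annotate_peaks(set1, g)["nearest_gene"])
        t2 = set(annotate_peaks(set2, g)["nearest_gene"])
        assert sig == cluster1 & t1 & t2

    def test_empty_cluster_errors(self):
        g = _genome()
        with pytest.raises(ValueError):
            build_signature(set(), peak_frame([("chr1", 0, 10)]),
                            peak_frame([("chr1", 0, 10)]), g)


class TestScore:
    def test_single_gene_signature_is_its_zscore(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        s = score_samples(expr, {"b"})
        row = expr.loc["b"]
        z = (row - row.mean()) / row.std(ddof=1)
        assert np.allclose(s, z)

    def test_constant_gene_excluded_with_warning(self):
        expr = pd.DataFrame({"s1": [1.0, 5.0], "s2": [1.0, 7.0], "s3": [1.0, 6.0]},
                            index=["flat", "var"])
        with pytest.warns(UserWarning):
            s = score_samples(expr, {"flat", "var"})
        z = (expr.loc["var"] - expr.loc["var"].mean()) / expr.loc["var"].std(ddof=1)
        assert np.allclose(s, z)

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(5, 12)),
                            index=[f"g{i}" for i in range(5)])
        sig = {"g0", "g2", "g3"}
        s = score_samples(expr, sig)
        zs = []
        for g in sorted(sig):
            row = expr.loc[g]
            zs.append((row - row.mean()) / row.std(ddof=1))
        assert np.allclose(s, np.mean(zs, axis=0))

    def test_no_overlap_errors(self):
        expr = pd.DataFrame(np.zeros((1, 3)), index=["x"])
        with pytest.raises(ValueError):
            score_samples(expr, {"y"})


class TestStratify:
    def test_single_low_outlier(self):
        scores = pd.Series([-3.0] + [0.0] * 8 + [3.0])
        groups = stratify(scores)
        assert (groups == "low").sum() == 1
        assert groups.iloc[0] == "low"

    def test_all_equal_no_low_group(self):
        with pytest.warns(UserWarning):
            groups = stratify(pd.Series([2.0, 2.0, 2.0, 2.0]))
        assert (groups == "mid-high").all()

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.normal(size=40))
        g1 = stratify(scores)
        g2 = stratify(scores * 7.5 + 100.0)
        assert g1.equals(g2)


def _logrank_oracle(time, event, group):
    """Hand-rolled two-group log-rank chi-square (no ties assumed across
    groups needed; handles ties in event times)."""
    times = np.unique(time[event])
    O_E, V = 0.0, 0.0
    for t in times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & group).sum()
        if n < 2:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / max(n - 1, 1)
        O_E += d1 - e1
        V += v
    return O_E ** 2 / V


class TestKMLogrank:
    def _cohort(self, times, events, samples=None):
        samples = samples or [f"s{i}" for i in range(len(times))]
        return pd.DataFrame({"sample": samples, "time": times, "event": events})

    def test_identical_groups_give_null_result(self):
        times = [5, 8, 12, 5, 8, 12]
        events = [True, True, False, True, True, False]
        cohort = self._cohort(times, events)
        groups = pd.Series(["low"] * 3 + ["mid-high"] * 3,
                           index=[f"s{i}" for i in range(6)])
        res = km_logrank(cohort, groups)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_computed_logrank(self):
        """Six subjects, all events, known table: lifelines must agree
        with the textbook O-E / V computation done here."""
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([True] * 6)
        grp = np.array([True, True, True, False, False, False])
        cohort = self._cohort(times, events)
        groups = pd.Series(np.where(grp, "low", "mid-high"),
                           index=[f"s{i}" for i in range(6)])
        res = km_logrank(cohort, groups)
        assert res.logrank_stat == pytest.approx(
            _logrank_oracle(times, events, grp), rel=1e-6)

    def test_km_without_censoring_is_empirical_survival(self):
        times = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        cohort = self._cohort(list(times) + [9.0], [True] * 5 + [True])
        groups = pd.Series(["low"] * 5 + ["mid-high"],
                           index=[f"s{i}" for i in range(6)])
        res = km_logrank(cohort, groups)
        km = res.km_curves["low"].set_index("time")["survival"]
        for t in [1.0, 2.0, 3.0, 4.0, 5.0]:
            assert km.loc[t] == pytest.approx((times > t).mean())

    def test_zero_event_group_noted(self):
        cohort = self._cohort([5, 6, 7, 8], [True, True, False, False])
        groups = pd.Series(["low", "low", "mid-high", "mid-high"],
                           index=[f"s{i}" for i in range(4)])
        res = km_logrank(cohort, groups)
        assert res.note is not None
        assert np.isfinite(res.logrank_stat)

    def test_planted_hazard_detected(self, scenario1):
        from epimaf.synth import gen_survival
        expr, cohort, truth = gen_survival(scenario1)
        scores = score_samples(expr, truth["signature_genes"])
        res = km_logrank(cohort, stratify(scores))
        assert res.p_value < 0.01


class TestGeneCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        expr = pd.DataFrame([x, np.exp(x)], index=["a", "b"])
        rho, p = gene_correlation(expr, "a", "b")
        assert rho == pytest.approx(1.0)

    def test_matches_rank_correlation_oracle(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        expr = pd.DataFrame([x, y], index=["a", "b"])
        rho, _ = gene_correlation(expr, "a", "b")
        from scipy.stats import rankdata
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-9)

    def test_constant_vector_errors(self):
        expr = pd.DataFrame([[1.0] * 12, list(range(12))], index=["a", "b"])
        with pytest.raises(ValueError):
            gene_correlation(expr, "a", "b")

    def test_too_few_observations_error(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5)),
                            index=["a", "b"])
        with pytest.raises(ValueError):
            gene_correlation(expr, "a", "b")


class TestAdjustExpression:
    def test_orthogonal_covariate_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(6)
        n = 40
        cov_vec = rng.normal(size=n)
        expr_row = rng.normal(size=n)
        # make the expression exactly orthogonal to the centred covariate
        c = cov_vec - cov_vec.mean()
        e = expr_row - expr_row.mean()
        e = e - (e @ c) / (c @ c) * c
        expr = pd.DataFrame([e + 5.0], index=["g"],
                            columns=[f"s{i}" for i in range(n)])
        covariates = pd.DataFrame({"x": cov_vec}, index=expr.columns)
        out = adjust_expression(expr, covariates)
        assert np.allclose(out.loc["g"], expr.loc["g"])

    def test_exact_linear_function_reduces_to_mean(self):
        n = 20
        x = np.arange(n, dtype=float)
        expr = pd.DataFrame([3.0 * x + 7.0], index=["g"],
                            columns=[f"s{i}" for i in range(n)])
        covariates = pd.DataFrame({"x": x}, index=expr.columns)
        out = adjust_expression(expr, covariates)
        assert np.allclose(out.loc["g"], expr.loc["g"].mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        n = 30
        x = rng.normal(size=n)
        grp = rng.choice(["a", "b"], size=n)
        expr = pd.DataFrame(rng.normal(size=(4, n)),
                            index=list("wxyz"), columns=[f"s{i}" for i in range(n)])
        covariates = pd.DataFrame({"x": x, "g": grp}, index=expr.columns)
        out = adjust_expression(expr, covariates)
        X = np.column_stack([np.ones(n), x, (grp == "b").astype(float)])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        for g in expr.index:
            y = expr.loc[g].to_numpy()
            resid = y - H @ y + y.mean()
            assert np.allclose(out.loc[g], resid)

    def test_rank_deficient_errors(self):
        expr = pd.DataFrame(np.random.default_rng(8).normal(size=(2, 10)),
                            columns=[f"s{i}" for i in range(10)])
        covariates = pd.DataFrame({"x": np.ones(10), "y": np.ones(10)},
                                  index=expr.columns)
        with pytest.raises(ValueError):
            adjust_expression(expr, covariates)
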