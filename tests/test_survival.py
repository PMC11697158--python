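"""Bulk scoring, median stratification, Cox / Kaplan-Meier and group tests."""

import numpy as np
import pandas as pd
import pytest

import metasig as ms
from metasig.simulate import BulkCohortData


def toy_cohort(expr: np.ndarray, genes, **clinical):
    samples = [f"s{i}" for i in range(expr.shape[0])]
    log_expr = pd.DataFrame(expr, index=samples, columns=genes)
    n = len(samples)
    clin = pd.DataFrame({
        "sample_id": samples,
        "time": clinical.get("time", np.ones(n)),
        "event": clinical.get("event", np.ones(n, int)),
        "cancer_type": clinical.get("cancer_type", ["x"] * n),
        "purity": 0.7,
        "stage": clinical.get("stage", 2),
        "age": 60.0,
        "tissue": clinical.get("tissue", ["tumour"] * n),
    }).set_index("sample_id")
    return BulkCohortData(log_expr, clin)


class TestSignatureZscore:
    def test_single_gene_equals_its_z(self):
        expr = np.array([[1.0, 9.0], [2.0, 9.0], [6.0, 9.0]])
        c = toy_cohort(expr, ["A", "B"])
        sc = ms.signature_zscore(c, ["A"])
        z = (expr[:, 0] - expr[:, 0].mean()) / expr[:, 0].std()
        np.testing.assert_allclose(sc, z)

    def test_cohort_mean_is_zero(self):
        rng = np.random.default_rng(0)
        c = toy_cohort(rng.normal(5, 1, (30, 4)), list("ABCD"))
        sc = ms.signature_zscore(c, list("ABCD"))
        assert sc.mean() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_genes(self):
        expr = np.array([[0.0, 3.0], [1.0, 4.0], [2.0, 8.0]])
        c = toy_cohort(expr, ["A", "B"])
        sc = ms.signature_zscore(c, ["A", "B"])
        za = (expr[:, 0] - 1.0) / np.std(expr[:, 0])
        zb = (expr[:, 1] - 5.0) / np.std(expr[:, 1])
        np.testing.assert_allclose(sc, (za + zb) / 2)

    def test_no_overlap_raises(self):
        c = toy_cohort(np.ones((3, 2)), ["A", "B"])
        with pytest.raises(KeyError):
            ms.signature_zscore(c, ["missing"])


class TestStratifyMedian:
    def test_median_rule(self):
        sc = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        ct = pd.Series(["x"] * 4, index=list("abcd"))
        lab = ms.stratify_median(sc, ct)
        assert lab.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_all_low(self):
        sc = pd.Series([2.0] * 4, index=list("abcd"))
        ct = pd.Series(["x"] * 4, index=list("abcd"))
        assert (ms.stratify_median(sc, ct) == "low").all()

    def test_per_type_medians(self):
        # disjoint ranges: each type still splits internally
        sc = pd.Series([1, 2, 3, 4, 101, 102, 103, 104.0],
                       index=[f"s{i}" for i in range(8)])
        ct = pd.Series(["a"] * 4 + ["b"] * 4, index=sc.index)
        lab = ms.stratify_median(sc, ct)
        assert lab.tolist() == ["low", "low", "high", "high"] * 2


class TestCoxFit:
    def test_null_score_beta_near_zero(self):
        cohort, _ = ms.gen_bulk_cohort(600, [f"S{i}" for i in range(10)],
                                       0.0, 0.0, seed=4)
        sc = ms.signature_zscore(cohort, [f"S{i}" for i in range(10)])
        fit = ms.cox_fit(cohort, sc)
        assert abs(fit.beta["score"]) < 0.15
        assert abs(fit.hazard_ratio["score"] - 1.0) < 0.2

    def test_covariate_family_present_and_bh(self):
        cohort, _ = ms.gen_bulk_cohort(400, [f"S{i}" for i in range(10)],
                                       np.log(2), 0.0, seed=5)
        sc = ms.signature_zscore(cohort, [f"S{i}" for i in range(10)])
        fit = ms.cox_fit(cohort, sc)
        assert {"score", "purity", "stage", "age"} <= set(fit.beta.index)
        assert (fit.adjusted_p >= fit.wald_p - 1e-12).all()

    def test_too_few_events_rejected(self):
        cohort, _ = ms.gen_bulk_cohort(50, ["A"], 0.0, 0.0, seed=1)
        cohort.clinical["event"] = 0
        cohort.clinical.loc[cohort.clinical.index[:5], "event"] = 1
        sc = ms.signature_zscore(cohort, ["A"])
        with pytest.raises(ValueError, match="events"):
            ms.cox_fit(cohort, sc)


class TestKMLogrank:
    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(1.0, 200)
        km = ms.km_logrank(pd.Series(np.r_[times, times * 0.5]),
                           pd.Series(np.ones(400, int)),
                           pd.Series(["a"] * 200 + ["b"] * 200))
        curve = km.curves["a"]
        t_sorted = np.sort(times)
        for q, t_q in [(0.25, t_sorted[49]), (0.5, t_sorted[99])]:
            # S(t) just after the k-th event equals 1 - k/n exactly
            val = curve[curve.index <= t_q + 1e-12].iloc[-1, 0]
            assert val == pytest.approx(1.0 - q, abs=1e-9)

    def test_exponential_median_ratio(self):
        rng = np.random.default_rng(1)
        t_slow = rng.exponential(1.0, 1000)
        t_fast = rng.exponential(0.5, 1000)
        km = ms.km_logrank(pd.Series(np.r_[t_slow, t_fast]),
                           pd.Series(np.ones(2000, int)),
                           pd.Series(["slow"] * 1000 + ["fast"] * 1000))
        assert km.medians["slow"] / km.medians["fast"] == pytest.approx(2.0, rel=0.1)
        assert km.p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ms.km_logrank(pd.Series([1.0, 2.0]), pd.Series([1, 1]),
                          pd.Series(["a", "a"]))


class TestGroupCompare:
    def test_exact_p_for_clean_separation(self):
        sc = pd.Series([5.0, 6, 7, 8, 1, 2, 3, 4], index=[f"s{i}" for i in range(8)])
        tissue = pd.Series(["tumour"] * 4 + ["normal"] * 4, index=sc.index)
        ct = pd.Series(["x"] * 8, index=sc.index)
        out = ms.group_compare(sc, tissue, ct)
        assert out.loc["x", "p"] == pytest.approx(1 / 70)

    def test_planted_shift_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sc = pd.Series(np.r_[rng.normal(1, 1, 50), rng.normal(0, 1, 50)],
                           index=[f"s{i}" for i in range(100)])
            tissue = pd.Series(["tumour"] * 50 + ["normal"] * 50, index=sc.index)
            ct = pd.Series(["x"] * 100, index=sc.index)
            detected += bool(ms.group_compare(sc, tissue, ct)["significant"].iloc[0])
        assert detected >= 9

    def test_missing_tissue_skipped(self):
        sc = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        tissue = pd.Series(["tumour", "tumour", "tumour", "normal"], index=sc.index)
        ct = pd.Series(["x", "x", "y", "y"], index=sc.index)
        out = ms.group_compare(sc, tissue, ct)
        assert list(out.index) == ["y"]


class TestStageCorrelation:
    def test_closed_form_point_biserial(self):
        sc = pd.Series([1.0, 2, 3, 4, 5, 6])
        stage = pd.Series([1, 1, 2, 3, 4, 4])  # late = stages >= 3
        r = ms.stage_correlation(sc, stage)
        late = (stage >= 3).astype(float)
        expected = np.corrcoef(sc, late)[0, 1]
        assert r == pytest.approx(expected)

    def test_independent_scores_near_zero(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sc = pd.Series(rng.normal(size=400))
            stage = pd.Series(rng.integers(1, 5, 400))
            rs.append(ms.stage_correlation(sc, stage))
        assert abs(np.mean(rs)) < 0.05
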