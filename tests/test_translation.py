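import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from convsig import (
    ExpressionMatrix,
    SampleAnnotation,
    km_compare,
    linear_predictor,
    multivariate_cox_train,
    mutation_association,
    optimal_cutpoints,
    rank_concordance,
    rank_disease_sites,
    split_by_quantiles,
    survival_frame,
    univariate_cox_screen,
    variance_filter,
)
from convsig.scoring import SignatureScoreVector
from convsig.translation import SiteRanking


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _sv(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return SignatureScoreVector(pd.Series(np.asarray(values, dtype=float),
                                          index=samples))


def _anns(n, sites=None, times=None, events=None, treated=None, muts=None):
    out = []
    for i in range(n):
        out.append(SampleAnnotation(
            sample_id=f"s{i}",
            disease_site=sites[i] if sites else "lung",
            treated=bool(treated[i]) if treated is not None else True,
            survival_time=float(times[i]) if times is not None else None,
            event=bool(events[i]) if events is not None else None,
            mutations=muts[i] if muts else None,
        ))
    return out


class TestSiteRanking:
    def test_planted_order_and_small_site_filter(self):
        sites = ["hi"] * 30 + ["mid"] * 30 + ["lo"] * 30 + ["tiny"] * 5
        scores = [3.0] * 30 + [1.0] * 30 + [-2.0] * 30 + [99.0] * 5
        rng = np.random.default_rng(0)
        scores = np.array(scores) + 0.01 * rng.normal(size=95)
        rank = rank_disease_sites(_sv(scores), _anns(95, sites=sites), min_n=25)
        assert rank.table["site"].tolist() == ["hi", "mid", "lo"]
        assert rank.table["rank"].tolist() == [1, 2, 3]
        assert "tiny" not in set(rank.table["site"])

    def test_median_of_shifted_scores_reported(self):
        sites = ["a"] * 5 + ["b"] * 5
        scores = [-1.0, 0.0, 1.0, 2.0, 3.0] + [0.0] * 5
        rank = rank_disease_sites(_sv(scores), _anns(10, sites=sites), min_n=5)
        # global min -1 -> shift 2: site a medians 1,2,3,4,5 -> 3; b -> 2
        row_a = rank.table[rank.table["site"] == "a"].iloc[0]
        assert row_a["median_score"] == pytest.approx(3.0)
        assert row_a["rank"] == 1

    def test_all_sites_too_small_rejected(self):
        with pytest.raises(ValueError, match="25"):
            rank_disease_sites(_sv([1.0] * 10), _anns(10), min_n=25)

    def test_concordance_oracle(self):
        ta = pd.DataFrame({"site": list("abcde"), "n": 30,
                           "median_score": [5, 4, 3, 2, 1], "rank": [1, 2, 3, 4, 5]})
        tb = pd.DataFrame({"site": list("abcde"), "n": 30,
                           "median_score": [5, 4, 3, 2, 1], "rank": [2, 1, 3, 4, 5]})
        rho, p, shared = rank_concordance(SiteRanking(ta), SiteRanking(tb))
        expect = stats.spearmanr([1, 2, 3, 4, 5], [2, 1, 3, 4, 5]).statistic
        assert rho == pytest.approx(expect)
        assert shared == list("abcde")

    def test_concordance_needs_three_shared_sites(self):
        ta = pd.DataFrame({"site": ["a", "b"], "n": 30, "median_score": [2, 1],
                           "rank": [1, 2]})
        with pytest.raises(ValueError, match="3"):
            rank_concordance(SiteRanking(ta), SiteRanking(ta))


class TestMutationAssociation:
    def test_chi_square_matches_hand_table(self):
        # 24 samples; scores 0..23 -> high = top 12. Gene M mutated in 10 of
        # the high group and 2 of the low group.
        scores = np.arange(24, dtype=float)
        mut = [{"M": False}] * 24
        for i in list(range(12, 22)) + [0, 1]:
            mut[i] = {"M": True}
        anns = _anns(24, muts=mut)
        res = mutation_association(_sv(scores), anns, ["M"])
        table = np.array([[10, 2], [2, 10]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        row = res.iloc[0]
        assert row["chi_square"] == pytest.approx(chi2)
        assert row["p_raw"] == pytest.approx(p)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, p))

    def test_untestable_genes_excluded_from_bonferroni(self):
        rng = np.random.default_rng(1)
        muts = [{"all": True, "none": False, "var": bool(rng.integers(2))}
                for _ in range(30)]
        res = mutation_association(_sv(rng.normal(size=30)), _anns(30, muts=muts),
                                   ["all", "none", "var"])
        res = res.set_index("gene")
        assert not res.loc["all", "testable"] and np.isnan(res.loc["all", "p_raw"])
        # only 1 testable gene -> bonferroni factor 1
        assert res.loc["var", "p_bonferroni"] == pytest.approx(res.loc["var", "p_raw"])

    def test_null_mutations_rarely_significant(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(40):
            muts = [{"G": bool(rng.random() < 0.3)} for _ in range(40)]
            res = mutation_association(_sv(rng.normal(size=40)),
                                       _anns(40, muts=muts), ["G"])
            if res.iloc[0]["testable"]:
                pvals.append(res.iloc[0]["p_raw"])
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_perfect_association_is_significant(self):
        scores = np.arange(40, dtype=float)
        muts = [{"M": i >= 20} for i in range(40)]
        res = mutation_association(_sv(scores), _anns(40, muts=muts), ["M"])
        assert res.iloc[0]["p_bonferroni"] < 1e-6

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="20"):
            mutation_association(_sv(np.arange(10.0)),
                                 _anns(10, muts=[{"M": False}] * 10), ["M"])


class TestVarianceFilter:
    def test_boundary_exactly_at_threshold_retained(self):
        # a gene whose variance equals the threshold exactly must be kept:
        # removal is strictly-below
        base = np.array([-1.0, 1.0] * 5)
        rows = np.vstack([base * 0.45, base * 0.1, base * 2.0])
        m = _em(rows, genes=["exact", "low", "high"])
        thr = float(m.frame.loc["exact"].var(ddof=1))
        kept = variance_filter(m, {"exact", "low", "high"}, threshold=thr)
        assert kept == {"exact", "high"}

    def test_no_survivor_rejected(self):
        m = _em(np.random.default_rng(0).normal(scale=0.01, size=(3, 10)))
        with pytest.raises(ValueError, match="variance filter"):
            variance_filter(m, set(m.gene_ids), threshold=0.2)

    def test_missing_gene_rejected(self):
        m = _em(np.random.default_rng(0).normal(size=(3, 10)))
        with pytest.raises(ValueError, match="absent"):
            variance_filter(m, {"nope"}, threshold=0.0)


def _surv_data(n=80, seed=5, beta=(-1.0, 0.8), extra=1):
    """Expression + survival where g0 is protective and g1 is harmful."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(len(beta) + extra, n))
    eta = np.asarray(beta) @ x[:len(beta)]
    times = rng.exponential(1.0 / (0.1 * np.exp(eta)))
    m = _em(x)
    cohort = pd.DataFrame({"time": times, "event": 1},
                          index=[f"s{i}" for i in range(n)])
    return m, cohort


class TestCoxScreenAndPanel:
    def test_harmful_gene_with_large_coef_excluded(self):
        m, cohort = _surv_data(n=400, seed=3, beta=(-1.0, 1.5))
        kept = univariate_cox_screen(m, cohort, {"g0", "g1", "g2"},
                                     coef_threshold=0.5)
        assert "g0" in kept and "g1" not in kept

    def test_protective_only_flag(self):
        m, cohort = _surv_data(n=400, seed=4, beta=(-1.0, 0.0))
        kept = univariate_cox_screen(m, cohort, {"g0"}, protective_only=True)
        assert kept == {"g0"}
        # a clearly harmful gene fails protective_only
        m2, cohort2 = _surv_data(n=400, seed=4, beta=(1.5, 0.0))
        with pytest.raises(ValueError, match="screen"):
            univariate_cox_screen(m2, cohort2, {"g0"}, protective_only=True)

    def test_single_gene_multivariate_equals_univariate(self):
        m, cohort = _surv_data(n=100, seed=6, beta=(-0.8,))
        model = multivariate_cox_train(m, cohort, {"g0"})
        cph = CoxPHFitter()
        df = m.frame.loc[["g0"]].T.copy()
        df["time"], df["event"] = cohort["time"], cohort["event"]
        cph.fit(df, duration_col="time", event_col="event")
        assert model.coefficients["g0"] == pytest.approx(float(cph.params_["g0"]),
                                                         rel=1e-8)

    def test_recovers_planted_coefficients(self):
        m, cohort = _surv_data(n=600, seed=7, beta=(-1.0, 0.5))
        model = multivariate_cox_train(m, cohort, {"g0", "g1"})
        assert model.coefficients["g0"] == pytest.approx(-1.0, abs=0.25)
        assert model.coefficients["g1"] == pytest.approx(0.5, abs=0.25)

    def test_collinear_panel_raises_informative_error(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1, 50))
        vals = np.vstack([x, x])  # perfectly collinear pair
        m = _em(vals)
        cohort = pd.DataFrame({"time": rng.exponential(5, size=50), "event": 1},
                              index=[f"s{i}" for i in range(50)])
        with pytest.raises(RuntimeError, match="collinearity|failed"):
            multivariate_cox_train(m, cohort, {"g0", "g1"})

    def test_linear_predictor_is_dot_product(self):
        m, cohort = _surv_data(n=60, seed=9, beta=(-1.0, 0.8))
        model = multivariate_cox_train(m, cohort, {"g0", "g1"})
        eta = linear_predictor(model, m)
        expected = (model.coefficients["g0"] * m.frame.loc["g0"]
                    + model.coefficients["g1"] * m.frame.loc["g1"])
        np.testing.assert_allclose(eta.to_numpy(), expected.to_numpy(), atol=1e-12)


class TestRiskGroups:
    def test_median_split_counts(self):
        risk = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        g = split_by_quantiles(risk, "median")
        assert (g == 0).sum() == 5 and (g == 1).sum() == 5

    def test_tertile_split_counts(self):
        risk = pd.Series(np.arange(9.0), index=[f"s{i}" for i in range(9)])
        g = split_by_quantiles(risk, "tertile")
        assert g.value_counts().sort_index().tolist() == [3, 3, 3]

    def test_optimal_single_cut_matches_brute_force(self):
        rng = np.random.default_rng(10)
        n = 15
        risk = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cohort = pd.DataFrame({
            "time": rng.exponential(1.0 / (0.2 * np.exp(risk.to_numpy()))),
            "event": 1,
        }, index=risk.index)
        res = optimal_cutpoints(risk, cohort, k=1, min_group=4)
        # brute force over every midpoint
        uniq = np.sort(risk.unique())
        best_chi, best_cut = -np.inf, None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            grp = (risk > c).astype(int)
            if grp.sum() < 4 or (1 - grp).sum() < 4:
                continue
            t = multivariate_logrank_test(cohort["time"], grp, cohort["event"])
            if t.test_statistic > best_chi + 1e-12:
                best_chi, best_cut = float(t.test_statistic), float(c)
        assert res.cutpoints[0] == pytest.approx(best_cut)
        assert res.chi_square == pytest.approx(best_chi, abs=1e-9)

    def test_single_feasible_cut_when_n_is_eight(self):
        # n=8, min_group=4: only the middle midpoint is feasible
        risk = pd.Series(np.arange(8.0), index=[f"s{i}" for i in range(8)])
        cohort = pd.DataFrame({"time": np.arange(1.0, 9.0), "event": 1},
                              index=risk.index)
        res = optimal_cutpoints(risk, cohort, k=1, min_group=4)
        assert res.cutpoints[0] == pytest.approx(3.5)
        assert res.group_sizes == [4, 4]

    def test_two_cuts_infeasible_for_small_n(self):
        risk = pd.Series(np.arange(11.0), index=[f"s{i}" for i in range(11)])
        cohort = pd.DataFrame({"time": np.arange(1.0, 12.0), "event": 1},
                              index=risk.index)
        with pytest.raises(ValueError, match="n=11"):
            optimal_cutpoints(risk, cohort, k=2, min_group=4)

    def test_two_cut_search_respects_min_group(self):
        rng = np.random.default_rng(12)
        n = 30
        risk = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cohort = pd.DataFrame({
            "time": rng.exponential(1.0 / (0.2 * np.exp(risk.to_numpy()))),
            "event": 1,
        }, index=risk.index)
        res = optimal_cutpoints(risk, cohort, k=2, min_group=5)
        assert len(res.cutpoints) == 2 and res.cutpoints[0] < res.cutpoints[1]
        assert min(res.group_sizes) >= 5 and sum(res.group_sizes) == n

    def test_km_compare_separates_planted_risk(self):
        rng = np.random.default_rng(13)
        n = 120
        risk = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        cohort = pd.DataFrame({
            "time": rng.exponential(1.0 / (0.1 * np.exp(1.5 * risk.to_numpy()))),
            "event": 1,
        }, index=risk.index)
        curves, chi2, p, df = km_compare(split_by_quantiles(risk), cohort)
        assert p < 1e-4 and df == 1 and len(curves) == 2

    def test_km_compare_null_is_calibrated(self):
        pvals = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            risk = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
            cohort = pd.DataFrame({"time": rng.exponential(5.0, size=40),
                                   "event": 1}, index=risk.index)
            _, _, p, _ = km_compare(split_by_quantiles(risk), cohort)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSurvivalFrame:
    def test_arm_filter_and_index(self):
        anns = _anns(6, times=[1, 2, 3, 4, 5, 6], events=[1, 0, 1, 1, 0, 1],
                     treated=[1, 1, 1, 0, 0, 0])
        df = survival_frame(anns, treated=True)
        assert list(df.index) == ["s0", "s1", "s2"]
        assert df.loc["s1", "event"] == 0

    def test_no_matching_records_rejected(self):
        anns = _anns(3)
        with pytest.raises(ValueError, match="no survival"):
            survival_frame(anns)
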