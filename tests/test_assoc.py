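import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfratio.assoc import (
    cfr_orr_correlation,
    contingency_test,
    group_difference,
    logistic_combiner,
    mutation_enrichment,
    response_rates,
    roc_auc,
    spearman,
)


class TestSpearman:
    def test_monotone_relation_gives_plus_minus_one(self):
        x = np.arange(10, dtype=float)
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
        assert spearman(x, -x**3).rho == pytest.approx(-1.0)

    def test_matches_sum_d_squared_formula_without_ties(self, rng):
        for _ in range(20):
            n = 10
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            d = stats.rankdata(x) - stats.rankdata(y)
            want = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
            assert spearman(x, y).rho == pytest.approx(want, abs=1e-12)

    def test_ci_brackets_rho(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman(x, y)
        assert res.ci_lower < res.rho < res.ci_upper
        assert -1 <= res.ci_lower and res.ci_upper <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestGroupDifference:
    def test_identical_groups_p_near_one(self):
        v = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = ["a"] * 10 + ["b"] * 10
        assert group_difference(v, labels).p > 0.9

    def test_u_statistic_and_exact_p_match_enumeration(self):
        """U for (1,2,3) vs (4,5,6) is 0; exact one-sided p = 1/20."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = group_difference(x + y, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == 0.0
        # enumeration oracle over all 20 arrangements of ranks into group a
        pooled = x + y
        u_obs = 0
        count_le = 0
        for combo in itertools.combinations(range(6), 3):
            grp = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for a in grp for b in rest if a > b)
            count_le += u <= u_obs
        assert count_le / 20 == pytest.approx(0.05)
        exact = stats.mannwhitneyu(x, y, alternative="less", method="exact")
        assert exact.pvalue == pytest.approx(0.05)

    def test_kruskal_on_three_identical_groups_is_zero(self):
        v = np.r_[np.arange(5.0)] * 1.0
        vals = np.concatenate([v, v, v])
        labels = np.repeat(["a", "b", "c"], 5)
        assert group_difference(vals, labels).statistic == pytest.approx(0.0)
        assert group_difference(vals, labels).method == "kruskal-wallis"

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            group_difference([1.0, 2.0, 3.0], ["a", "a", "b"], paired=True)

    def test_paired_uses_signed_rank(self, rng):
        before = rng.normal(size=15)
        after = before + 1.0 + rng.normal(scale=0.1, size=15)
        res = group_difference(np.r_[before, after],
                               ["pre"] * 15 + ["post"] * 15, paired=True)
        assert res.method == "wilcoxon-signed-rank"
        assert res.p < 0.01


class TestResponseRates:
    def test_printed_counts_reproduce_overall_orr(self):
        """PD 11, PR 17, SD 33 of n = 61 -> ORR 27.9%, DCR 82.0%."""
        responses = ["PD"] * 11 + ["PR"] * 17 + ["SD"] * 33
        out = response_rates(responses)
        assert out.loc["overall", "n"] == 61
        assert round(100 * out.loc["overall", "orr"], 1) == 27.9
        assert round(100 * out.loc["overall", "dcr"], 1) == 82.0

    def test_group_split_reconstructed_from_printed_percentages(self):
        """The (34, 27) high/low split is the unique split of PD 11 / PR 17 /
        SD 33 whose rounded per-group percentages are 41/56/3 and 11/52/37."""
        solutions = []
        for ph in range(18):
            for sh in range(34):
                for dh in range(12):
                    nh = ph + sh + dh
                    nl = 61 - nh
                    if nh == 0 or nl == 0:
                        continue
                    hi = (round(100 * ph / nh), round(100 * sh / nh), round(100 * dh / nh))
                    lo = (round(100 * (17 - ph) / nl), round(100 * (33 - sh) / nl),
                          round(100 * (11 - dh) / nl))
                    if hi == (41, 56, 3) and lo == (11, 52, 37):
                        solutions.append((nh, nl, ph, sh, dh))
        assert len(solutions) == 1
        nh, nl, ph, sh, dh = solutions[0]
        assert (nh, nl) == (34, 27)
        responses = (["PR"] * ph + ["SD"] * sh + ["PD"] * dh
                     + ["PR"] * (17 - ph) + ["SD"] * (33 - sh) + ["PD"] * (11 - dh))
        groups = ["high"] * nh + ["low"] * nl
        out = response_rates(responses, groups)
        assert round(100 * out.loc["high", "orr"]) == 41
        assert round(100 * out.loc["low", "orr"]) == 11
        assert round(100 * out.loc["high", "dcr"]) == 97
        assert round(100 * out.loc["low", "dcr"]) == 63

    def test_zero_responders_gives_zero_orr(self):
        out = response_rates(["SD", "PD", "SD"])
        assert out.loc["overall", "orr"] == 0.0

    def test_orr_never_exceeds_dcr(self, rng):
        responses = rng.choice(["CR", "PR", "SD", "PD"], 200)
        groups = rng.choice(["a", "b"], 200)
        out = response_rates(responses, groups)
        assert (out["orr"] <= out["dcr"] + 1e-12).all()

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            response_rates([])
        with pytest.raises(ValueError):
            response_rates(["PR", "XX"])


class TestContingency:
    def test_proportional_small_table_fisher_p_one(self):
        res = contingency_test([[2, 3], [4, 6]])  # n = 15 < 20 -> Fisher
        assert res.method == "fisher-exact"
        assert res.p == pytest.approx(1.0)

    def test_fisher_p_matches_hypergeometric_enumeration(self, rng):
        for _ in range(10):
            tab = rng.integers(0, 6, size=(2, 2))
            if tab.sum() == 0 or tab.sum() >= 20:
                continue
            res = contingency_test(tab)
            assert res.method == "fisher-exact"
            # enumerate the hypergeometric support at fixed margins
            r1, r2 = tab.sum(axis=1)
            c1 = tab[:, 0].sum()
            n = tab.sum()
            p_obs = stats.hypergeom.pmf(tab[0, 0], n, r1, c1)
            p_two = sum(
                stats.hypergeom.pmf(a, n, r1, c1)
                for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                if stats.hypergeom.pmf(a, n, r1, c1) <= p_obs * (1 + 1e-9)
            )
            assert res.p == pytest.approx(p_two, rel=1e-8)

    def test_yates_used_for_sparse_expected_counts(self):
        tab = [[3, 18], [12, 9]]  # n = 42, min expected = 21*15/42 = 7.5 -> plain
        assert contingency_test(tab).method == "chi-square"
        tab = [[2, 28], [8, 22]]  # expected min = 30*10/60 = 5 -> plain (not < 5)
        assert contingency_test(tab).method == "chi-square"
        tab = [[1, 29], [7, 23]]  # expected min = 30*8/60 = 4 -> Yates
        assert contingency_test(tab).method == "chi-square-yates"

    def test_doubling_cells_preserves_odds_ratio(self):
        tab = np.array([[12, 30], [25, 14]])
        odds = lambda t: (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        assert odds(tab) == pytest.approx(odds(2 * tab))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[0, 0], [0, 0]])


class TestLogisticCombiner:
    def test_uninformative_predictor_intercept_is_logit_prevalence(self, rng):
        y = np.r_[np.ones(30), np.zeros(70)]
        x = np.full(100, 2.5) + rng.normal(scale=1e-9, size=100)
        fit = logistic_combiner(y, pd.DataFrame({"x": x}))
        prevalence_logit = np.log(0.3 / 0.7)
        predicted_intercept = fit.coef["const"] + fit.coef["x"] * 2.5
        assert predicted_intercept == pytest.approx(prevalence_logit, abs=1e-3)

    def test_parameter_recovery(self, rng):
        n = 2000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 2.0 * x)))
        y = rng.binomial(1, p)
        fit = logistic_combiner(y, pd.DataFrame({"x": x}))
        assert fit.coef["const"] == pytest.approx(-1.0, abs=0.15)
        assert fit.coef["x"] == pytest.approx(2.0, abs=0.15)

    def test_fitted_deviance_not_above_null_deviance(self, rng):
        x = rng.normal(size=200)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        fit = logistic_combiner(y, pd.DataFrame({"x": x}))
        assert fit.deviance <= fit.null_deviance + 1e-9

    def test_perfect_separation_rejected(self):
        x = np.r_[np.arange(10.0), np.arange(10.0) + 20]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(ValueError, match="separation"):
            logistic_combiner(y, pd.DataFrame({"x": x}))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_combiner(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestRocAuc:
    def test_perfect_and_constant_scores(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        assert roc_auc(np.arange(10.0), y) == 1.0
        assert roc_auc(np.zeros(10), y) == 0.5

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(10):
            score = rng.integers(0, 8, 30).astype(float)
            label = rng.integers(0, 2, 30)
            if label.min() == label.max():
                continue
            pos = score[label == 1]
            neg = score[label == 0]
            pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
            assert roc_auc(score, label) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_complement_under_score_negation(self, rng):
        score = rng.normal(size=50)
        label = rng.integers(0, 2, 50)
        label[:2] = [0, 1]
        assert roc_auc(score, label) + roc_auc(-score, label) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5))


class TestMutationEnrichment:
    def _matrix(self, rng, genes=12, n=40):
        mm = pd.DataFrame(rng.integers(0, 2, (genes, n)),
                          index=[f"G{i}" for i in range(genes)],
                          columns=[f"s{i}" for i in range(n)])
        labels = rng.choice(["hi", "lo"], n)
        labels[:2] = ["hi", "lo"]
        return mm, labels

    def test_equal_fractions_give_p_one(self):
        mm = pd.DataFrame([[1, 1, 0, 0, 1, 1, 0, 0]], index=["G"],
                          columns=[f"s{i}" for i in range(8)])
        labels = ["a"] * 4 + ["b"] * 4
        out = mutation_enrichment(mm, labels)
        assert out.loc["G", "p"] == pytest.approx(1.0)

    def test_per_gene_p_matches_contingency_fisher_path(self, rng):
        mm, labels = self._matrix(rng, genes=8, n=15)  # n < 20 -> fisher path
        out = mutation_enrichment(mm, labels)
        for gene in out.index:
            row = mm.loc[gene].to_numpy()
            g1 = np.asarray(labels) == "hi"
            tab = [[int(row[g1].sum()), int(g1.sum() - row[g1].sum())],
                   [int(row[~g1].sum()), int((~g1).sum() - row[~g1].sum())]]
            res = contingency_test(tab)
            assert res.method == "fisher-exact"
            assert out.loc[gene, "p"] == pytest.approx(res.p)

    def test_q_values_match_naive_step_up_and_are_monotone(self, rng):
        mm, labels = self._matrix(rng)
        out = mutation_enrichment(mm, labels)
        p = out["p"].to_numpy()  # already sorted ascending
        m = len(p)
        naive = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(out["q"].to_numpy(), np.minimum(naive, 1.0))
        assert (np.diff(out["q"]) >= -1e-12).all()

    def test_unmutated_gene_skipped(self, rng):
        mm = pd.DataFrame([[0, 0, 0, 0], [1, 0, 1, 0]], index=["silent", "active"],
                          columns=list("abcd"))
        out = mutation_enrichment(mm, ["x", "x", "y", "y"])
        assert list(out.index) == ["active"]

    def test_top_k_truncates(self, rng):
        mm, labels = self._matrix(rng)
        assert len(mutation_enrichment(mm, labels, top_k=5)) == 5


class TestCfrOrrCorrelation:
    def test_identical_rankings_give_rho_one(self):
        cfr = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        orr = pd.Series([0.05, 0.10, 0.20, 0.30, 0.50], index=list("abcde"))
        res, report = cfr_orr_correlation(cfr, orr)
        assert res.rho == pytest.approx(1.0)
        assert report["n_matched"] == 5

    def test_unmatched_key_dropped_without_changing_statistic(self):
        cfr = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=list("abcde"))
        orr = pd.Series([0.05, 0.10, 0.20, 0.30, 0.50], index=list("abcde"))
        res_full, _ = cfr_orr_correlation(cfr, orr)
        cfr_extra = pd.concat([cfr, pd.Series({"zzz": 0.9})])
        res_extra, report = cfr_orr_correlation(cfr_extra, orr)
        assert res_extra.rho == res_full.rho
        assert report["unmatched_cfr"] == ["zzz"]

    def test_shuffled_orr_averages_near_zero(self, rng):
        cfr = pd.Series(np.arange(10.0), index=[f"t{i}" for i in range(10)])
        rhos = []
        for _ in range(100):
            orr = pd.Series(rng.permutation(10).astype(float), index=cfr.index)
            rhos.append(cfr_orr_correlation(cfr, orr)[0].rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_matched_types_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="matched"):
            cfr_orr_correlation(s, s)
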