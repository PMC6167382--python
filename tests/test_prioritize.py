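"""Candidate gates, target nomination, and the expression-support tests."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from accessprior.core import CountMatrix, ValidationError
from accessprior.prioritize import (
    coexpression_selection,
    expression_percentile_gate,
    family_expression_ordering,
    fisher_gene_set,
    log2_quantile_normalize,
    nominate_targets,
    overexpression_gate,
    residualize_covariates,
    select_candidates,
    wilcoxon_signed_rank,
)


class TestPercentileGate:
    def setup_method(self):
        self.means = pd.Series(
            np.arange(1.0, 101.0), index=[f"g{i}" for i in range(100)]
        )

    def test_maximum_is_100th_percentile_and_passes(self):
        out = expression_percentile_gate(self.means, ["g99"])
        assert out.loc["g99", "percentile"] == 100.0
        assert out.loc["g99", "passed"]

    def test_median_fails_at_75(self):
        out = expression_percentile_gate(self.means, ["g49"])
        assert out.loc["g49", "percentile"] == pytest.approx(50.0)
        assert not out.loc["g49", "passed"]

    def test_missing_gene_flagged_and_fails(self):
        out = expression_percentile_gate(self.means, ["nope"])
        assert out.loc["nope", "missing"] and not out.loc["nope", "passed"]


class TestOverexpressionGate:
    def make_expr(self, tf_fold, rng, n_genes=300):
        mu = rng.lognormal(np.log(100), 0.8, size=n_genes)
        fold = np.ones((n_genes, 6))
        fold[0, :3] = tf_fold
        lam = rng.gamma(1 / 0.05, 0.05 * mu[:, None] * fold)
        return CountMatrix(
            rng.poisson(lam),
            [f"g{i}" for i in range(n_genes)],
            [f"s{j}" for j in range(6)],
            {f"s{j}": ("E+" if j < 3 else "E-") for j in range(6)},
        )

    def test_identical_conditions_fail(self, rng):
        cm = self.make_expr(1.0, rng)
        out = overexpression_gate(cm, ["g0"])
        assert not out.loc["g0", "passed"]

    def test_planted_overexpression_passes(self, rng):
        cm = self.make_expr(2.0 ** 1.5, rng)
        out = overexpression_gate(cm, ["g0"])
        assert out.loc["g0", "passed"] and out.loc["g0", "log2fc"] > 0

    def test_downregulation_fails_despite_significance(self, rng):
        cm = self.make_expr(0.1, rng)
        out = overexpression_gate(cm, ["g0"])
        assert out.loc["g0", "p"] < 0.05 and not out.loc["g0", "passed"]


class TestSelectCandidates:
    def fixtures(self, exclusive_to="tumor_specific", pct_pass=True, oe_pass=True):
        verdicts = pd.DataFrame(
            {
                "motif_id": ["m"],
                "significant_in": [exclusive_to],
                "exclusive": [bool(exclusive_to)],
                "exclusive_to": [exclusive_to],
            }
        )
        enr = pd.DataFrame({"motif_id": ["m"], "rank": [1]})
        pct = pd.DataFrame(
            {"percentile": [90.0 if pct_pass else 10.0], "passed": [pct_pass],
             "missing": [False]},
            index=pd.Index(["gX"], name="gene_id"),
        )
        oe = pd.DataFrame(
            {"log2fc": [1.0], "p": [0.01 if oe_pass else 0.7], "passed": [oe_pass],
             "missing": [False]},
            index=pd.Index(["gX"], name="gene_id"),
        )
        return verdicts, enr, pct, oe

    def test_full_conjunction_selects(self):
        out = select_candidates(*self.fixtures(), {"m": "gX"})
        assert out["selected"].tolist() == [True]

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(exclusive_to=""), "not exclusive"),
            (dict(pct_pass=False), "percentile"),
            (dict(oe_pass=False), "overexpressed"),
        ],
    )
    def test_each_failing_gate_blocks_selection_with_audit(self, kwargs, reason):
        out = select_candidates(*self.fixtures(**kwargs), {"m": "gX"})
        assert not out["selected"].any()
        assert reason in out["fail_reason"].iloc[0]

    def test_missing_gene_mapping_is_audited(self):
        out = select_candidates(*self.fixtures(), {})
        assert not out["selected"].any()
        assert "no cognate gene" in out["fail_reason"].iloc[0]


class TestNomination:
    def de(self, lfcs):
        return pd.DataFrame(
            {"feature_id": list(lfcs), "log2fc": list(lfcs.values()),
             "q": [0.001] * len(lfcs)}
        )

    def test_peak_count_dominates_ranking(self):
        de = self.de({"egfr_like": 3.5, "aqp4_like": 4.9})
        out = nominate_targets(
            de,
            {"egfr_like": [f"p{i}" for i in range(18)], "aqp4_like": [f"q{i}" for i in range(6)]},
            {pid: 100.0 for pid in [f"p{i}" for i in range(18)] + [f"q{i}" for i in range(6)]},
        )
        assert list(out["gene_id"]) == ["egfr_like", "aqp4_like"]
        assert list(out["rank"]) == [1, 2]

    def test_strict_log2fc_cutoff(self):
        de = self.de({"a": 2.9, "b": 3.0})
        out = nominate_targets(de, {"a": ["p1"], "b": ["p2"]}, {"p1": 1.0, "p2": 1.0})
        assert out.empty  # 2.9 < 3 and 3.0 is not > 3

    def test_no_motif_peaks_excludes_gene(self):
        de = self.de({"a": 5.0})
        out = nominate_targets(de, {"a": []}, {})
        assert out.empty

    def test_score_breaks_peak_count_ties(self):
        de = self.de({"a": 4.0, "b": 4.0})
        out = nominate_targets(
            de, {"a": ["p1"], "b": ["p2"]}, {"p1": 500.0, "p2": 900.0}
        )
        assert list(out["gene_id"]) == ["b", "a"]


class TestWilcoxon:
    def test_small_sample_worked_example(self):
        w, p = wilcoxon_signed_rank([4, 2, 5], [1, 1, 3], alternative="greater")
        assert w == 6.0 and p == pytest.approx(1 / 8)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_p_matches_sign_enumeration(self, rng, n):
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n)
        d = x - y
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=len(d))
            if sum(r for s, r in zip(signs, ranks) if s) >= w_obs
        )
        _, p = wilcoxon_signed_rank(x, y, alternative="greater")
        assert p == pytest.approx(count / 2 ** len(d), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n15(self, rng):
        x = rng.normal(0.3, 1, 15)
        y = rng.normal(0.0, 1, 15)
        _, p_exact = wilcoxon_signed_rank(x, y, exact_max_n=25)
        _, p_approx = wilcoxon_signed_rank(x, y, exact_max_n=0)
        assert abs(p_exact - p_approx) < 0.01

    def test_zero_differences_dropped(self):
        w, p = wilcoxon_signed_rank([1, 2, 5, 7], [1, 2, 3, 4], alternative="greater")
        assert w == 3.0 and p == pytest.approx(0.25)

    def test_family_ordering_pairwise_and_degenerate(self):
        expr = pd.DataFrame(
            [[2.0, 4.0, 8.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
            index=["a", "b", "b_twin"], columns=["s1", "s2", "s3"],
        )
        out = family_expression_ordering(expr, ["a", "b", "b_twin"])
        ab = out[(out.gene_a == "a") & (out.gene_b == "b")].iloc[0]
        assert ab["p_greater"] == pytest.approx(1 / 8)
        twin = out[(out.gene_a == "b") & (out.gene_b == "b_twin")].iloc[0]
        assert twin["degenerate"] and twin["p_greater"] == 1.0

    def test_planted_family_ordering_is_decisive(self, rng):
        n = 150
        base = rng.normal(10, 1, n)
        expr = pd.DataFrame(
            {"m1": base + 2.0 + rng.normal(0, 0.3, n), "m2": base},
        ).T
        expr.columns = [f"s{i}" for i in range(n)]
        out = family_expression_ordering(expr, ["m1", "m2"])
        p = out[(out.gene_a == "m1") & (out.gene_b == "m2")]["p_greater"].iloc[0]
        assert p < 1e-10


class TestCoexpression:
    def test_anchor_duplicate_has_rho_one(self, rng):
        n = 40
        anchor = rng.normal(0, 1, n)
        expr = pd.DataFrame(
            {"anchor": anchor, "twin": anchor.copy(), "anti": -anchor},
        ).T
        expr.columns = [f"s{i}" for i in range(n)]
        out = coexpression_selection(expr, "anchor").set_index("gene_id")
        assert out.loc["twin", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)
        assert bool(out.loc["twin", "selected"])
        assert not bool(out.loc["anti", "selected"])

    def test_constant_anchor_rejected(self):
        expr = pd.DataFrame(
            np.vstack([np.ones(12), np.arange(12.0)]), index=["a", "g"],
            columns=[f"s{i}" for i in range(12)],
        )
        with pytest.raises(ValidationError):
            coexpression_selection(expr, "a")

    def test_planted_correlates_recovered_with_fdr_control(self, rng):
        n, n_null, n_corr = 150, 200, 20
        anchor = rng.normal(0, 1, n)
        rows = {"anchor": anchor}
        for i in range(n_corr):
            rows[f"c{i}"] = 0.6 * anchor + 0.8 * rng.normal(0, 1, n)
        for i in range(n_null):
            rows[f"n{i}"] = rng.normal(0, 1, n)
        expr = pd.DataFrame(rows).T
        expr.columns = [f"s{i}" for i in range(n)]
        out = coexpression_selection(expr, "anchor")
        selected = set(out.loc[out["selected"], "gene_id"])
        truth = {f"c{i}" for i in range(n_corr)}
        recall = len(selected & truth) / n_corr
        fdr = len(selected - truth) / max(1, len(selected))
        assert recall >= 0.9
        assert fdr <= 0.1


class TestFisher:
    @staticmethod
    def exact_upper_tail(a, b, c, d):
        """Hypergeometric tail by direct summation over more-extreme tables."""
        n_sel, K, N = a + b, a + c, a + b + c + d
        total = 0.0
        for k in range(a, min(n_sel, K) + 1):
            total += (
                math.comb(K, k) * math.comb(N - K, n_sel - k) / math.comb(N, n_sel)
            )
        return total

    def test_worked_example_against_summation(self):
        universe = [f"g{i}" for i in range(20)]
        selected = universe[:10]          # a+b = 10
        gene_set = universe[:8] + universe[10:11]  # a = 8, c = 1
        odds, p = fisher_gene_set(selected, gene_set, universe)
        assert p == pytest.approx(self.exact_upper_tail(8, 2, 1, 9), abs=1e-12)
        assert p == pytest.approx(0.00274, abs=5e-5)

    def test_proportional_margins_are_null(self):
        universe = [f"g{i}" for i in range(100)]
        selected = universe[:50]
        gene_set = universe[25:75]  # half in, half out
        _, p = fisher_gene_set(selected, gene_set, universe)
        assert p >= 0.5

    def test_perfect_containment_matches_enumeration(self):
        universe = [f"g{i}" for i in range(12)]
        gene_set = universe[:4]
        odds, p = fisher_gene_set(gene_set, gene_set, universe)
        assert p == pytest.approx(1 / math.comb(12, 4), abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_gene_set(set(), set(), set())


class TestExpressionTransforms:
    def test_quantile_normalization_equalizes_distributions(self, rng):
        raw = pd.DataFrame(
            rng.lognormal(3, 1, size=(200, 5)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(5)],
        )
        qn = log2_quantile_normalize(raw)
        sorted_cols = np.sort(qn.to_numpy(), axis=0)
        for j in range(1, 5):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0], atol=1e-9)

    def test_residualization_removes_linear_covariate(self, rng):
        n = 60
        age = rng.normal(50, 10, n)
        expr = pd.DataFrame(
            {"g1": 0.5 * age + rng.normal(0, 0.1, n), "g2": rng.normal(0, 1, n)}
        ).T
        expr.columns = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"age": age}, index=expr.columns)
        resid = residualize_covariates(expr, cov)
        r = stats.pearsonr(resid.loc["g1"], age).statistic
        assert abs(r) < 0.05
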