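"""The NB-Wald engine: normalization, dispersion, testing, BH."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from accessprior import nbglm
from accessprior.core import CountMatrix
from accessprior.nbglm import (
    ContrastSpec,
    EstimationError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    run_contrast,
    wald_test,
)


def make_cm(counts, n_a=None):
    counts = np.asarray(counts)
    F, n = counts.shape
    n_a = n_a if n_a is not None else n // 2
    return CountMatrix(
        counts,
        [f"f{i}" for i in range(F)],
        [f"s{j}" for j in range(n)],
        {f"s{j}": ("A" if j < n_a else "B") for j in range(n)},
    )


AB = ContrastSpec("ab", ("A",), ("B",))


def simulate_nb(rng, mu, alpha):
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_cm(np.tile([[10], [40], [7]], (1, 2)))
        assert np.allclose(estimate_size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_splits_symmetrically(self):
        base = np.array([[10], [40], [7]])
        cm = make_cm(np.hstack([base, 2 * base]))
        assert np.allclose(
            estimate_size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_recovers_true_depths_within_5pct(self, rng):
        mu = rng.lognormal(np.log(200), 0.6, size=500)
        depth = np.array([0.5, 0.8, 1.0, 1.3, 1.9, 2.5])
        counts = simulate_nb(rng, mu[:, None] * depth[None, :], 0.05)
        sf = estimate_size_factors(make_cm(counts))
        ratio = sf / depth
        ratio /= np.exp(np.mean(np.log(ratio)))  # factors are scale-free
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_feature_permutation_invariance(self, rng):
        counts = rng.integers(1, 100, size=(50, 4))
        sf = estimate_size_factors(make_cm(counts))
        sf_perm = estimate_size_factors(make_cm(counts[rng.permutation(50)]))
        assert np.allclose(sf, sf_perm)

    def test_no_universally_expressed_feature_errors(self):
        with pytest.raises(EstimationError):
            estimate_size_factors(make_cm([[0, 5], [3, 0]]))


class TestDispersions:
    def test_all_raw_at_prior_is_fixed_point(self):
        # engineered so every feature has the same raw dispersion: then the
        # shrunk value equals it regardless of the prior weight
        rng = np.random.default_rng(1)
        counts = simulate_nb(rng, np.full((400, 6), 200.0), 0.2)
        cm = make_cm(counts, n_a=3)
        sf = estimate_size_factors(cm)
        d = estimate_dispersions(cm, sf)
        same = np.isclose(d.raw, d.prior)
        assert np.allclose(d.shrunk[same], d.raw[same])

    def test_infinite_prior_weight_collapses_to_prior(self, rng):
        counts = simulate_nb(rng, np.full((100, 6), 150.0), 0.1)
        cm = make_cm(counts, n_a=3)
        sf = estimate_size_factors(cm)
        d = estimate_dispersions(cm, sf, prior_weight=1e12)
        assert np.allclose(d.shrunk, d.prior, rtol=1e-6)

    def test_shrunk_is_convex_combination(self, rng):
        counts = simulate_nb(rng, rng.lognormal(5, 0.5, 200)[:, None] * np.ones(8), 0.3)
        cm = make_cm(counts)
        d = estimate_dispersions(cm, estimate_size_factors(cm))
        lo = np.minimum(d.raw, d.prior) - 1e-12
        hi = np.maximum(d.raw, d.prior) + 1e-12
        assert np.all((d.shrunk >= lo) & (d.shrunk <= hi))

    def test_poisson_data_yields_near_zero_dispersion(self, rng):
        counts = rng.poisson(np.full((800, 8), 300.0))
        cm = make_cm(counts)
        d = estimate_dispersions(cm, estimate_size_factors(cm))
        assert np.median(d.shrunk) <= 0.05

    def test_single_sample_condition_rejected(self):
        cm = CountMatrix(
            [[5, 6, 7]], ["f0"], ["s0", "s1", "s2"],
            {"s0": "A", "s1": "B", "s2": "B"},
        )
        with pytest.raises(EstimationError, match="replicates"):
            estimate_dispersions(cm, np.ones(3))


class TestWald:
    def test_exact_null_constant_counts(self):
        cm = make_cm(np.tile([[50]], (3, 8)))
        _, tab = run_contrast(cm, AB)
        assert np.allclose(tab["log2fc"], 0.0, atol=1e-9)
        assert np.allclose(tab["p"], 1.0, atol=1e-9)

    def test_all_zero_feature_flagged(self, rng):
        counts = rng.integers(10, 100, size=(5, 6))
        counts[2] = 0
        cm = make_cm(counts, n_a=3)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        tab = wald_test(cm, sf, disp, AB)
        row = tab.iloc[2]
        assert row["all_zero"] and row["p"] == 1.0 and row["log2fc"] == 0.0

    def test_group_swap_negates_lfc_and_preserves_p(self, rng):
        counts = simulate_nb(rng, rng.lognormal(5, 0.7, 300)[:, None] * np.ones(8), 0.1)
        cm = make_cm(counts)
        _, t1 = run_contrast(cm, AB)
        _, t2 = run_contrast(cm, ContrastSpec("ba", ("B",), ("A",)))
        assert np.allclose(t1["log2fc"], -t2["log2fc"], atol=1e-6)
        assert np.allclose(t1["p"], t2["p"], atol=1e-9)

    def test_null_calibration_at_5pct(self, rng):
        mu = rng.lognormal(np.log(100), 0.7, size=2000)
        counts = simulate_nb(rng, mu[:, None] * np.ones(8), 0.1)
        _, tab = run_contrast(make_cm(counts), AB)
        frac = (tab["p"] < 0.05).mean()
        assert 0.035 <= frac <= 0.065

    def test_planted_lfc_recovered_with_small_bias(self, rng):
        mu = rng.lognormal(np.log(100), 0.5, size=2000)
        fold = np.ones((2000, 8))
        fold[:300, :4] = 4.0  # log2FC = 2 in the first 300 features
        counts = simulate_nb(rng, mu[:, None] * fold, 0.05)
        _, tab = run_contrast(make_cm(counts), AB)
        assert abs(tab["log2fc"][:300].mean() - 2.0) <= 0.3

    def test_wald_p_uniform_under_null(self, rng):
        mu = rng.lognormal(np.log(200), 0.4, size=1500)
        counts = simulate_nb(rng, mu[:, None] * np.ones(10), 0.08)
        _, tab = run_contrast(make_cm(counts, n_a=5), AB)
        ks = stats.kstest(tab["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_agrees_with_independent_nb_engine(self, rng):
        """Cross-check log2FC and calls against an independently developed
        NB shrinkage DE implementation on mixed null/signal data."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        F, n = 300, 8
        mu = rng.lognormal(np.log(100), 0.7, size=F)
        fold = np.ones((F, n))
        fold[:60, :4] = 2.0 ** rng.uniform(-2, 2, 60)[:, None]
        counts = simulate_nb(rng, mu[:, None] * fold, 0.05)
        cm = make_cm(counts)
        _, tab = run_contrast(cm, AB)
        dds = DeseqDataSet(
            counts=pd.DataFrame(counts.T, columns=cm.feature_ids),
            metadata=pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4}),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
        ds.summary()
        ref = ds.results_df.loc[cm.feature_ids]
        r = stats.pearsonr(tab["log2fc"], ref["log2FoldChange"]).statistic
        assert r > 0.99
        mine = set(tab.loc[tab["q"] < 0.05, "feature_id"])
        theirs = set(ref.index[ref["padj"] < 0.05])
        jaccard = len(mine & theirs) / max(1, len(mine | theirs))
        assert jaccard > 0.8


class TestBH:
    def test_step_up_worked_example(self):
        assert np.allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(Exception):
            bh_adjust([0.5, 1.2])

    def test_matches_definitional_scan_on_random_vectors(self, rng):
        def brute(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            q = np.empty(m)
            for rank_pos, idx in enumerate(order, start=1):
                q[idx] = min(
                    min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0
                )
            return q

        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), brute(p), atol=1e-12)

    def test_null_uniform_pvalues_yield_no_discoveries(self, rng):
        p = rng.random(1000)
        assert (bh_adjust(p) < 0.05).sum() <= 2


class TestRunContrast:
    def test_lfc_cutoff_empties_small_effects(self, rng):
        mu = rng.lognormal(np.log(100), 0.3, size=400)
        fold = np.ones((400, 8))
        fold[:100, :4] = 1.6  # |log2FC| ~ 0.68, below the cutoff of 1
        counts = simulate_nb(rng, mu[:, None] * fold, 0.01)
        spec = ContrastSpec("mig", ("A",), ("B",), direction="any", lfc_cutoff=1.0)
        sig, _ = run_contrast(make_cm(counts), spec)
        assert sig == set()

    def test_direction_greater_excludes_downregulated(self, rng):
        mu = rng.lognormal(np.log(200), 0.5, size=500)
        fold = np.ones((500, 8))
        fold[:50, :4] = 0.2  # strongly DOWN in A
        counts = simulate_nb(rng, mu[:, None] * fold, 0.05)
        sig, tab = run_contrast(make_cm(counts), AB)
        down = set(tab.loc[tab["log2fc"] < 0, "feature_id"])
        assert not (sig & down)
        sig_any, _ = run_contrast(
            make_cm(counts), ContrastSpec("any", ("A",), ("B",), direction="any")
        )
        assert len(sig_any & {f"f{i}" for i in range(50)}) >= 45
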