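import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import dexil
from dexil.decore import MAX_ABS_LOG2, contrast_weights
from dexil.simdata import CountMatrix


def _matrix(counts: np.ndarray, n_donors: int | None = None) -> CountMatrix:
    """Wrap a raw array in a minimal valid 2x2 design (donors = columns/4)."""
    counts = np.asarray(counts)
    m = counts.shape[1]
    assert m % 4 == 0
    n_donors = m // 4
    rows = []
    i = 0
    for d in range(n_donors):
        for il17 in (0, 1):
            for dex in (0, 1):
                rows.append({"sample_id": f"s{i}", "donor": f"D{d}", "il17": il17, "dex": dex})
                i += 1
    samples = pd.DataFrame(rows).set_index("sample_id")
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    return CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples.index),
        samples=samples,
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [20], [5]], (1, 4))
        m = _matrix(counts)
        s = dexil.estimate_size_factors(m)
        assert np.allclose(s, 1.0)

    def test_doubled_sample_splits_symmetrically(self):
        base = np.arange(1, 21).reshape(-1, 1)
        counts = np.hstack([base, 2 * base, base, 2 * base])
        s = dexil.estimate_size_factors(_matrix(counts))
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)] * 2)

    def test_single_gene_hand_computation(self):
        # counts {4, 9}: ratios to geomean 6 are {2/3, 3/2}, already geomean 1
        counts = pd.DataFrame([[4, 9]], index=["g"], columns=["a", "b"])
        s = dexil.estimate_size_factors(counts)
        assert np.allclose(s, [np.sqrt(4 / 9), np.sqrt(9 / 4)])

    def test_positive_counts_fallback_warns(self):
        counts = np.array([[5, 0, 7, 3], [0, 6, 2, 8]])
        with pytest.warns(UserWarning, match="positive-counts"):
            s = dexil.estimate_size_factors(_matrix(counts))
        assert (s > 0).all()


class TestDispersions:
    def test_poisson_counts_estimate_near_floor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(200, size=(400, 16))
        m = _matrix(counts)
        alpha = dexil.estimate_dispersions(m, dexil.estimate_size_factors(m))
        assert 1e-8 <= np.median(alpha) <= 0.05

    def test_underdispersed_counts_clamp_to_floor(self):
        # each gene constant across samples: variance 0 < mean everywhere
        counts = np.repeat(np.arange(50, 80)[:, None], 16, axis=1)
        m = _matrix(counts)
        s = pd.Series(1.0, index=m.sample_ids)
        alpha = dexil.estimate_dispersions(m, s)
        assert np.allclose(alpha, 1e-8)

    def test_nb_recovery(self):
        rng = np.random.default_rng(3)
        mu, a = 300.0, 0.2
        counts = rng.negative_binomial(1 / a, (1 / a) / (1 / a + mu), size=(200, 16))
        m = _matrix(counts)
        alpha = dexil.estimate_dispersions(m, dexil.estimate_size_factors(m))
        assert 0.1 <= np.median(alpha) <= 0.4


class TestNbGlmFit:
    def _two_group(self, n=8):
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        return X

    def test_equal_means_give_zero_coefficient(self):
        X = self._two_group()
        y = np.array([100, 100, 100, 100, 100, 100, 100, 100])
        beta, se, cov, conv, it, dev = dexil.fit_nb_glm(y, X, np.ones(8), 0.05)
        assert conv
        assert abs(beta[1]) < 1e-6

    def test_poisson_limit_matches_log_ratio_of_means(self):
        X = self._two_group()
        y = np.array([90, 110, 95, 105, 380, 420, 410, 390])
        beta, *_ = dexil.fit_nb_glm(y, X, np.ones(8), 1e-10)
        expected = np.log2(np.mean(y[4:]) / np.mean(y[:4]))
        assert abs(beta[1] - expected) < 1e-4

    def test_grid_search_oracle_equivalence(self):
        """IRLS matches a dense NB log-likelihood grid on a tiny instance."""
        X = np.column_stack([np.ones(5), np.array([0, 0, 1, 1, 1.0])])
        y = np.array([12, 18, 45, 60, 38])
        alpha = 0.1
        beta, *_ = dexil.fit_nb_glm(y, X, np.ones(5), alpha)

        size = 1 / alpha

        def negll(b0, b1):
            mu = np.exp(b0 + b1 * X[:, 1])
            return -scipy.stats.nbinom.logpmf(y, size, size / (size + mu)).sum()

        # coarse-to-fine grid, natural-log scale
        b0s = np.arange(0.0, 6.0, 0.05)
        b1s = np.arange(-4.0, 4.0, 0.05)
        grid = np.array([[negll(a_, b_) for b_ in b1s] for a_ in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        b0c, b1c = b0s[i], b1s[j]
        fine0 = np.arange(b0c - 0.06, b0c + 0.06, 0.0005)
        fine1 = np.arange(b1c - 0.06, b1c + 0.06, 0.0005)
        grid = np.array([[negll(a_, b_) for b_ in fine1] for a_ in fine0])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        ln2 = np.log(2)
        assert abs(beta[0] - fine0[i] / ln2) < 1e-3
        assert abs(beta[1] - fine1[j] / ln2) < 1e-3

    def test_monte_carlo_recovery(self):
        """beta_il17 = 2 log2, mu = 500, alpha = 0.05, 16 samples: each
        estimate within 0.5, the average over 200 replicate genes within 0.1."""
        rng = np.random.default_rng(8)
        n = 16
        X = np.column_stack([np.ones(n), np.tile([0, 1.0], n // 2)])
        mu = 500 * 2.0 ** (2.0 * X[:, 1])
        a = 0.05
        errs = []
        for _ in range(200):
            y = rng.negative_binomial(1 / a, (1 / a) / (1 / a + mu))
            beta, *_ = dexil.fit_nb_glm(y, X, np.ones(n), a)
            errs.append(beta[1] - 2.0)
        errs = np.array(errs)
        assert np.median(np.abs(errs)) < 0.25
        assert (np.abs(errs) < 0.5).mean() >= 0.95
        assert abs(errs.mean()) < 0.1

    def test_separated_gene_flagged_not_dropped(self):
        X = self._two_group()
        y = np.array([0, 0, 0, 0, 50, 60, 55, 45])
        beta, se, cov, conv, *_ = dexil.fit_nb_glm(y, X, np.ones(8), 0.05)
        assert not conv
        assert abs(beta[1]) <= MAX_ABS_LOG2


class TestWaldContrast:
    def test_identities(self, sim_default, de_default):
        _cfg, matrix, _truth = sim_default
        fit = dexil.fit_glm_matrix(matrix, dexil.DesignSpec())

        zero = dexil.wald_contrast(fit, np.zeros(len(fit.columns)))
        assert (zero["log2fc"] == 0).all() and (zero["pvalue"] == 1).all()

        # combination-vs-control = il17 + dex + interaction coefficients
        combo = dexil.wald_contrast(fit, contrast_weights(fit, "combo_vs_ctrl"))
        idx = {c: i for i, c in enumerate(fit.columns)}
        manual = (
            fit.beta[:, idx["il17"]]
            + fit.beta[:, idx["dex"]]
            + fit.beta[:, idx["il17:dex"]]
        )
        assert np.allclose(combo["log2fc"], manual)

        # stat^2 of a single coefficient equals its squared z
        single = dexil.wald_contrast(fit, contrast_weights(fit, "il17_vs_ctrl"))
        z = fit.beta[:, idx["il17"]] / fit.se[:, idx["il17"]]
        assert np.allclose(single["stat"] ** 2, z**2)

    def test_wrong_length_rejected(self, sim_default):
        _cfg, matrix, _ = sim_default
        fit = dexil.fit_glm_matrix(matrix, dexil.DesignSpec())
        with pytest.raises(ValueError, match="contrast length"):
            dexil.wald_contrast(fit, np.ones(2))


class TestBhAdjust:
    def test_all_ones(self):
        assert np.allclose(dexil.bh_adjust(np.ones(3)), 1.0)

    def test_stepup_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(dexil.bh_adjust(p), 0.04)

    def test_contract_bounds(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        q = dexil.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = dexil.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dexil.bh_adjust(np.array([0.5, 1.5]))


class TestRunDe:
    def test_planted_dex_suppression_consistency(self, sim_default, de_default):
        """dex_only genes are significant in dex_vs_ctrl and the interaction
        contrast flags the same genes (planted beta_int = -beta_dex)."""
        _cfg, _m, truth = sim_default
        t = truth.table.set_index("gene_id")
        strong = t[(t["class"] == "dex_only") & (t["mu"] >= 100)].index
        dex = de_default[de_default["contrast"] == "dex_vs_ctrl"].set_index("gene_id")
        inter = de_default[de_default["contrast"] == "interaction"].set_index("gene_id")
        dex_sig = dex.loc[strong, "padj"] < 0.05
        int_sig = inter.loc[strong, "padj"] < 0.05
        assert dex_sig.mean() >= 0.8
        assert int_sig.mean() >= 0.8
        assert (dex_sig & int_sig).sum() >= 0.7 * len(strong)

    def test_sample_scaling_invariance(self):
        """Doubling one sample's counts is absorbed by its size factor and
        leaves log2FCs unchanged.  Checked on the saturated 2x2 design (one
        insert per condition), where the fitted means equal the normalized
        data and the absorption is exact; in replicated designs the NB MLE
        re-weights the deeper sample slightly by construction."""
        rng = np.random.default_rng(21)
        counts = rng.poisson(200, size=(50, 4)) + 1
        samples = pd.DataFrame(
            {
                "donor": ["D1"] * 4,
                "il17": [0, 1, 0, 1],
                "dex": [0, 0, 1, 1],
            },
            index=pd.Index(["a", "b", "c", "d"], name="sample_id"),
        )
        genes = pd.Index([f"g{i}" for i in range(50)], name="gene_id")
        m1 = CountMatrix(
            counts=pd.DataFrame(counts, index=genes, columns=samples.index),
            samples=samples,
        )
        alpha = np.full(50, 0.05)
        fit1 = dexil.fit_glm_matrix(m1, dexil.DesignSpec(), dispersions=alpha)
        counts2 = m1.counts.copy()
        counts2.iloc[:, 0] = counts2.iloc[:, 0] * 2
        m2 = CountMatrix(counts=counts2, samples=samples)
        fit2 = dexil.fit_glm_matrix(m2, dexil.DesignSpec(), dispersions=alpha)
        assert np.allclose(
            fit2.size_factors.iloc[0] / fit1.size_factors.iloc[0],
            2.0 * (fit2.size_factors / fit1.size_factors).iloc[1],
            rtol=1e-9,
        )
        conv = fit1.converged & fit2.converged
        idx = fit1.columns.index("il17")
        diff = np.abs(fit1.beta[conv, idx] - fit2.beta[conv, idx])
        assert diff.max() < 1e-6

    def test_padj_monotone_in_p_within_contrast(self, de_default):
        for _c, g in de_default.groupby("contrast"):
            g = g.sort_values("pvalue")
            assert g["padj"].is_monotonic_increasing

    def test_cross_check_against_independent_nb_engine(self):
        """log2FC estimates agree with an independently developed NB-GLM DE
        implementation (pydeseq2, MLE coefficients) on a small unpaired run."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        m, _t = dexil.generate_counts(
            dexil.SimConfig(n_genes=300, seed=5, cilia_coupling=0.0)
        )
        de = dexil.run_de(m, dexil.DesignSpec(pairing=False))
        il17 = de[de["contrast"] == "il17_vs_ctrl"].set_index("gene_id")

        meta = m.samples.copy()
        meta["il17"] = meta["il17"].astype(str)
        meta["dex"] = meta["dex"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=m.counts.T, metadata=meta,
                design="~il17 + dex + il17:dex", quiet=True,
            )
            dds.deseq2()
            ds = DeseqStats(dds, contrast=["il17", "1", "0"], quiet=True)
            ds.summary()
        both = il17.join(ds.results_df[["log2FoldChange"]]).dropna()
        diff = (both["log2fc"] - both["log2FoldChange"]).abs()
        assert diff.median() < 0.05
        assert both["log2fc"].corr(both["log2FoldChange"]) > 0.99
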