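"""Differential-statistics unit tests: transforms, moderated t, BH, calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from icimeth.diffstats import (
    bh_adjust, beta_to_m, call_dmps, call_degs, differential_expression,
    m_to_beta, moderated_t, normalize_counts,
)


class TestBetaM:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1 - 1e-3))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_antisymmetry(self):
        b = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(beta_to_m(b), -beta_to_m(1 - b), atol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            beta_to_m(np.array([0.5, bad]))

    def test_dataframe_passthrough(self):
        df = pd.DataFrame([[0.5, 0.8]], index=["p1"], columns=["a", "b"])
        out = beta_to_m(df)
        assert isinstance(out, pd.DataFrame)
        assert list(out.columns) == ["a", "b"]


class TestModeratedT:
    def test_matches_pooled_t_without_shrinkage(self):
        # d0 = 0 disables shrinkage; must equal the ordinary pooled-variance
        # two-sample t computed independently by scipy, feature by feature.
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 20))
        g = np.array([0] * 10 + [1] * 10)
        res = moderated_t(X, g, d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(X[:, g == 1].T, X[:, g == 0].T, equal_var=True)
        np.testing.assert_allclose(res.table["t"], t_ref, atol=1e-8)
        np.testing.assert_allclose(res.table["p"], p_ref, atol=1e-8)

    def test_full_shrinkage_shares_one_variance(self):
        # d0 = inf: every feature is tested against the same prior variance,
        # so t must be exactly proportional to logFC.
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 12))
        g = np.array([0] * 6 + [1] * 6)
        res = moderated_t(X, g, d0_override=np.inf)
        ratio = res.table["t"] / res.table["logFC"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-10)

    def test_identical_groups_give_null(self):
        half = np.arange(15.0).reshape(5, 3)
        X = np.hstack([half, half])  # group 1 duplicates group 0 exactly
        g = np.array([0, 0, 0, 1, 1, 1])
        res = moderated_t(X, g)
        # groups contain identical case sets -> zero logFC everywhere
        np.testing.assert_allclose(res.table["logFC"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0, atol=1e-12)

    def test_constant_feature_no_failure(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 14))
        X[0] = 3.0  # constant in both groups
        g = np.array([0] * 7 + [1] * 7)
        res = moderated_t(X, g)
        row = res.table.iloc[0]
        assert row["logFC"] == 0.0
        assert np.isfinite(row["p"])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5000, 30))
        g = np.array([0] * 15 + [1] * 15)
        res = moderated_t(X, g)
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_needs_two_cases_per_group(self):
        with pytest.raises(ValueError):
            moderated_t(np.zeros((3, 3)), [0, 1, 1])


class TestBH:
    def test_hand_computed_step_up(self):
        # step-up: sorted p*(m/rank) then cummin from the largest rank
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.8]), [0.015, 0.06, 0.8], atol=1e-12
        )

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        perm = rng.permutation(200)
        adj = bh_adjust(p)
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, atol=1e-12)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestCalling:
    def _result(self, logfc, adj_p):
        table = pd.DataFrame({
            "logFC": logfc, "t": logfc, "p": adj_p, "adj_p": adj_p,
            "direction": np.sign(logfc).astype(int),
        }, index=[f"cg{i}" for i in range(len(logfc))])
        from icimeth.diffstats import DifferentialResult
        return DifferentialResult(table, d0=4.0, s0_sq=1.0, df=10, untested=[])

    def test_threshold_rules(self):
        res = self._result([1.5, 1.0, 2.0, -1.2], [0.005, 0.005, 0.02, 0.001])
        called = call_dmps(res)
        assert called == {("cg0", 1), ("cg3", -1)}  # cg1 boundary, cg2 fails p

    def test_equals_bruteforce(self):
        rng = np.random.default_rng(5)
        res = self._result(rng.normal(scale=1.2, size=300), rng.uniform(size=300))
        expected = {
            (probe, int(np.sign(row["logFC"])))
            for probe, row in res.table.iterrows()
            if abs(row["logFC"]) > 1 and row["adj_p"] < 0.01
        }
        assert call_dmps(res) == expected


class TestDifferentialExpression:
    @staticmethod
    def _nb(rng, mu, disp, size):
        n = 1 / disp
        return rng.negative_binomial(n, n / (n + mu), size=size)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(6)
        mu = rng.lognormal(4, 1, size=2000)
        counts = pd.DataFrame(
            self._nb(rng, mu[:, None], 0.1, (2000, 40)),
            index=[f"g{i}" for i in range(2000)],
        )
        res = differential_expression(counts, [0] * 20 + [1] * 20)
        frac = float((res.table["adj_p"] < 0.01).mean())
        assert frac <= 0.02  # BH at 0.01 under the global null

    def test_power_on_fourfold_shift(self):
        rng = np.random.default_rng(7)
        detected = 0
        reps = 100
        for _ in range(reps):
            mu = rng.lognormal(4, 1, size=200)
            counts = self._nb(rng, mu[:, None], 0.1, (200, 60)).astype(float)
            counts[0, 30:] *= 4.0  # 4x mean shift in group 1
            df = pd.DataFrame(np.round(counts), index=[f"g{i}" for i in range(200)])
            res = differential_expression(df, [0] * 30 + [1] * 30)
            if ("g0", 1) in call_degs(res):
                detected += 1
        assert detected >= 95

    def test_all_zero_gene_untested(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 0], [5, 8, 4, 9, 7, 6], [3, 2, 4, 2, 3, 5]],
            index=["dead", "g1", "g2"],
        )
        res = differential_expression(counts, [0, 0, 0, 1, 1, 1])
        assert res.untested == ["dead"]
        assert "dead" not in res.table.index

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            differential_expression(pd.DataFrame([[-1, 2, 1, 2]]), [0, 0, 1, 1])

    def test_size_factor_normalization_removes_depth(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(5, 1, size=300)  # per-gene expression level
        depth = np.array([1, 2, 4, 1, 3, 1, 2, 1, 5, 1], dtype=float)
        counts = pd.DataFrame(rng.poisson(mu[:, None] * depth[None, :]))
        norm = normalize_counts(counts)
        # after normalization, per-gene means must no longer track depth
        est_depth = norm.sum(axis=0) / norm.sum(axis=0).iloc[0]
        np.testing.assert_allclose(est_depth, 1.0, rtol=0.05)


def test_moderated_t_matches_limma(tmp_path):
    """Cross-check the empirical-Bayes test against limma's eBayes fit."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(200, 20)) * rng.lognormal(0, 0.5, size=(200, 1))
    X[:20, 10:] += 1.0
    g = np.array([0] * 10 + [1] * 10)
    res = moderated_t(X, g)

    mat = tmp_path / "m.tsv"
    out = tmp_path / "limma.tsv"
    pd.DataFrame(X).to_csv(mat, sep="\t", index=False)
    script = f"""
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{mat}"))
    design <- cbind(Intercept=1, Group=c(rep(0,10), rep(1,10)))
    fit <- eBayes(lmFit(x, design))
    write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior,
                           s0=fit$s2.prior),
                "{out}", sep="\t", row.names=FALSE)
    """
    import subprocess
    r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    if r.returncode != 0:
        pytest.skip(f"Rscript/limma unavailable: {r.stderr[:200]}")
    ref = pd.read_csv(out, sep="\t")
    np.testing.assert_allclose(res.table["t"], ref["t"], rtol=1e-4)
    np.testing.assert_allclose(res.table["p"], ref["p"], rtol=1e-4)
    assert res.d0 == pytest.approx(ref["d0"][0], rel=1e-3)
    assert res.s0_sq == pytest.approx(ref["s0"][0], rel=1e-3)
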