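import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellprop.cell_table import DesignMatrix
from cellprop.empirical_bayes import (
    VariancePrior,
    bh_adjust,
    fit_variance_prior,
    moderated_f_test,
    moderated_t_test,
    squeeze_var,
)
from cellprop.linear_model import ContrastFit, fit_clusterwise_ols, make_contrast


def _two_group_fit(y: np.ndarray, m: int):
    """OLS fit of clusters x (2m samples) data on the balanced 2-group design."""
    X = np.zeros((2 * m, 2))
    X[:m, 0] = 1.0
    X[m:, 1] = 1.0
    design = DesignMatrix(pd.DataFrame(X, columns=["g1", "g2"]), ("g1", "g2"))
    frame = pd.DataFrame(y.T, columns=[f"K{i}" for i in range(y.shape[0])])
    fit = fit_clusterwise_ols(frame, design)
    return fit, make_contrast(fit, ["g1", "g2"])


class TestVariancePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(6, 2.5), df=4)
        assert math.isinf(prior.d0)
        np.testing.assert_allclose(prior.s0_sq, 2.5, rtol=1e-10)

    def test_recovers_generating_parameters_of_scaled_f(self):
        # s^2 ~ s0^2 * F(df, d0): the marginal of sample variances under the
        # scaled-inverse-chi-square prior; the generator is the oracle.
        d0_true, s0_true, df = 4.0, 1.0, 10
        rng = np.random.default_rng(2024)
        sigma_sq = s0_true * stats.f.rvs(df, d0_true, size=2000, random_state=rng)
        prior = fit_variance_prior(sigma_sq, df)
        assert abs(prior.d0 - d0_true) / d0_true < 0.20
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.10

    def test_single_cluster_warns_and_returns_infinite_d0(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            prior = fit_variance_prior(np.array([1.7]), df=3)
        assert math.isinf(prior.d0)

    def test_invalid_prior_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariancePrior(d0=-1, s0_sq=1.0)
        with pytest.raises(ValueError):
            VariancePrior(d0=2.0, s0_sq=0.0)


class TestSqueezeVar:
    def test_limits_and_midpoint(self):
        s2 = np.array([2.0, 0.5])
        assert np.allclose(squeeze_var(s2, 10, VariancePrior(1e-300, 1.0)), s2)
        assert np.allclose(
            squeeze_var(s2, 10, VariancePrior(math.inf, 1.0)), [1.0, 1.0]
        )
        np.testing.assert_allclose(
            squeeze_var(np.array([2.0]), 10, VariancePrior(10.0, 1.0)), [1.5]
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_convex_combination_with_stated_weights(self, seed):
        rng = np.random.default_rng(seed)
        s2 = rng.uniform(0.1, 5, size=8)
        df, d0, s0 = 6.0, float(rng.uniform(0.5, 20)), float(rng.uniform(0.2, 3))
        post = squeeze_var(s2, df, VariancePrior(d0, s0))
        expected = (df / (d0 + df)) * s2 + (d0 / (d0 + df)) * s0
        np.testing.assert_allclose(post, expected, rtol=1e-12)
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()


class TestModeratedT:
    def test_degenerate_prior_reduces_to_classical_t(self):
        rng = np.random.default_rng(1)
        m = 4
        y = rng.normal(size=(3, 2 * m))
        y[1, m:] += 1.0
        _, contrast = _two_group_fit(y, m)
        # d0 -> 0: no moderation; must equal the equal-variance two-sample t
        out = moderated_t_test(contrast, VariancePrior(1e-300, 1.0))
        for k in range(3):
            t_ref, p_ref = stats.ttest_ind(y[k, m:], y[k, :m], equal_var=True)
            np.testing.assert_allclose(out.statistic.iloc[k], t_ref, rtol=1e-8)
            np.testing.assert_allclose(out.p_value.iloc[k], p_ref, rtol=1e-6)

    def test_zero_effect_gives_zero_t_and_unit_p(self):
        y = np.array([[1.0, 2.0, 1.0, 2.0]])
        _, contrast = _two_group_fit(y, 2)
        out = moderated_t_test(contrast, VariancePrior(4.0, 0.5))
        assert out.statistic.iloc[0] == 0.0
        assert out.p_value.iloc[0] == 1.0

    def test_toy_dataset_matches_hand_formula_chain(self):
        # brute-force chain: group means -> RSS -> squeeze -> t -> p
        y = np.array([[0.10, 0.20, 0.40, 0.50], [0.30, 0.30, 0.32, 0.28]])
        _, contrast = _two_group_fit(y, 2)
        prior = VariancePrior(d0=3.0, s0_sq=0.01)
        out = moderated_t_test(contrast, prior)
        for k in range(2):
            g1, g2 = y[k, :2], y[k, 2:]
            rss = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
            s2 = rss / 2.0
            post = (3.0 * 0.01 + 2.0 * s2) / (3.0 + 2.0)
            t = (g2.mean() - g1.mean()) / np.sqrt(post * (1 / 2 + 1 / 2))
            # total df = df + d0, capped at the 2 clusters' pooled residual df
            p = 2 * stats.t.sf(abs(t), min(2.0 + 3.0, 2 * 2.0))
            np.testing.assert_allclose(out.statistic.iloc[k], t, rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(out.p_value.iloc[k], p, rtol=1e-10)

    def test_t_magnitude_monotone_in_effect(self):
        y = np.array([[0.0, 0.1, 1.0, 1.1]])
        _, contrast = _two_group_fit(y, 2)
        prior = VariancePrior(5.0, 0.2)
        ts = []
        for scale in [0.5, 1.0, 2.0, 4.0]:
            scaled = ContrastFit(
                effects=contrast.effects * scale,
                stdev_unscaled=contrast.stdev_unscaled,
                cov_unscaled=contrast.cov_unscaled,
                sigma=contrast.sigma,
                df_residual=contrast.df_residual,
            )
            ts.append(abs(moderated_t_test(scaled, prior).statistic.iloc[0]))
        assert ts == sorted(ts)


class TestModeratedF:
    def test_f_equals_t_squared_for_two_conditions(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(4, 8))
        _, contrast = _two_group_fit(y, 4)
        prior = VariancePrior(6.0, float(np.var(y)))
        t_out = moderated_t_test(contrast, prior)
        f_out = moderated_f_test(contrast, prior)
        np.testing.assert_allclose(f_out.statistic, t_out.statistic**2, rtol=1e-10)
        np.testing.assert_allclose(f_out.p_value, t_out.p_value, rtol=1e-10)

    def test_three_group_f_with_degenerate_prior_matches_anova(self):
        rng = np.random.default_rng(11)
        m, groups = 5, 3
        y = rng.normal(size=(3, groups * m))
        y[0, :m] += 2.0
        X = np.zeros((groups * m, groups))
        for g in range(groups):
            X[g * m : (g + 1) * m, g] = 1.0
        design = DesignMatrix(
            pd.DataFrame(X, columns=["a", "b", "c"]), ("a", "b", "c")
        )
        frame = pd.DataFrame(y.T, columns=["K0", "K1", "K2"])
        contrast = make_contrast(fit_clusterwise_ols(frame, design), ["a", "b", "c"])
        out = moderated_f_test(contrast, VariancePrior(1e-300, 1.0))
        for k in range(3):
            F_ref, p_ref = stats.f_oneway(y[k, :m], y[k, m : 2 * m], y[k, 2 * m :])
            np.testing.assert_allclose(out.statistic.iloc[k], F_ref, rtol=1e-8)
            np.testing.assert_allclose(out.p_value.iloc[k], p_ref, rtol=1e-6)

    def test_equal_condition_means_give_zero_f(self):
        y = np.tile([1.0, 2.0], 3)[None, :]  # identical pattern in all groups
        X = np.kron(np.eye(3), np.ones((2, 1)))
        design = DesignMatrix(pd.DataFrame(X, columns=["a", "b", "c"]), ("a", "b", "c"))
        contrast = make_contrast(
            fit_clusterwise_ols(pd.DataFrame(y.T, columns=["K"]), design),
            ["a", "b", "c"],
        )
        out = moderated_f_test(contrast, VariancePrior(2.0, 0.5))
        np.testing.assert_allclose(out.statistic.iloc[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.p_value.iloc[0], 1.0)


def _bh_oracle(p):
    """Step-up rule by direct enumeration: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBHAdjust:
    def test_hand_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), [0.2] * 4)
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_step_up_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 30)))
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_permutation_equivariant_and_dominates_raw_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=12)
        q = bh_adjust(p)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-12)
        assert (q >= p).all() and (q <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestAgainstLimma:
    """Independent oracle: Bioconductor limma run through Rscript."""

    R_SCRIPT = """
    suppressMessages(library(limma))
    y <- as.matrix(read.table("{y}", header=FALSE))
    design <- as.matrix(read.table("{design}", header=FALSE))
    fit <- lmFit(y, design)
    fit2 <- contrasts.fit(fit, matrix(c(-1, 1), ncol=1))
    fit2 <- eBayes(fit2)
    out <- data.frame(coef=fit2$coefficients[,1], t=fit2$t[,1],
                      p=fit2$p.value[,1], s2post=fit2$s2.post)
    out$d0 <- fit2$df.prior
    out$s02 <- fit2$s2.prior
    write.table(format(out, digits=15), "{out}", sep="\\t", quote=FALSE)
    """

    def test_moderated_t_chain_matches_limma(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        rng = np.random.default_rng(123)
        m, n_clusters = 3, 8
        y = rng.normal(loc=1.0, scale=0.3, size=(n_clusters, 2 * m))
        y[0, m:] += 0.8

        fit, contrast = _two_group_fit(y, m)
        prior = fit_variance_prior(fit.sigma.to_numpy() ** 2, fit.df_residual)
        ours = moderated_t_test(contrast, prior)

        y_path, d_path, out_path = (tmp_path / f for f in ("y.txt", "d.txt", "o.txt"))
        np.savetxt(y_path, y)
        X = np.zeros((2 * m, 2))
        X[:m, 0] = 1.0
        X[m:, 1] = 1.0
        np.savetxt(d_path, X)
        script = self.R_SCRIPT.format(y=y_path, design=d_path, out=out_path)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")

        np.testing.assert_allclose(prior.d0, ref["d0"].iloc[0], rtol=1e-6)
        np.testing.assert_allclose(prior.s0_sq, ref["s02"].iloc[0], rtol=1e-6)
        np.testing.assert_allclose(
            contrast.effects.iloc[:, 0], ref["coef"], rtol=1e-8
        )
        np.testing.assert_allclose(ours.post_var, ref["s2post"], rtol=1e-6)
        np.testing.assert_allclose(ours.statistic, ref["t"], rtol=1e-6)
        np.testing.assert_allclose(ours.p_value, ref["p"], rtol=1e-6)
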