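"""Count models: NB-GLM, hurdle, variance partitioning, OGT analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from defensomics.abundance import (
    bin_ogt,
    hurdle_nb,
    kruskal_dunn,
    nagelkerke_r2,
    nb_glm,
    percent_change,
    size_regression_residual_test,
    spearman_rho,
    truncated_nb_loglik,
    varpart_two,
)


def simulate_nb(rng, mu, theta):
    lam = rng.gamma(theta, mu / theta)
    return rng.poisson(lam)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 5, 50)
        rho, _ = spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.arange(20.0)
        rho, _ = spearman_rho(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_pearson_on_midranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0])
        rho, _ = spearman_rho(x, y)
        oracle, _ = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))
        assert rho == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho(np.ones(10), np.arange(10.0))


class TestSizeRegression:
    def test_exact_linear_law(self):
        size = np.linspace(1, 5, 40)
        counts = 2.0 * size
        domain = np.array(["Archaea", "Bacteria"] * 20)
        r2, p = size_regression_residual_test(counts, size, domain)
        assert r2 == pytest.approx(1.0)
        assert p == 1.0  # residuals identically zero

    def test_domain_offset_flagged(self):
        rng = np.random.default_rng(1)
        n = 200
        size = rng.uniform(1, 5, n)
        domain = np.array(["Archaea"] * (n // 2) + ["Bacteria"] * (n // 2))
        counts = 3 * size + 5 * (domain == "Bacteria") + rng.normal(0, 1, n)
        _, p = size_regression_residual_test(counts, size, domain)
        assert p < 1e-6

    def test_equal_law_not_flagged(self):
        rng = np.random.default_rng(2)
        n = 400
        size = rng.uniform(1, 5, n)
        domain = np.array(["Archaea"] * (n // 2) + ["Bacteria"] * (n // 2))
        counts = 3 * size + rng.normal(0, 1, n)
        _, p = size_regression_residual_test(counts, size, domain)
        assert p > 0.01

    def test_single_domain_rejected(self):
        with pytest.raises(ValueError):
            size_regression_residual_test(
                np.arange(20.0), np.arange(20.0), np.array(["Archaea"] * 20)
            )


class TestVarpart:
    def test_components_sum_to_one(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=100)
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        vp = varpart_two(y, a, b)
        total = vp.unique_a + vp.unique_b + vp.shared + vp.unexplained
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_identical_blocks_share_everything(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=200)
        y = 2 * a + rng.normal(0, 0.5, 200)
        vp = varpart_two(y, a, a.copy())
        assert vp.unique_a == pytest.approx(0.0, abs=1e-9)
        assert vp.unique_b == pytest.approx(0.0, abs=1e-9)
        assert vp.shared > 0.8

    def test_pure_noise_block_contributes_nothing(self):
        rng = np.random.default_rng(5)
        n = 5000
        a = rng.normal(size=n)
        y = a + rng.normal(0, 1, n)
        noise = rng.normal(size=n)
        vp = varpart_two(y, a, noise)
        assert abs(vp.unique_b) < 0.01
        assert abs(vp.shared) < 0.01


class TestBinOgt:
    @pytest.mark.parametrize(
        "ogt,expected",
        [(20.0, "mesophilic"), (49.99, "mesophilic"), (50.0, "thermophilic"),
         (79.9, "thermophilic"), (80.0, "hyperthermophilic"), (85.0, "hyperthermophilic")],
    )
    def test_half_open_bins(self, ogt, expected):
        assert bin_ogt(ogt) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bin_ogt(float("nan"))


class TestKruskalDunn:
    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(6)
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(5, 1, 50)]
        )
        groups = np.array(["a"] * 50 + ["b"] * 50 + ["c"] * 50)
        omnibus_p, dunn = kruskal_dunn(values, groups)
        assert omnibus_p < 1e-10
        involving_c = dunn[(dunn["group_a"] == "c") | (dunn["group_b"] == "c")]
        assert (involving_c["p_adjusted"] < 0.001).all()
        not_c = dunn[(dunn["group_a"] != "c") & (dunn["group_b"] != "c")]
        assert (not_c["p_adjusted"] > 0.05).all()

    def test_bonferroni_is_p_times_k_capped(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=60)
        groups = np.repeat(["a", "b", "c"], 20)
        _, dunn = kruskal_dunn(values, groups)
        k = len(dunn)
        for _, row in dunn.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p"] * k))

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn(np.arange(5.0), np.array(["a", "a", "a", "a", "b"]))


class TestNbGlm:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.uniform(0, 10, n)
        beta0, beta1, theta = 1.0, 0.2, 2.0
        mu = np.exp(beta0 + beta1 * x)
        y = simulate_nb(rng, mu, theta)
        X = np.column_stack([np.ones(n), x])
        fit = nb_glm(y, X)
        assert fit.coefficients[0] == pytest.approx(beta0, abs=3 * fit.standard_errors[0])
        assert fit.coefficients[1] == pytest.approx(beta1, abs=3 * fit.standard_errors[1])
        assert fit.theta == pytest.approx(theta, rel=0.25)

    def test_poisson_limit_matches_poisson_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 3000
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        X = np.column_stack([np.ones(n), x])
        fit = nb_glm(y, X)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert fit.coefficients == pytest.approx(pois.params, abs=0.01)
        assert fit.theta > 50  # near-Poisson dispersion

    def test_covariate_rescaling_equivariance(self):
        rng = np.random.default_rng(10)
        n = 1000
        x = rng.uniform(0, 10, n)
        y = simulate_nb(rng, np.exp(1.0 + 0.15 * x), 2.0)
        f1 = nb_glm(y, np.column_stack([np.ones(n), x]))
        f2 = nb_glm(y, np.column_stack([np.ones(n), 10 * x]))
        assert f2.coefficients[1] == pytest.approx(f1.coefficients[1] / 10, rel=1e-4)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_glm(np.zeros(50), np.ones((50, 1)))

    def test_percent_change_transform(self):
        assert percent_change(np.log(1.357) / 10) == pytest.approx(35.7, abs=0.01)


class TestHurdle:
    def _simulate(self, seed=11, n=1500):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        # zero part: P(positive) = expit(0.8 + 0.5 x)
        positive = rng.random(n) < 1 / (1 + np.exp(-(0.8 + 0.5 * x)))
        # count part: zero-truncated NB(mu, theta)
        mu = np.exp(0.7 + 0.3 * x)
        y = np.zeros(n, dtype=int)
        idx = np.where(positive)[0]
        draws = simulate_nb(rng, mu[idx], 1.5)
        while True:  # redraw zeros to realize the truncated distribution
            zero_mask = draws == 0
            if not zero_mask.any():
                break
            draws[zero_mask] = simulate_nb(rng, mu[idx][zero_mask], 1.5)
        y[idx] = draws
        return y, X

    def test_count_part_matches_direct_truncated_mle(self):
        y, X = self._simulate()
        fit = hurdle_nb(y, X)
        pos = y > 0
        res = minimize(
            lambda p: -truncated_nb_loglik(p, y[pos].astype(float), X[pos]),
            x0=np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 10000, "maxfev": 10000},
        )
        assert fit.count_loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_both_parts_recovered(self):
        y, X = self._simulate(seed=12, n=4000)
        fit = hurdle_nb(y, X)
        assert fit.zero_coefficients == pytest.approx([0.8, 0.5], abs=0.2)
        assert fit.count_coefficients == pytest.approx([0.7, 0.3], abs=0.15)

    def test_no_zeros_gives_directed_error(self):
        y = np.ones(50, dtype=int)
        with pytest.raises(ValueError, match="plain NB"):
            hurdle_nb(y, np.ones((50, 1)))

    def test_hurdle_loglik_dominates_plain_nb(self):
        y, X = self._simulate(seed=13)
        fit = hurdle_nb(y, X)
        plain = nb_glm(y, X)
        assert fit.loglik >= plain.loglik - 1e-6


class TestNagelkerke:
    def test_zero_when_no_improvement(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_bounded_unit_interval(self):
        assert 0 <= nagelkerke_r2(-10.0, -80.0, 100) <= 1

    def test_matches_hand_formula(self):
        ll1, ll0, n = -45.0, -60.0, 80
        cs = 1 - np.exp(2 * (ll0 - ll1) / n)
        want = cs / (1 - np.exp(2 * ll0 / n))
        assert nagelkerke_r2(ll1, ll0, n) == pytest.approx(want)

    def test_worse_fit_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-70.0, -60.0, 50)
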