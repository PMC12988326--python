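"""Wilson intervals, Firth logistic regression, FDR, prevalence contrasts."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from defensomics.prevalence import (
    SeparationError,
    bh_fdr,
    completeness_adjusted_prevalence,
    firth_logistic,
    phylum_contrasts,
    wilson_ci,
)


def wilson_closed_form(k, n, conf=0.95):
    """Independent closed-form Wilson interval."""
    z = norm.ppf(0.5 + conf / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def penalized_loglik_oracle(X, y, beta):
    """Jeffreys-penalized logistic log-likelihood, written independently."""
    eta = X @ beta
    p = expit(eta)
    ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    W = np.diag(p * (1 - p))
    info = X.T @ W @ X
    return ll + 0.5 * np.log(np.linalg.det(info))


class TestWilsonCi:
    def test_zero_successes_lower_bound_zero(self):
        low, _ = wilson_ci(0, 10)
        assert low == 0.0

    @pytest.mark.parametrize("k,n", [(5, 10), (1, 50), (49, 50), (20, 100)])
    def test_matches_closed_form(self, k, n):
        got = wilson_ci(k, n)
        want = wilson_closed_form(k, n)
        assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_about_half(self):
        lo1, hi1 = wilson_ci(3, 10)
        lo2, hi2 = wilson_ci(7, 10)
        assert lo1 == pytest.approx(1 - hi2) and hi1 == pytest.approx(1 - lo2)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts(self, k, n):
        with pytest.raises(ValueError):
            wilson_ci(k, n)


class TestFirthLogistic:
    def test_balanced_symmetric_slope_zero(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0.0, 1.0] * 20)
        X = np.column_stack([np.ones(40), x])
        fit = firth_logistic(X, y)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize(
        "cells", [(15, 35, 40, 10), (3, 47, 20, 30), (1, 9, 5, 5)]
    )
    def test_2x2_matches_add_half_log_odds_ratio(self, cells):
        y1x0, y0x0, y1x1, y0x1 = cells
        x = np.array([0.0] * (y1x0 + y0x0) + [1.0] * (y1x1 + y0x1))
        y = np.array([1.0] * y1x0 + [0.0] * y0x0 + [1.0] * y1x1 + [0.0] * y0x1)
        X = np.column_stack([np.ones_like(x), x])
        fit = firth_logistic(X, y)
        expected = np.log(((y1x1 + 0.5) / (y0x1 + 0.5)) / ((y1x0 + 0.5) / (y0x0 + 0.5)))
        assert fit.coefficients[1] == pytest.approx(expected, abs=1e-6)
        assert fit.converged

    def test_matches_numeric_maximizer(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=60)
        y = (rng.random(60) < expit(0.5 + 1.2 * x)).astype(float)
        X = np.column_stack([np.ones(60), x])
        fit = firth_logistic(X, y)
        res = minimize(
            lambda b: -penalized_loglik_oracle(X, y, b),
            x0=np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.coefficients == pytest.approx(res.x, abs=1e-5)

    def test_finite_under_complete_separation(self):
        x = np.arange(10.0)
        y = (x > 4).astype(float)
        X = np.column_stack([np.ones(10), x])
        fit = firth_logistic(X, y)
        assert np.all(np.isfinite(fit.coefficients))
        assert np.all(np.isfinite(fit.standard_errors))

    def test_shrinks_toward_zero_relative_to_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        y = (rng.random(80) < expit(1.5 * x)).astype(float)
        X = np.column_stack([np.ones(80), x])
        mle = sm.Logit(y, X).fit(disp=0)
        fit = firth_logistic(X, y)
        assert abs(fit.coefficients[1]) <= abs(mle.params[1])

    def test_recentering_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = (rng.random(100) < expit(0.3 + 0.8 * x)).astype(float)
        X1 = np.column_stack([np.ones(100), x])
        X2 = np.column_stack([np.ones(100), x - 10.0])
        f1 = firth_logistic(X1, y)
        f2 = firth_logistic(X2, y)
        assert f1.coefficients[1] == pytest.approx(f2.coefficients[1], abs=1e-6)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        y = np.array([0.0, 1.0] * 5)
        with pytest.raises(ValueError):
            firth_logistic(X, y)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        out = bh_fdr(np.full(5, 0.2))
        assert np.allclose(out, 0.2)

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            p = rng.random(rng.integers(1, 20))
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert bh_fdr(p) == pytest.approx(adj)

    def test_never_decreases_and_preserves_max(self):
        p = np.array([0.9, 0.01, 0.04, 0.5])
        out = bh_fdr(p)
        assert np.all(out >= p)
        assert out[np.argmax(p)] == pytest.approx(p.max())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestPhylumContrasts:
    def _simulate(self, prevalences, n_each, seed):
        rng = np.random.default_rng(seed)
        presence, phylum = [], []
        for name, (p, n) in prevalences.items():
            presence.append((rng.random(n) < p).astype(float))
            phylum.extend([name] * n)
        return np.concatenate(presence), np.array(phylum)

    def test_small_phylum_excluded(self):
        y, ph = self._simulate({"A": (0.5, 100), "B": (0.5, 100), "C": (0.5, 9)}, None, 1)
        out = phylum_contrasts(y, ph, min_n=10)
        assert {c.phylum for c in out} == {"A", "B"}

    def test_strong_signal_flagged_over(self):
        y, ph = self._simulate(
            {"hot": (0.8, 200), "a": (0.2, 200), "b": (0.2, 200), "c": (0.2, 200)},
            None, 3,
        )
        out = {c.phylum: c for c in phylum_contrasts(y, ph)}
        assert out["hot"].direction == "over"
        assert all(out[k].direction in ("under", "ns") for k in ("a", "b", "c"))

    def test_ci_brackets_estimate_and_padj_monotone(self):
        y, ph = self._simulate({"A": (0.4, 150), "B": (0.6, 150), "C": (0.5, 150)}, None, 5)
        for c in phylum_contrasts(y, ph):
            assert c.ci_low <= c.estimate <= c.ci_high
            assert c.p_adjusted >= c.p_raw - 1e-12

    def test_all_small_phyla_rejected(self):
        y, ph = self._simulate({"A": (0.5, 5), "B": (0.5, 5)}, None, 2)
        with pytest.raises(ValueError):
            phylum_contrasts(y, ph, min_n=10)


class TestCompletenessAdjusted:
    def test_recovers_known_logistic_truth(self):
        rng = np.random.default_rng(6)
        n = 5000
        completeness = rng.uniform(0.5, 1.0, n)
        domain = np.where(rng.random(n) < 0.5, "Archaea", "Bacteria")
        a, b, c = -1.0, 2.0, 0.7
        eta = a + b * completeness + c * (domain == "Bacteria")
        y = (rng.random(n) < expit(eta)).astype(float)
        out = completeness_adjusted_prevalence(y, completeness, domain).set_index("domain")
        truth_arch = expit(a + b)
        truth_bact = expit(a + b + c)
        assert out.loc["Archaea", "ci_low"] <= truth_arch <= out.loc["Archaea", "ci_high"]
        assert out.loc["Bacteria", "ci_low"] <= truth_bact <= out.loc["Bacteria", "ci_high"]

    def test_constant_complete_cohort_returns_sample_prevalence(self):
        rng = np.random.default_rng(7)
        n = 400
        domain = np.array(["Archaea"] * (n // 2) + ["Bacteria"] * (n // 2))
        y = np.concatenate(
            [(rng.random(n // 2) < 0.3), (rng.random(n // 2) < 0.6)]
        ).astype(float)
        out = completeness_adjusted_prevalence(y, np.ones(n), domain).set_index("domain")
        assert out.loc["Archaea", "prevalence"] == pytest.approx(
            y[domain == "Archaea"].mean(), abs=1e-6
        )
        assert out.loc["Bacteria", "prevalence"] == pytest.approx(
            y[domain == "Bacteria"].mean(), abs=1e-6
        )

    def test_separation_raises_directed_error(self):
        n = 100
        domain = np.array(["Archaea"] * 50 + ["Bacteria"] * 50)
        completeness = np.linspace(0.5, 1.0, n)
        y = (domain == "Bacteria").astype(float)  # perfectly separated
        with pytest.raises(SeparationError, match="firth"):
            completeness_adjusted_prevalence(y, completeness, domain)
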