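"""Count modelling of defense-system abundance.

Defense counts per genome are overdispersed, so abundance-vs-covariate
relationships are fitted with negative-binomial GLMs (log link, NB2
variance ``mu + mu²/theta``); responses with excess zeros use a hurdle
model — a logistic part for crossing zero and a zero-truncated NB part on
the positives. Effect sizes on temperature are reported as percent change
per 10 °C, ``100·(exp(10·β) − 1)``; explanatory power as Nagelkerke's
pseudo-R². Genome-size structure is examined by Spearman correlation, OLS
with between-domain residual rank tests, and two-block variance
partitioning on adjusted R².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import norm
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.discrete.truncated_model import TruncatedLFNegativeBinomialP


# ----------------------------------------------------------------- generic

def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; large-sample p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def size_regression_residual_test(
    counts: np.ndarray, size_mb: np.ndarray, domain: np.ndarray
) -> tuple[float, float]:
    """OLS of counts on genome size; Wilcoxon rank-sum on residuals by domain.

    Returns ``(r_squared, residual_test_p)``: how much of the count
    variance genome size explains, and whether residual abundance still
    differs between the two domains once size is accounted for.
    """
    counts = np.asarray(counts, dtype=float)
    size_mb = np.asarray(size_mb, dtype=float)
    domain = np.asarray(domain, dtype=object)
    labels = sorted(np.unique(domain))
    if len(labels) != 2:
        raise ValueError("residual test needs exactly two domains")
    for lab in labels:
        if (domain == lab).sum() < 10:
            raise ValueError(f"domain {lab!r} has fewer than 10 genomes")
    X = sm.add_constant(size_mb)
    res = sm.OLS(counts, X).fit()
    resid = res.resid
    a = resid[domain == labels[0]]
    b = resid[domain == labels[1]]
    scale = max(1.0, float(np.max(np.abs(counts))))
    if np.max(np.abs(resid)) < 1e-10 * scale:  # perfect fit: nothing to compare
        return float(res.rsquared), 1.0
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.rsquared), float(p)


@dataclass
class VarPartResult:
    """Two-block variance partition on adjusted R²."""

    unique_a: float
    unique_b: float
    shared: float
    unexplained: float


def _adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    res = sm.OLS(y, sm.add_constant(X)).fit()
    return float(res.rsquared_adj)


def varpart_two(
    y: np.ndarray, predictor_a: np.ndarray, predictor_b: np.ndarray
) -> VarPartResult:
    """Partition explained variance between two predictor blocks.

    From the adjusted R² of the fits on A, B and A+B: unique_a = R²(ab) −
    R²(b); unique_b = R²(ab) − R²(a); shared = R²(a) + R²(b) − R²(ab);
    unexplained = 1 − R²(ab). Small negative components can occur with
    adjusted R² and are reported as-is. Components sum to 1 by
    construction.
    """
    y = np.asarray(y, dtype=float)
    A = np.atleast_2d(np.asarray(predictor_a, dtype=float))
    B = np.atleast_2d(np.asarray(predictor_b, dtype=float))
    if A.shape[0] == 1:
        A = A.T
    if B.shape[0] == 1:
        B = B.T
    n = y.size
    if n <= A.shape[1] + B.shape[1] + 1:
        raise ValueError("need n greater than the number of parameters")
    for name, block in (("a", A), ("b", B)):
        if np.linalg.matrix_rank(sm.add_constant(block)) < block.shape[1] + 1:
            raise ValueError(f"predictor block {name} is collinear")
    r2_a = _adjusted_r2(y, A)
    r2_b = _adjusted_r2(y, B)
    AB = np.column_stack([A, B])
    if np.linalg.matrix_rank(sm.add_constant(AB)) < AB.shape[1] + 1:
        # identical blocks: joint fit adds nothing beyond either alone
        r2_ab = max(r2_a, r2_b)
    else:
        r2_ab = _adjusted_r2(y, AB)
    return VarPartResult(
        unique_a=r2_ab - r2_b,
        unique_b=r2_ab - r2_a,
        shared=r2_a + r2_b - r2_ab,
        unexplained=1.0 - r2_ab,
    )


# --------------------------------------------------------------------- OGT

OGT_BINS = ("mesophilic", "thermophilic", "hyperthermophilic")


def bin_ogt(ogt_c: float) -> str:
    """Half-open temperature bins: <50 °C mesophilic, [50, 80) thermophilic,
    >=80 °C hyperthermophilic."""
    if not np.isfinite(ogt_c):
        raise ValueError("OGT must be finite")
    if ogt_c < 50:
        return "mesophilic"
    if ogt_c < 80:
        return "thermophilic"
    return "hyperthermophilic"


def kruskal_dunn(
    values: np.ndarray, groups: np.ndarray, correction: str = "bonferroni"
) -> tuple[float, pd.DataFrame]:
    """Kruskal–Wallis omnibus plus Dunn's pairwise post-hoc z tests.

    Dunn's z uses tie-corrected rank variance; pairwise p-values are
    Bonferroni-multiplied by the number of comparisons and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(np.unique(groups))
    samples = [values[groups == l] for l in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    _, omnibus_p = stats.kruskal(*samples)

    N = values.size
    ranks = stats.rankdata(values)
    mean_rank = {l: float(ranks[groups == l].mean()) for l in labels}
    n_by = {l: int((groups == l).sum()) for l in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    k = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / n_by[a] + 1.0 / n_by[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2 * norm.sf(abs(z))
        p_adj = min(1.0, p * k) if correction == "bonferroni" else p
        rows.append(
            {"group_a": a, "group_b": b, "z": float(z), "p": float(p),
             "p_adjusted": float(p_adj)}
        )
    return float(omnibus_p), pd.DataFrame(rows)


# ------------------------------------------------------------------ NB GLM

@dataclass
class NBFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    theta: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")


def nb_glm(counts: np.ndarray, design: np.ndarray) -> NBFit:
    """Negative-binomial (NB2) regression with log link, MLE in β and θ.

    ``design`` must include its own intercept column if one is wanted.
    Dispersion is parameterized as θ = 1/α where Var = μ + α·μ².
    """
    y = np.asarray(counts, dtype=float)
    X = np.asarray(design, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if np.all(y == 0):
        raise ValueError("all counts are zero: degenerate fit")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = NegativeBinomial(y, X, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(method="bfgs", disp=0, maxiter=500)
            converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            res = model.fit(method="bfgs", disp=0, maxiter=1000,
                            start_params=res.params)
            converged = bool(res.mle_retvals.get("converged", True))
    alpha = max(float(res.params[-1]), 1e-8)
    return NBFit(
        coefficients=np.asarray(res.params[:-1], dtype=float),
        standard_errors=np.asarray(res.bse[:-1], dtype=float),
        theta=1.0 / alpha,
        loglik=float(res.llf),
        converged=converged,
    )


def percent_change(beta: float, delta: float = 10.0) -> float:
    """Percent change in expected count per ``delta`` units of a covariate
    under a log link: ``100·(exp(delta·β) − 1)``."""
    return float(100.0 * (np.exp(delta * beta) - 1.0))


def nagelkerke_r2(fit_loglik: float, null_loglik: float, n: int) -> float:
    """Nagelkerke's pseudo-R²: Cox–Snell R² scaled by its maximum."""
    if fit_loglik < null_loglik - 1e-9:
        raise ValueError("fitted log-likelihood must be >= null log-likelihood")
    cox_snell = 1.0 - np.exp(2.0 * (null_loglik - fit_loglik) / n)
    max_cs = 1.0 - np.exp(2.0 * null_loglik / n)
    if max_cs <= 0:
        return 0.0
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


# ------------------------------------------------------------------ hurdle

@dataclass
class HurdleFit:
    zero_coefficients: np.ndarray
    count_coefficients: np.ndarray
    count_theta: float
    zero_loglik: float
    count_loglik: float

    @property
    def loglik(self) -> float:
        return self.zero_loglik + self.count_loglik


def truncated_nb_loglik(
    params: np.ndarray, y: np.ndarray, X: np.ndarray
) -> float:
    """Zero-truncated NB2 log-likelihood; params = (β..., log θ).

    Each NB term is renormalized by 1 − P(0; μ, θ). Exposed for use as an
    independent check on the fitted count part.
    """
    beta = params[:-1]
    theta = np.exp(params[-1])
    mu = np.exp(X @ beta)
    # NB2 pmf: C(y+theta-1, y) (theta/(theta+mu))^theta (mu/(theta+mu))^y
    from scipy.special import gammaln

    ll = (
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    p0 = (theta / (theta + mu)) ** theta
    return float((ll - np.log1p(-p0)).sum())


def hurdle_nb(
    counts: np.ndarray,
    design_zero: np.ndarray,
    design_count: np.ndarray | None = None,
) -> HurdleFit:
    """Hurdle model: logistic zero part + zero-truncated NB count part.

    The zero part models the probability of a positive count; the count
    part is fitted by MLE on the positive observations only, with each NB
    term divided by ``1 − P(0)``. Predictor sets default to identical.
    """
    y = np.asarray(counts, dtype=float)
    Xz = np.asarray(design_zero, dtype=float)
    Xc = np.asarray(design_count, dtype=float) if design_count is not None else Xz
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    positive = y > 0
    if positive.all():
        raise ValueError(
            "no zero counts: the hurdle zero part is degenerate — fit a plain NB"
        )
    if not positive.any():
        raise ValueError("no positive counts: the truncated part is empty")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zero_res = sm.Logit(positive.astype(float), Xz).fit(disp=0)
        trunc = TruncatedLFNegativeBinomialP(
            y[positive], Xc[positive], truncation=0, p=2
        )
        count_res = trunc.fit(disp=0, maxiter=500)
        if not count_res.mle_retvals.get("converged", True):
            count_res = trunc.fit(
                method="bfgs", disp=0, maxiter=1000, start_params=count_res.params
            )
    alpha = max(float(count_res.params[-1]), 1e-8)
    return HurdleFit(
        zero_coefficients=np.asarray(zero_res.params, dtype=float),
        count_coefficients=np.asarray(count_res.params[:-1], dtype=float),
        count_theta=1.0 / alpha,
        zero_loglik=float(zero_res.llf),
        count_loglik=float(count_res.llf),
    )


# ------------------------------------------------------------- batteries

def ogt_nb_model(cohort: pd.DataFrame, response: str = "total_systems") -> dict:
    """NB-GLM of a count response on OGT; reports percent change per 10 °C
    and Nagelkerke pseudo-R² against the intercept-only model."""
    y = cohort[response].to_numpy()
    X = np.column_stack([np.ones(len(cohort)), cohort["ogt_c"].to_numpy()])
    fit = nb_glm(y, X)
    null = nb_glm(y, np.ones((len(cohort), 1)))
    beta_ogt = float(fit.coefficients[1])
    se = float(fit.standard_errors[1])
    z = beta_ogt / se if se > 0 else np.nan
    return {
        "beta_ogt": beta_ogt,
        "se": se,
        "p": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        "percent_change_per_10C": percent_change(beta_ogt),
        "theta": fit.theta,
        "pseudo_r2": nagelkerke_r2(fit.loglik, null.loglik, len(cohort)),
    }


def predictor_pseudo_r2(
    cohort: pd.DataFrame,
    response: str = "total_systems",
    include_ogt: bool = True,
) -> pd.DataFrame:
    """One-predictor NB models (log genome size, phylum, completeness, OGT)
    plus the full model, each scored by Nagelkerke pseudo-R²."""
    y = cohort[response].to_numpy()
    n = len(cohort)
    ones = np.ones((n, 1))
    null = nb_glm(y, ones)

    def dummies(col: str) -> np.ndarray:
        levels = sorted(cohort[col].unique())[1:]
        return np.column_stack(
            [(cohort[col] == l).to_numpy(dtype=float) for l in levels]
        ) if levels else np.empty((n, 0))

    blocks: dict[str, np.ndarray] = {
        "log_size": np.log(cohort["size_mb"].to_numpy())[:, None],
        "phylum": dummies("phylum"),
        "completeness": cohort["completeness"].to_numpy()[:, None],
    }
    if include_ogt and "ogt_c" in cohort:
        blocks["ogt"] = cohort["ogt_c"].to_numpy()[:, None]
    rows = []
    full_parts = []
    for name, block in blocks.items():
        if block.shape[1] == 0:
            continue
        fit = nb_glm(y, np.column_stack([ones, block]))
        rows.append(
            {"predictor": name,
             "pseudo_r2": nagelkerke_r2(fit.loglik, null.loglik, n)}
        )
        full_parts.append(block)
    full = nb_glm(y, np.column_stack([ones] + full_parts))
    rows.append(
        {"predictor": "full", "pseudo_r2": nagelkerke_r2(full.loglik, null.loglik, n)}
    )
    return pd.DataFrame(rows)
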