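"""Presence/absence modelling of defense-system prevalence.

Rare systems within small phyla produce separated logistic likelihoods with
divergent maximum-likelihood estimates, so phylum-level prevalence is
modelled with Firth's bias-reduced logistic regression: the Jeffreys-prior
penalized likelihood ℓ(β) + ½ log det I(β) has a finite maximizer even
under complete separation. Phylum prevalences are compared against the
(unweighted) overall mean of phylum marginal means on the logit scale, with
Benjamini–Hochberg control across phyla.

Genome incompleteness deflates observed prevalence; a logistic model with
completeness and domain as predictors extrapolates prevalence to a complete
genome (completeness = 1), with Wald intervals built on the logit scale and
mapped through the inverse logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


class SeparationError(RuntimeError):
    """Perfect separation in an ordinary logistic fit; use firth_logistic."""


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    if not 0 < conf < 1:
        raise ValueError("conf must be in (0, 1)")
    low, high = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(low), float(high)


@dataclass
class FirthFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    penalized_loglik: float
    converged: bool
    iterations: int
    cov: np.ndarray


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood via log1p(exp) for stability
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    p = expit(eta)
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    design: np.ndarray,
    response: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthFit:
    """Bias-reduced (Firth) logistic regression with a logit link.

    Newton iteration on the Firth-modified score
    ``U*(β) = Xᵀ(y − p + h ∘ (½ − p))`` where ``h`` is the diagonal of the
    logistic hat matrix, with step-halving whenever a step decreases the
    penalized log-likelihood. Standard errors come from the Fisher
    information at the optimum.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    n, k = X.shape
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = p * (1 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        # hat diagonal of W^1/2 X (X'WX)^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        if np.linalg.norm(score) < tol:
            converged = True
            break
        step = info_inv @ score
        new_beta = beta + step
        new_ll = _penalized_loglik(X, y, new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _penalized_loglik(X, y, new_beta)
            halvings += 1
        # objective stalled at machine resolution with a near-zero score:
        # the optimum is resolved as finely as floats allow
        if new_ll - ll < 1e-12 and np.linalg.norm(score) < np.sqrt(tol):
            converged = True
            break
        beta, ll = new_beta, new_ll

    p = expit(X @ beta)
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    cov = np.linalg.inv(info)
    return FirthFit(
        coefficients=beta,
        standard_errors=np.sqrt(np.diag(cov)),
        penalized_loglik=ll,
        converged=converged,
        iterations=it,
        cov=cov,
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PrevalenceContrast:
    phylum: str
    estimate: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_adjusted: float
    direction: str  # over / under / ns
    n: int


def phylum_contrasts(
    presence: np.ndarray,
    phylum: np.ndarray,
    min_n: int = 10,
    alpha: float = 0.05,
    conf: float = 0.95,
) -> list[PrevalenceContrast]:
    """Per-phylum prevalence vs the overall mean, on the logit scale.

    Fits a Firth model ``presence ~ phylum`` (cell-means coding), takes
    each phylum's marginal mean on the link scale, and tests the Wald
    contrast against the unweighted average of all phylum means, with
    Benjamini–Hochberg adjustment across phyla. Phyla with fewer than
    ``min_n`` genomes are excluded up front.
    """
    presence = np.asarray(presence, dtype=float).ravel()
    phylum = np.asarray(phylum, dtype=object).ravel()
    if presence.shape != phylum.shape:
        raise ValueError("presence/phylum length mismatch")
    labels, counts = np.unique(phylum, return_counts=True)
    keep = [l for l, c in zip(labels, counts) if c >= min_n]
    if len(keep) < 2:
        raise ValueError(f"need >= 2 phyla with n >= {min_n}")
    mask = np.isin(phylum, keep)
    y = presence[mask]
    ph = phylum[mask]
    sizes = {l: int((ph == l).sum()) for l in keep}

    # cell-means design: one indicator per phylum, no intercept
    X = np.column_stack([(ph == l).astype(float) for l in keep])
    fit = firth_logistic(X, y)
    eta = fit.coefficients  # phylum marginal means on the logit scale
    m = len(keep)
    grand = eta.mean()
    z_crit = norm.ppf(0.5 + conf / 2)

    results = []
    p_raw = []
    for i, label in enumerate(keep):
        c = -np.ones(m) / m
        c[i] += 1.0  # contrast: phylum i minus unweighted grand mean
        se_c = float(np.sqrt(c @ fit.cov @ c))
        z = float((eta[i] - grand) / se_c) if se_c > 0 else 0.0
        p = float(2 * norm.sf(abs(z)))
        p_raw.append(p)
        se_i = float(np.sqrt(fit.cov[i, i]))
        results.append(
            PrevalenceContrast(
                phylum=str(label),
                estimate=float(expit(eta[i])),
                ci_low=float(expit(eta[i] - z_crit * se_i)),
                ci_high=float(expit(eta[i] + z_crit * se_i)),
                p_raw=p,
                p_adjusted=np.nan,
                direction="ns",
                n=sizes[label],
            )
        )
    adjusted = bh_fdr(np.array(p_raw))
    for i, res in enumerate(results):
        res.p_adjusted = float(adjusted[i])
        if res.p_adjusted < alpha:
            res.direction = "over" if eta[i] > grand else "under"
    return results


def contrasts_to_frame(contrasts: list[PrevalenceContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phylum": c.phylum, "n": c.n, "estimate": c.estimate,
                "ci_low": c.ci_low, "ci_high": c.ci_high,
                "p_raw": c.p_raw, "p_adjusted": c.p_adjusted,
                "direction": c.direction,
            }
            for c in contrasts
        ]
    )


def completeness_adjusted_prevalence(
    presence: np.ndarray,
    completeness: np.ndarray,
    domain: np.ndarray,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Predicted prevalence at completeness = 1 per domain.

    Ordinary logistic regression ``presence ~ completeness + domain``;
    predictions at a fully complete genome with Wald intervals computed on
    the logit scale and transformed through the inverse logit. Perfect
    separation raises :class:`SeparationError` (the Firth routine handles
    that regime).
    """
    presence = np.asarray(presence, dtype=float).ravel()
    completeness = np.asarray(completeness, dtype=float).ravel()
    domain = np.asarray(domain, dtype=object).ravel()
    if np.any(completeness <= 0) or np.any(completeness > 1):
        raise ValueError("completeness must be in (0, 1]")
    domains = sorted(np.unique(domain))
    if len(domains) < 2:
        raise ValueError("both domains must be present")

    # constant completeness carries no information and collides with the
    # intercept; the model then reduces to per-domain prevalence
    varying = np.ptp(completeness) > 1e-12
    cols = [np.ones_like(presence)]
    if varying:
        cols.append(completeness)
    cols += [(domain == d).astype(float) for d in domains[1:]]
    X = np.column_stack(cols)
    model = sm.GLM(presence, X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
    except Exception as exc:  # PerfectSeparation or numerical failure
        raise SeparationError(
            f"logistic fit failed ({exc}); data may be separated — "
            "use firth_logistic"
        ) from exc
    fitted = res.predict(X)
    if fitted.min() < 1e-10 or fitted.max() > 1 - 1e-10:
        raise SeparationError(
            "fitted probabilities at 0/1: data appear separated — use firth_logistic"
        )

    z_crit = norm.ppf(0.5 + conf / 2)
    offset = 2 if varying else 1
    rows = []
    for d in domains:
        x = np.zeros(X.shape[1])
        x[0] = 1.0
        if varying:
            x[1] = 1.0  # completeness = 1
        for j, other in enumerate(domains[1:], start=offset):
            x[j] = 1.0 if d == other else 0.0
        eta = float(x @ res.params)
        se = float(np.sqrt(x @ res.cov_params() @ x))
        rows.append(
            {
                "domain": d,
                "prevalence": float(expit(eta)),
                "ci_low": float(expit(eta - z_crit * se)),
                "ci_high": float(expit(eta + z_crit * se)),
                "n": int((domain == d).sum()),
            }
        )
    return pd.DataFrame(rows)
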