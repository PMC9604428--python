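"""Heteroscedastic normal location-scale models and scale comparisons.

The eigenvalue of a PC-score vector is its variance, so group or covariate
effects on noise components become effects on the *scale* parameter of a
normal model for the scores.  This module fits normal models in which both
the mean and the standard deviation depend on covariates (the normal
location-scale family, with a log link on sigma), compares fitted scale
parameters between groups with Wald tests, and controls the false discovery
rate over families of comparisons.

Two fitting routines are provided:

* :func:`fit_group_location_scale` — a saturated one-way layout.  Means and
  scales decouple and have closed-form maximum-likelihood solutions:
  mu_k = group mean, sigma_k = group ML standard deviation, with
  se(sigma_k) = sigma_k / sqrt(2 n_k) and se(log sigma_k) = 1 / sqrt(2 n_k).
* :func:`fit_location_scale_regression` — y ~ Normal(a0 + a x,
  exp(b0 + b x)), fitted by Fisher scoring.  For the normal family the
  expected information between location and scale blocks is zero, so the
  algorithm alternates weighted least squares for the location
  coefficients with a Newton step on the log-scale coefficients.

Maximum-likelihood (1/n) variances are used inside these fits; descriptive
estimators elsewhere in the package use unbiased (n-1) variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScaleModelFit",
    "ComparisonResult",
    "ConvergenceError",
    "fit_group_location_scale",
    "fit_location_scale_regression",
    "wald_compare",
    "compare_groups",
    "fdr_adjust",
    "noise_from_scale",
    "adjust_for_litter_size",
]


class ConvergenceError(RuntimeError):
    """Scoring iterations exhausted; carries the last iterate in ``last_fit``."""

    def __init__(self, message: str, last_fit: "ScaleModelFit"):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class ScaleModelFit:
    """A fitted normal location-scale model.

    ``location_coeffs``/``scale_coeffs`` map coefficient names to point
    estimates; scale coefficients live on the log link.  For a saturated
    group model the names are the group levels and ``sigma(level)`` /
    ``sigma_se(level)`` return back-transformed per-group scales.
    """

    location_coeffs: dict
    location_se: dict
    scale_coeffs: dict  # on the log-sigma link
    scale_se: dict
    loglik: float
    n_obs: int
    converged: bool
    group_levels: Optional[list] = None
    n_iter: int = 0

    def sigma(self, name) -> float:
        return float(np.exp(self.scale_coeffs[name]))

    def sigma_se(self, name) -> float:
        # delta method back from the log link
        return self.sigma(name) * float(self.scale_se[name])

    def mu(self, name) -> float:
        return float(self.location_coeffs[name])

    def to_dict(self) -> dict:
        return {
            "location_coeffs": dict(self.location_coeffs),
            "location_se": dict(self.location_se),
            "scale_coeffs": dict(self.scale_coeffs),
            "scale_se": dict(self.scale_se),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "group_levels": self.group_levels,
        }


@dataclass
class ComparisonResult:
    """A Wald comparison of two parameter estimates (z reference)."""

    theta_1: float
    se_1: float
    theta_2: float
    se_2: float
    wald_w: float
    p_value: float
    q_value: float = float("nan")
    label: str = ""


def _normal_loglik(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    return float(np.sum(stats.norm.logpdf(y, loc=mu, scale=sigma)))


def fit_group_location_scale(
    values: Sequence[float],
    groups: Sequence,
    min_group_size: int = 3,
) -> ScaleModelFit:
    """Saturated one-way normal location-scale fit (closed-form ML).

    Group means and group standard deviations are estimated simultaneously
    by maximum likelihood; in the saturated layout they decouple into the
    per-group sample mean and the per-group ML (1/n) standard deviation.

    Parameters
    ----------
    values, groups
        Observations and their group labels, aligned.
    min_group_size
        Smallest admissible group (default 3; lower only makes sense in
        closed-form sanity checks).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape or y.ndim != 1:
        raise ValueError("values and groups must be aligned 1-D sequences")
    levels = list(dict.fromkeys(g.tolist()))  # stable order of appearance
    loc, loc_se, sc, sc_se = {}, {}, {}, {}
    loglik = 0.0
    for lev in levels:
        yk = y[g == lev]
        nk = yk.size
        if nk < min_group_size:
            raise ValueError(f"group {lev!r} has {nk} < {min_group_size} observations")
        mu_k = float(yk.mean())
        sigma_k = float(np.sqrt(np.mean((yk - mu_k) ** 2)))  # ML, 1/n
        if sigma_k == 0.0:
            raise ValueError(f"group {lev!r} has zero within-group variance")
        loc[lev] = mu_k
        loc_se[lev] = sigma_k / np.sqrt(nk)
        sc[lev] = float(np.log(sigma_k))
        sc_se[lev] = 1.0 / np.sqrt(2.0 * nk)
        loglik += _normal_loglik(yk, mu_k, sigma_k)
    return ScaleModelFit(
        location_coeffs=loc,
        location_se=loc_se,
        scale_coeffs=sc,
        scale_se=sc_se,
        loglik=loglik,
        n_obs=y.size,
        converged=True,
        group_levels=levels,
    )


def fit_location_scale_regression(
    y: Sequence[float],
    x: Sequence[float],
    max_iter: int = 200,
    tol: float = 1e-10,
) -> ScaleModelFit:
    """Fit y ~ Normal(a0 + a*x, exp(b0 + b*x)) by Fisher scoring.

    Coefficient names are ``alpha0``/``alpha`` (location) and
    ``beta0``/``beta`` (log scale).  Standard errors come from the expected
    information: (X' W X)^-1 for the location block (W = 1/sigma_i^2) and
    (2 X' X)^-1 for the log-scale block.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be aligned 1-D vectors")
    if y.size < 8:
        raise ValueError("need at least 8 observations")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0.0:
        raise ValueError(
            "covariate has zero variance; use fit_group_location_scale for a "
            "single-stratum fit"
        )

    X = np.column_stack([np.ones_like(x), x])
    alpha = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ alpha
    beta = np.array([np.log(np.sqrt(np.mean(resid**2)) + 1e-300), 0.0])

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sigma = np.exp(X @ beta)
        # location step: weighted least squares with weights 1/sigma^2
        w = 1.0 / sigma**2
        XtW = X.T * w
        alpha = np.linalg.solve(XtW @ X, XtW @ y)
        resid = y - X @ alpha
        # scale step: Newton/scoring on the log link
        z = resid**2 / sigma**2 - 1.0
        score = X.T @ z
        info = 2.0 * (X.T @ X)
        beta = beta + np.linalg.solve(info, score)
        ll = _normal_loglik(y, X @ alpha, np.exp(X @ beta))
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll

    sigma = np.exp(X @ beta)
    w = 1.0 / sigma**2
    cov_alpha = np.linalg.inv((X.T * w) @ X)
    cov_beta = np.linalg.inv(2.0 * (X.T @ X))
    fit = ScaleModelFit(
        location_coeffs={"alpha0": float(alpha[0]), "alpha": float(alpha[1])},
        location_se={
            "alpha0": float(np.sqrt(cov_alpha[0, 0])),
            "alpha": float(np.sqrt(cov_alpha[1, 1])),
        },
        scale_coeffs={"beta0": float(beta[0]), "beta": float(beta[1])},
        scale_se={
            "beta0": float(np.sqrt(cov_beta[0, 0])),
            "beta": float(np.sqrt(cov_beta[1, 1])),
        },
        loglik=_normal_loglik(y, X @ alpha, sigma),
        n_obs=y.size,
        converged=converged,
        n_iter=it,
    )
    if not converged:
        raise ConvergenceError(
            f"scoring did not converge in {max_iter} iterations", last_fit=fit
        )
    return fit


def wald_compare(
    theta_1: float, se_1: float, theta_2: float, se_2: float, label: str = ""
) -> ComparisonResult:
    """Two-sided Wald z test of theta_1 vs theta_2.

    w = (theta_1 - theta_2) / sqrt(se_1^2 + se_2^2), referred to the
    standard normal.
    """
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive")
    w = (theta_1 - theta_2) / np.sqrt(se_1**2 + se_2**2)
    p = float(2.0 * stats.norm.sf(abs(w)))
    return ComparisonResult(
        theta_1=float(theta_1), se_1=float(se_1),
        theta_2=float(theta_2), se_2=float(se_2),
        wald_w=float(w), p_value=p, label=label,
    )


def compare_groups(
    fit: ScaleModelFit,
    parameter: str = "scale",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """All pairwise Wald comparisons of a saturated group fit, BH-adjusted.

    ``parameter`` selects the per-group scale (on sigma, where the
    comparison is equivalent to one on eta = sqrt(2) sigma) or location.
    The comparisons within one call form one FDR family.
    """
    if fit.group_levels is None:
        raise ValueError("fit has no group structure")
    results = []
    for i, a in enumerate(fit.group_levels):
        for b in fit.group_levels[i + 1:]:
            if parameter == "scale":
                res = wald_compare(
                    fit.sigma(a), fit.sigma_se(a), fit.sigma(b), fit.sigma_se(b),
                    label=f"{a} vs {b}",
                )
            elif parameter == "location":
                res = wald_compare(
                    fit.mu(a), fit.location_se[a], fit.mu(b), fit.location_se[b],
                    label=f"{a} vs {b}",
                )
            else:
                raise ValueError(f"unknown parameter {parameter!r}")
            results.append(res)
    qs = fdr_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def noise_from_scale(sigma_hat: float, se_sigma: float) -> tuple[float, float, float]:
    """Map a fitted PC-score scale to a noise estimate with a 95% interval.

    eta_hat = sqrt(2) * sigma_hat; the delta-method standard error is
    sqrt(2) * se, and the interval is symmetric +-1.96 se on the eta scale.
    Wald comparisons are unchanged by this rescaling (the factor cancels).
    """
    if sigma_hat <= 0:
        raise ValueError("sigma_hat must be positive")
    if se_sigma <= 0:
        raise ValueError("standard error must be positive")
    eta = np.sqrt(2.0) * sigma_hat
    se = np.sqrt(2.0) * se_sigma
    return float(eta), float(eta - 1.96 * se), float(eta + 1.96 * se)


def adjust_for_litter_size(
    log_mass: Sequence[float], litter_size: Sequence[float]
) -> np.ndarray:
    """Litter-size-adjusted log masses.

    Ordinary-least-squares residuals of log mass on litter size across the
    full cohort, re-centered at the grand mean — removes the crowding
    effect of large litters while keeping values on the original scale.
    """
    y = np.asarray(log_mass, dtype=float)
    ls = np.asarray(litter_size, dtype=float)
    if y.shape != ls.shape or y.ndim != 1:
        raise ValueError("log_mass and litter_size must be aligned 1-D vectors")
    X = np.column_stack([np.ones_like(ls), ls])
    coef = np.linalg.lstsq(X, y, rcond=None)[0]
    return y - X @ coef + y.mean()
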