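"""Per-cell-type beta regression.

Secondary analysis that models each cell-type proportion separately as a
Beta-distributed outcome: mean ``mu_i = expit(x_i' beta)`` with shape
parameters ``(mu_i * phi, (1 - mu_i) * phi)``, where the precision
``phi`` is constant across samples and parameterized internally on the
log scale. Coefficients are on the log-odds scale, as is conventional.

Estimation is maximum likelihood via Newton ascent with a backtracking
line search that only accepts steps increasing the log-likelihood, so
the likelihood path is monotone by construction. Starting values come
from a linear fit on logit(y) and a method-of-moments precision.
Inference is Wald, from the observed information at the optimum; a
case-resampling bootstrap (sharing the compositional model's resampler
conventions) is available for percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logit, polygamma
from scipy import stats

from .design import ModelSpec, build_design

__all__ = [
    "BetaRegFit",
    "fit_beta_regression",
    "wald_summary",
    "bootstrap_beta_regression",
]


@dataclass
class BetaRegFit:
    cell_type: str
    design_columns: list[str]
    coefficients: np.ndarray      # P, log-odds scale
    phi: float                    # precision, > 0
    covariance: np.ndarray        # (P+1) x (P+1) for (beta, phi)
    loglik: float
    converged: bool
    n_samples: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0


def _loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    mu = expit(X @ beta)
    a, b = mu * phi, (1.0 - mu) * phi
    return float(
        np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def _score(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic gradient of the log-likelihood in (beta, log phi)."""
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    mu = expit(X @ beta)
    ystar = logit(y)
    mustar = digamma(mu * phi) - digamma((1.0 - mu) * phi)
    g_beta = phi * (X.T @ ((ystar - mustar) * mu * (1.0 - mu)))
    g_phi = np.sum(
        mu * (ystar - mustar)
        + np.log1p(-y)
        - digamma((1.0 - mu) * phi)
        + digamma(phi)
    )
    return np.append(g_beta, phi * g_phi)


def _hessian(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic observed-information Hessian in (beta, log phi)."""
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    mu = expit(X @ beta)
    m = mu * (1.0 - mu)
    a, b = mu * phi, (1.0 - mu) * phi
    ystar = logit(y)
    mustar = digamma(a) - digamma(b)
    psi1a, psi1b = polygamma(1, a), polygamma(1, b)
    # d2 ll / d eta_i^2 and cross terms with phi
    d2_eta = phi * (-(psi1a + psi1b) * phi * m * m + (ystar - mustar) * m * (1.0 - 2.0 * mu))
    d_eta_dphi = m * ((ystar - mustar) - phi * (psi1a * mu - psi1b * (1.0 - mu)))
    d_phi = np.sum(mu * (ystar - mustar) + np.log1p(-y) - digamma(b) + digamma(phi))
    d2_phi = np.sum(-psi1a * mu * mu - psi1b * (1.0 - mu) ** 2 + polygamma(1, phi))
    P = X.shape[1]
    H = np.empty((P + 1, P + 1))
    H[:P, :P] = X.T @ (d2_eta[:, None] * X)
    H[:P, P] = H[P, :P] = phi * (X.T @ d_eta_dphi)
    H[P, P] = phi * phi * d2_phi + phi * d_phi  # chain rule through log phi
    return H


def fit_beta_regression(
    y,
    cohort: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    design: pd.DataFrame | None = None,
    cell_type: str = "",
    squeeze: bool = False,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> BetaRegFit:
    """Fit a beta regression of a proportion on the exposure design.

    ``y`` must lie strictly inside (0, 1); boundary values raise unless
    ``squeeze`` applies the standard compression ``(y*(n-1) + 0.5)/n``
    (off by default — deconvolved, zero-replaced proportions are interior).
    Convergence requires the score max-norm to fall below ``gtol``.
    """
    y = np.asarray(y, dtype=float)
    if design is None:
        if cohort is None or spec is None:
            raise ValueError("provide either a prebuilt design or (cohort, spec)")
        design = build_design(cohort, spec)
    X = design.to_numpy(dtype=float)
    n, P = X.shape
    if y.shape != (n,):
        raise ValueError("response length does not match design")
    if squeeze:
        y = (y * (n - 1) + 0.5) / n
    on_boundary = (y <= 0.0) | (y >= 1.0)
    if np.any(on_boundary):
        offenders = list(np.asarray(design.index)[on_boundary][:10])
        raise ValueError(
            f"proportions on the boundary of (0,1) for samples {offenders}; "
            "use squeeze=True or fix the input"
        )
    if n <= P + 1:
        raise ValueError(f"too few samples (n={n}) for P={P} predictors")

    # starting values: linear model on logit(y), method-of-moments phi
    beta0, *_ = np.linalg.lstsq(X, logit(y), rcond=None)
    mu0 = expit(X @ beta0)
    s2 = float(np.mean((y - mu0) ** 2))
    phi0 = max(float(np.mean(mu0 * (1.0 - mu0)) / s2 - 1.0), 1.0) if s2 > 0 else 100.0
    theta = np.append(beta0, np.log(phi0))

    ll = _loglik(theta, X, y)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = _score(theta, X, y)
        if np.max(np.abs(g)) < gtol:
            converged = True
            break
        H = _hessian(theta, X, y)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            step = g
        newton = step @ g > 0
        if not newton:  # not an ascent direction; fall back to gradient
            step = g
        if newton and np.max(np.abs(g)) < 1e-2:
            # quadratic regime: likelihood gains are below the float noise of
            # the summed log-likelihood, so skip the line search
            t = 1.0
        else:
            t = 1.0
            while t > 1e-12:
                ll_new = _loglik(theta + t * step, X, y)
                if ll_new > ll - 1e-12:
                    break
                t *= 0.5
        theta = theta + t * step
        ll = _loglik(theta, X, y)
        path.append(ll)
    else:
        g = _score(theta, X, y)
        converged = bool(np.max(np.abs(g)) < gtol)

    if not converged:
        raise RuntimeError(
            f"beta regression did not converge in {max_iter} iterations "
            f"(score max-norm {np.max(np.abs(_score(theta, X, y))):.2e})"
        )

    H = _hessian(theta, X, y)
    cov_theta = np.linalg.inv(-H)
    phi = float(np.exp(theta[-1]))
    # delta method from (beta, log phi) to (beta, phi)
    J = np.eye(P + 1)
    J[-1, -1] = phi
    cov = J @ cov_theta @ J.T
    cov = 0.5 * (cov + cov.T)
    return BetaRegFit(
        cell_type=cell_type,
        design_columns=list(design.columns),
        coefficients=theta[:-1].copy(),
        phi=phi,
        covariance=cov,
        loglik=ll,
        converged=converged,
        n_samples=n,
        loglik_path=np.asarray(path),
        n_iter=it,
    )


def wald_summary(fit: BetaRegFit, ci_level: float = 0.95, decimals: int | None = None) -> pd.DataFrame:
    """Per-coefficient Wald table: estimate, CI bounds and two-sided p,
    on the log-odds scale."""
    if not fit.converged:
        raise ValueError("cannot summarize a non-converged fit")
    P = len(fit.coefficients)
    se = np.sqrt(np.diag(fit.covariance)[:P])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    est = fit.coefficients
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, est / se, 0.0)
    out = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_lo": est - z * se,
            "ci_hi": est + z * se,
            "p": 2.0 * stats.norm.sf(np.abs(wald)),
        },
        index=fit.design_columns,
    )
    if decimals is not None:
        out = out.round(decimals)
    return out


def bootstrap_beta_regression(
    y,
    cohort: pd.DataFrame,
    spec: ModelSpec,
    B: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    cell_type: str = "",
) -> pd.DataFrame:
    """Case-resampling percentile bootstrap for the beta regression.

    Returns the Wald table augmented with percentile CI columns
    (``boot_lo``, ``boot_hi``) over B replicates.
    """
    y = np.asarray(y, dtype=float)
    design = build_design(cohort, spec)
    fit = fit_beta_regression(y, design=design, cell_type=cell_type)
    rng = np.random.default_rng(seed)
    n = len(y)
    draws = np.empty((B, len(fit.coefficients)))
    b = 0
    failures = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        Xb = design.iloc[idx]
        if np.linalg.matrix_rank(Xb.to_numpy(dtype=float)) < Xb.shape[1]:
            failures += 1
            if failures > 0.1 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        try:
            fb = fit_beta_regression(y[idx], design=Xb.reset_index(drop=True), cell_type=cell_type)
        except RuntimeError:
            failures += 1
            if failures > 0.1 * B:
                raise
            continue
        draws[b] = fb.coefficients
        b += 1
    alpha = 1.0 - ci_level
    out = wald_summary(fit, ci_level)
    out["boot_lo"] = np.percentile(draws, 100 * alpha / 2, axis=0)
    out["boot_hi"] = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    return out
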