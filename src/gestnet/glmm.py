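"""Random-intercept mixed models for observation-level gesture data.

Gesture sequences are hierarchically structured: level 1 is the focal
signaller, level 2 the individual sequence, so every model carries a random
intercept for focal identity (no random slopes). Two families are
supported:

* ``binomial_logit`` — binary responses (gesture present/absent, response
  type). Fitted by maximum likelihood, integrating the random intercept
  out of the likelihood per group with Gauss--Hermite quadrature (the
  1-D integral makes this exact up to quadrature error). Standard errors
  come from the numerical Hessian of the log-likelihood at the optimum,
  p-values from the Wald normal approximation.
* ``gaussian_identity`` — continuous responses (durations, repertoire
  sizes). Delegated to statsmodels ``MixedLM`` with full maximum
  likelihood.

When the random-intercept variance is (near) zero both families reduce to
ordinary logistic/linear regression. Non-convergence is flagged on the
result, never silent; quasi-separation in the binomial family is reported
as a warning when a coefficient diverges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, stats

from .types import ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("binomial_logit", "gaussian_identity")

#: Gauss-Hermite nodes; 25 is ample for a 1-D logit random intercept
_GH_POINTS = 25
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class GlmmSpec:
    """Model specification: response ~ fixed_effects + (1 | group)."""

    response: str
    family: str
    fixed_effects: Tuple[str, ...]
    group: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))


@dataclass(frozen=True)
class GlmmResult:
    """Tidy fixed-effect estimates plus the random-intercept variance."""

    spec: GlmmSpec
    estimates: pd.DataFrame  # index: intercept + fixed effects; columns: estimate, se, p
    random_intercept_var: float
    n_obs: int
    n_groups: int
    converged: bool
    log_likelihood: float
    diagnostics: Tuple[str, ...] = ()

    def estimate(self, term: str) -> float:
        return float(self.estimates.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.estimates.loc[term, "se"])


def _prepare(data: pd.DataFrame, spec: GlmmSpec):
    cols = [spec.response, *spec.fixed_effects, spec.group]
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"data lacks columns {missing_cols}")
    frame = data[cols].dropna()
    n_obs = len(frame)
    if n_obs < len(spec.fixed_effects) + 2:
        raise ValidationError(
            f"only {n_obs} complete rows for {len(spec.fixed_effects)} "
            "fixed effects"
        )
    groups, group_idx = np.unique(frame[spec.group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValidationError("grouping factor needs at least 2 levels")
    y = frame[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n_obs)]
        + [frame[c].to_numpy(dtype=float) for c in spec.fixed_effects]
    )
    return y, X, group_idx, len(groups), n_obs


def _binomial_nll(params, y, X, group_idx, n_groups, nodes, log_wts):
    """Negative marginal log-likelihood, random intercept integrated by GH."""
    beta = params[:-1]
    sd = np.exp(params[-1])
    eta = (X @ beta)[:, None] + sd * nodes[None, :]
    # log Bernoulli likelihood, numerically safe for large |eta|
    ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
    ll_group = np.zeros((n_groups, len(nodes)))
    np.add.at(ll_group, group_idx, ll_obs)
    a = ll_group + log_wts[None, :]
    m = a.max(axis=1, keepdims=True)
    return -float((np.log(np.exp(a - m).sum(axis=1)) + m[:, 0]).sum())


def _numerical_hessian(fun, x, eps=1e-4):
    k = len(x)
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return hess


def _fit_binomial(y, X, group_idx, n_groups, n_obs, spec) -> GlmmResult:
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValidationError("binomial response must be coded 0/1")
    nodes, wts = hermegauss(_GH_POINTS)
    log_wts = np.log(wts) - 0.5 * np.log(2 * np.pi)
    args = (y, X, group_idx, n_groups, nodes, log_wts)
    p = X.shape[1]
    x0 = np.zeros(p + 1)
    x0[-1] = np.log(0.5)  # log random-intercept s.d. start
    # log-s.d. bounded below: a variance of exp(-12) is numerically zero and
    # keeps the profile from drifting to -inf on degenerate data
    bounds = [(None, None)] * p + [(-6.0, 3.0)]
    with np.errstate(over="ignore"):
        res = optimize.minimize(
            _binomial_nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if not res.success:
            polish = optimize.minimize(
                _binomial_nll, res.x, args=args, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if polish.fun <= res.fun:
                res = polish
    diagnostics: List[str] = []
    converged = bool(res.success)
    if not converged:
        diagnostics.append(f"optimizer: {res.message}")
        logger.warning("binomial GLMM did not converge: %s", res.message)
    beta = res.x[:p]
    sd_u = float(np.exp(res.x[-1]))
    if np.abs(beta).max() > _SEPARATION_BOUND:
        diagnostics.append(
            "possible (quasi-)separation: a coefficient exceeds "
            f"{_SEPARATION_BOUND} on the logit scale; consider a penalized fit"
        )
        logger.warning("binomial GLMM: %s", diagnostics[-1])
    with np.errstate(over="ignore"):
        hess = _numerical_hessian(lambda v: _binomial_nll(v, *args), res.x)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        diagnostics.append("Hessian singular; standard errors unavailable")
    se = np.where(se > 0, se, np.nan)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    names = ["intercept", *spec.fixed_effects]
    estimates = pd.DataFrame(
        {"estimate": beta, "se": se, "p": pvals}, index=names
    )
    return GlmmResult(
        spec=spec,
        estimates=estimates,
        random_intercept_var=sd_u**2,
        n_obs=n_obs,
        n_groups=n_groups,
        converged=converged,
        log_likelihood=-float(res.fun),
        diagnostics=tuple(diagnostics),
    )


def _fit_gaussian(y, X, group_idx, n_groups, n_obs, spec) -> GlmmResult:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=group_idx)
        fit = model.fit(reml=False, method="lbfgs")
    converged = bool(fit.converged)
    diagnostics: Tuple[str, ...] = ()
    if not converged:
        diagnostics = ("MixedLM did not converge",)
        logger.warning("gaussian GLMM did not converge")
    p = X.shape[1]
    names = ["intercept", *spec.fixed_effects]
    estimates = pd.DataFrame(
        {
            "estimate": np.asarray(fit.fe_params),
            "se": np.asarray(fit.bse_fe),
            "p": np.asarray(fit.pvalues)[:p],
        },
        index=names,
    )
    return GlmmResult(
        spec=spec,
        estimates=estimates,
        random_intercept_var=float(np.asarray(fit.cov_re).ravel()[0]),
        n_obs=n_obs,
        n_groups=n_groups,
        converged=converged,
        log_likelihood=float(fit.llf),
        diagnostics=diagnostics,
    )


def fit_glmm(data: pd.DataFrame, spec: GlmmSpec) -> GlmmResult:
    """Fit a random-intercept model; deterministic given the data.

    Rows with a missing value in the response, any fixed effect or the
    grouping column are dropped listwise. Estimates are invariant to row
    order and to group relabeling.
    """
    y, X, group_idx, n_groups, n_obs = _prepare(data, spec)
    if spec.family == "binomial_logit":
        return _fit_binomial(y, X, group_idx, n_groups, n_obs, spec)
    return _fit_gaussian(y, X, group_idx, n_groups, n_obs, spec)
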