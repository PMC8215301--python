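"""Two-stage MI/IPW missing-data handling.

This module is an explicit reconstruction of the two-stage strategy commonly
used with cohort attrition: unit (wave) non-response is handled by inverse
probability-of-response weights fitted on fully observed baseline confounders,
item non-response among responders by chained-equation multiple imputation,
and estimates are pooled across imputations with Rubin's rules.  The final
analysis weight is the product of the response weight and the confounding
weight.

The imputation engine is deliberately small: linear models with proper
parameter draws for continuous variables, Bayesian-ish logistic draws for
binary variables, and a proportional-odds model (without parameter
perturbation) for ordinal variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import t as t_dist

from .balance import WeightSet, build_design
from .concentration import CIEstimate

__all__ = [
    "ResponseModel",
    "ImputationSet",
    "response_weights",
    "impute",
    "pool",
]


@dataclass
class ResponseModel:
    params: pd.Series
    probability: np.ndarray  # per-record P(response | baseline)


@dataclass
class ImputationSet:
    """m completed tables; observed cells identical across them."""

    tables: list
    models: dict
    seed: int
    iterations: int

    @property
    def m(self) -> int:
        return len(self.tables)


def response_weights(table: pd.DataFrame, baseline_names: Sequence[str],
                     outcome_names: Sequence[str] | None = None,
                     response_col: str | None = None) -> WeightSet:
    """Inverse probability-of-response weights for wave non-response.

    A record counts as a responder when any outcome column is observed (or per
    an explicit 0/1 ``response_col``).  Responders get weight 1/P(response |
    baseline confounders); non-responders get weight 0 and are excluded from
    outcome stages.  Multiply by the confounding weights downstream.
    """
    if response_col is not None:
        resp = table[response_col].to_numpy(float)
    else:
        if outcome_names is None:
            outcome_names = table.attrs.get("outcome_names")
        if not outcome_names:
            raise ValueError("outcome_names required to define response")
        resp = (~table[list(outcome_names)].isna().all(axis=1)).to_numpy(float)
    if resp.min() == resp.max():
        if resp.min() == 0.0:
            raise ValueError("no responders")
        return WeightSet(weights=np.ones(len(table)), method="response-ipw",
                         meta={"response_rate": 1.0})

    X, names = build_design(table, baseline_names)
    Xc = sm.add_constant(X)
    fit = sm.Logit(resp, Xc).fit(disp=0, maxiter=200)
    p = np.asarray(fit.predict(Xc))
    if np.any(p[resp == 1.0] <= 0.0):
        raise ValueError("fitted response probability 0 for a responder")
    w = np.where(resp == 1.0, 1.0 / p, 0.0)
    model = ResponseModel(params=pd.Series(fit.params, index=["const"] + names),
                          probability=p)
    return WeightSet(weights=w, method="response-ipw",
                     meta={"response_rate": float(resp.mean()), "model": model})


def _model_kind(col: pd.Series, declared: str | None) -> str:
    if declared:
        return declared
    vals = col.dropna()
    if isinstance(col.dtype, pd.CategoricalDtype):
        return "ordinal" if col.cat.ordered else "logistic"
    uniq = np.unique(vals.to_numpy(float))
    if len(uniq) <= 1:
        raise ValueError(f"variable {col.name!r} has no information to impute from")
    if len(uniq) == 2 and set(uniq) <= {0.0, 1.0}:
        return "logistic"
    if np.allclose(uniq, np.round(uniq)) and len(uniq) <= 6:
        return "ordinal"
    return "linear"


def _draw_linear(rng, Xo, yo, Xm):
    """Proper imputation: draw sigma^2 and beta from their posterior, then
    add residual noise."""
    n, k = Xo.shape
    beta, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(n - k, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    XtX_inv = np.linalg.pinv(Xo.T @ Xo)
    beta_star = rng.multivariate_normal(beta, sigma2 * XtX_inv, method="cholesky"
                                        ) if k > 1 else np.atleast_1d(
        rng.normal(beta[0], np.sqrt(sigma2 * XtX_inv[0, 0])))
    return Xm @ beta_star + rng.normal(0.0, np.sqrt(sigma2), size=len(Xm))


def _draw_logistic(rng, Xo, yo, Xm):
    fit = sm.Logit(yo, Xo).fit(disp=0, maxiter=100)
    beta = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params())
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    p = expit(Xm @ beta_star)
    return (rng.random(len(Xm)) < p).astype(float)


def _draw_ordinal(rng, Xo, yo, Xm):
    """Proportional-odds draw; levels are the observed unique values."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    levels = np.unique(yo)
    codes = np.searchsorted(levels, yo)
    # OrderedModel wants no constant column
    Xo_ = Xo[:, 1:] if Xo.shape[1] > 1 else Xo
    Xm_ = Xm[:, 1:] if Xm.shape[1] > 1 else Xm
    try:
        fit = OrderedModel(codes, Xo_, distr="logit").fit(
            method="bfgs", disp=0, maxiter=200)
        probs = np.asarray(fit.model.predict(fit.params, exog=Xm_))
    except Exception:
        # fall back to the marginal distribution
        counts = np.bincount(codes, minlength=len(levels)).astype(float)
        probs = np.tile(counts / counts.sum(), (len(Xm_), 1))
    cum = probs.cumsum(axis=1)
    u = rng.random(len(Xm_))[:, None]
    draw_codes = (u > cum).sum(axis=1)
    return levels[draw_codes.clip(0, len(levels) - 1)]


def impute(table: pd.DataFrame, m: int = 5, iterations: int = 10, seed: int = 0,
           model_types: Mapping[str, str] | None = None,
           predictor_names: Sequence[str] | None = None,
           weights: np.ndarray | None = None) -> ImputationSet:
    """Chained-equation multiple imputation of item-missing cells.

    Every variable with missing cells gets a model (linear / logistic /
    proportional-odds, inferred from its values unless declared in
    ``model_types``) regressed on the fully observed ``predictor_names``
    (default: the table's confounders) plus the current imputations of the
    other incomplete variables and, optionally, an analysis-weight covariate.
    Deterministic given ``seed``; observed cells are never altered.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    model_types = dict(model_types or {})
    if predictor_names is None:
        predictor_names = table.attrs.get("confounder_names")
        if predictor_names is None:
            raise ValueError("predictor_names required (no confounders in attrs)")

    missing_vars = [c for c in table.columns
                    if c not in ("id",) and table[c].isna().any()]
    for var in missing_vars:
        if table[var].isna().all():
            raise ValueError(f"variable {var!r} is 100% missing; cannot impute")
        if var in predictor_names:
            raise ValueError(f"predictor {var!r} has missing cells; predictors "
                             "must be fully observed")
    kinds = {var: _model_kind(table[var], model_types.get(var))
             for var in missing_vars}

    base_X, _ = build_design(table, predictor_names)
    base_X = sm.add_constant(base_X)
    if weights is not None:
        w = np.asarray(weights, float)[:, None]
        base_X = np.hstack([base_X, (w - w.mean()) / (w.std() + 1e-12)])

    rng = np.random.default_rng(seed)
    completed = []
    for _ in range(m):
        work = table.copy()
        # initial fill: random draws from the observed distribution
        for var in missing_vars:
            obs = work[var].dropna().to_numpy()
            mask = work[var].isna().to_numpy()
            work.loc[mask, var] = rng.choice(obs, size=mask.sum())
        if missing_vars:
            for _ in range(iterations):
                for var in missing_vars:
                    mask = table[var].isna().to_numpy()
                    others = [v for v in missing_vars if v != var]
                    X = base_X
                    if others:
                        extra = work[others].to_numpy(float)
                        X = np.hstack([base_X, extra])
                    yo = work.loc[~mask, var].to_numpy(float)
                    Xo, Xm = X[~mask], X[mask]
                    kind = kinds[var]
                    if kind == "linear":
                        draw = _draw_linear(rng, Xo, yo, Xm)
                    elif kind == "logistic":
                        draw = _draw_logistic(rng, Xo, yo, Xm)
                    elif kind == "ordinal":
                        draw = _draw_ordinal(rng, Xo, yo, Xm)
                    else:
                        raise ValueError(f"unknown model type {kind!r} for {var!r}")
                    work.loc[mask, var] = draw
        work.attrs = dict(table.attrs)
        completed.append(work)
    return ImputationSet(tables=completed, models=kinds, seed=seed,
                         iterations=iterations)


def pool(estimates: Sequence[CIEstimate]) -> CIEstimate:
    """Rubin's rules across imputations: pooled point = mean of points,
    total variance = within + (1 + 1/m) * between, t interval with the
    conventional degrees of freedom."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates to pool")
    variants = {e.variant for e in estimates}
    if len(variants) != 1:
        raise ValueError(f"mismatched variants {variants}")
    m = len(estimates)
    points = np.array([e.estimate for e in estimates])
    within = float(np.mean([e.se ** 2 for e in estimates]))
    between = float(points.var(ddof=1))
    point = float(points.mean())
    total = within + (1.0 + 1.0 / m) * between
    se = float(np.sqrt(total))
    if between > 0 and within > 0:
        dof = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
        tcrit = float(t_dist.ppf(0.975, dof))
    else:
        tcrit = 1.959963984540054
    e0 = estimates[0]
    return CIEstimate(variant=e0.variant, estimate=point,
                      lo95=point - tcrit * se, hi95=point + tcrit * se,
                      se=se, se_method=f"rubin({e0.se_method})",
                      mu=float(np.mean([e.mu for e in estimates])),
                      var_rank=float(np.mean([e.var_rank for e in estimates])),
                      n_eff=float(np.mean([e.n_eff for e in estimates])),
                      n=e0.n, n_boot=e0.n_boot)
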