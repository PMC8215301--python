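"""Inverse-probability weights balancing confounders across school systems.

Three candidate propensity models (main-effects logistic, a flexible logistic
with a natural cubic spline on the ability score, and a ridge-penalized
logistic) plus exact-mean-matching entropy balancing.  Weights target the
whole-population counterfactual ("everyone under each system"), i.e. 1/p and
1/(1-p) weights.  A transparent selector picks the candidate with the best
achieved balance (smallest mean absolute standardized mean difference), and a
report reproduces the before/after percentage table and SMDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegressionCV

from .synthetic import COMPREHENSIVE, SELECTIVE

__all__ = [
    "PropensityModel",
    "WeightSet",
    "BalanceReport",
    "BalanceError",
    "InfeasibleBalanceError",
    "fit_propensity",
    "make_ipw",
    "entropy_balance",
    "select_weights",
    "balance_report",
    "build_design",
    "PROPENSITY_METHODS",
]

PROPENSITY_METHODS = ("logistic", "spline", "ridge")


class BalanceError(RuntimeError):
    pass


class InfeasibleBalanceError(BalanceError):
    """Moment constraints outside the convex hull of an arm's covariates."""


def _natural_spline_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots), df columns
    excluding the intercept; knots at equally spaced quantiles."""
    qs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, qs)
    knots = np.unique(knots)
    if len(knots) < 3:
        raise BalanceError("too few distinct values for a spline basis")
    K = len(knots)

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[-1], 0, None) ** 3) / (knots[-1] - knots[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(k) - d(K - 2))
    return np.column_stack(cols)


def build_design(table: pd.DataFrame, confounder_names: Sequence[str],
                 spline_df: int | None = None, drop_first: bool = True,
                 ) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the confounders: drop-first indicator columns for
    categoricals (reference = first category) and z-scored continuous columns
    (spline-expanded when ``spline_df`` is set)."""
    cols, names = [], []
    for name in confounder_names:
        if name not in table.columns:
            raise KeyError(f"unknown confounder {name!r}")
        col = table[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cats = (list(col.cat.categories)
                    if isinstance(col.dtype, pd.CategoricalDtype)
                    else sorted(col.dropna().astype(str).unique()))
            vals = col.astype(str).to_numpy()
            start = 1 if drop_first else 0
            for level in cats[start:]:
                cols.append((vals == str(level)).astype(float))
                names.append(f"{name}={level}")
        else:
            x = col.to_numpy(float)
            if np.any(~np.isfinite(x)):
                raise ValueError(f"missing values in confounder {name!r}; "
                                 "handle missingness upstream")
            sd = x.std()
            if sd == 0:
                raise ValueError(f"constant confounder {name!r}")
            z = (x - x.mean()) / sd
            if spline_df:
                basis = _natural_spline_basis(z, df=spline_df)
                for j in range(basis.shape[1]):
                    cols.append(basis[:, j])
                    names.append(f"{name}_ns{j + 1}")
            else:
                cols.append(z)
                names.append(name)
    if not cols:
        raise ValueError("no confounders given")
    return np.column_stack(cols), names


@dataclass
class PropensityModel:
    method: str
    propensity: np.ndarray
    params: pd.Series | None = None
    bse: pd.Series | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class WeightSet:
    """Per-record analysis weights with provenance."""

    weights: np.ndarray
    method: str
    estimand: str = "average-population"
    criterion: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def cv(self) -> float:
        w = self.weights
        return float(w.std() / w.mean()) if w.mean() > 0 else np.inf


def _exposure_indicator(table: pd.DataFrame, system_col: str = "system") -> np.ndarray:
    vals = table[system_col].astype(str).to_numpy()
    labels = set(vals)
    if not labels <= {COMPREHENSIVE, SELECTIVE}:
        raise ValueError(f"unexpected system labels {labels}")
    if len(labels) < 2:
        raise BalanceError("exposure has a single level; cannot model propensity")
    return (vals == SELECTIVE).astype(float)


def fit_propensity(table: pd.DataFrame, confounder_names: Sequence[str],
                   method: str = "logistic", spline_df: int = 4,
                   ridge_folds: int = 5, ridge_seed: int = 0) -> PropensityModel:
    """Fit the probability of selective-system attendance on the confounders.

    ``method``: "logistic" (main effects), "spline" (natural cubic spline,
    default 4 df, on continuous confounders), or "ridge" (L2-penalized with
    penalty chosen by cross-validated deviance).
    """
    y = _exposure_indicator(table)
    if method not in PROPENSITY_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {PROPENSITY_METHODS}")
    X, names = build_design(table, confounder_names,
                            spline_df=spline_df if method == "spline" else None)

    if method == "ridge":
        clf = LogisticRegressionCV(
            Cs=np.logspace(-3, 3, 13), cv=ridge_folds,
            scoring="neg_log_loss", max_iter=2000,
            random_state=ridge_seed)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X, y)
        p = clf.predict_proba(X)[:, 1]
        params = pd.Series(np.r_[clf.intercept_, clf.coef_.ravel()],
                           index=["const"] + names)
        model = PropensityModel(method=method, propensity=p, params=params,
                                meta={"C": float(clf.C_[0])})
    else:
        Xc = sm.add_constant(X)
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception as err:  # includes perfect separation
            raise BalanceError(
                f"propensity fit failed ({err}); with perfect separation "
                "consider method='ridge'") from err
        if not fit.mle_retvals.get("converged", True):
            raise BalanceError(
                "propensity fit did not converge (possible perfect separation); "
                "consider method='ridge'")
        p = np.asarray(fit.predict(Xc))
        idx = ["const"] + names
        model = PropensityModel(method=method, propensity=p,
                                params=pd.Series(fit.params, index=idx),
                                bse=pd.Series(fit.bse, index=idx))
    if not np.all((p > 0.0) & (p < 1.0)):
        raise BalanceError("fitted propensity hit 0 or 1; positivity violated")
    return model


def make_ipw(model: PropensityModel, table: pd.DataFrame,
             truncate_pct: float | None = None) -> WeightSet:
    """Whole-population inverse-probability weights: 1/p for the selective
    arm, 1/(1-p) for the comprehensive arm; optional upper truncation at a
    weight percentile (off by default)."""
    p = np.asarray(model.propensity, float)
    if len(p) != len(table):
        raise ValueError("propensity not aligned to table")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("propensity of 0 or 1 encountered")
    sel = _exposure_indicator(table)
    w = np.where(sel == 1.0, 1.0 / p, 1.0 / (1.0 - p))
    meta = {}
    if truncate_pct is not None:
        cap = np.percentile(w, truncate_pct)
        meta["truncated_at"] = float(cap)
        w = np.minimum(w, cap)
    meta["arm_totals"] = {
        COMPREHENSIVE: float(w[sel == 0].sum()),
        SELECTIVE: float(w[sel == 1].sum()),
    }
    return WeightSet(weights=w, method=f"ipw-{model.method}", meta=meta)


def entropy_balance(table: pd.DataFrame, confounder_names: Sequence[str],
                    target: np.ndarray | None = None, tol: float = 1e-8,
                    ) -> WeightSet:
    """Exact-mean-balancing weights, closest to uniform in KL divergence.

    Within each system arm, solves the dual of min KL(w || uniform) subject to
    the weighted first moments of the confounder design equaling the
    full-sample moments (the whole-population target).  Weights are positive
    by construction; infeasible constraints (target outside the arm's convex
    hull) raise :class:`InfeasibleBalanceError` rather than producing negative
    weights.
    """
    X, names = build_design(table, confounder_names)
    if target is None:
        target = X.mean(axis=0)
    target = np.asarray(target, float)
    if target.shape != (X.shape[1],):
        raise ValueError("target moment vector has wrong length")
    sel = _exposure_indicator(table)
    n = len(table)
    w = np.empty(n)
    for arm in (0.0, 1.0):
        mask = sel == arm
        Z = X[mask] - target

        def dual_val(lam, Z=Z):
            e = Z @ lam
            m = e.max()
            return m + np.log(np.exp(e - m).sum())

        # damped Newton on the strictly convex dual: gradient is the
        # softmax-weighted moment error, Hessian its weighted covariance
        lam = np.zeros(Z.shape[1])
        p = np.full(len(Z), 1.0 / len(Z))
        for _ in range(200):
            g = Z.T @ p
            if np.abs(g).max() < tol * 1e-2:
                break
            H = Z.T @ (Z * p[:, None]) - np.outer(g, g)
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(len(g)), g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            f0 = dual_val(lam)
            t = 1.0
            while t > 1e-8 and dual_val(lam - t * step) > f0 - 1e-4 * t * (g @ step):
                t /= 2.0
            lam = lam - t * step
            e = Z @ lam
            p = np.exp(e - e.max())
            p /= p.sum()
        err = np.abs(Z.T @ p).max()
        if err > tol:
            raise InfeasibleBalanceError(
                f"entropy balancing infeasible in arm {int(arm)}: max first-moment "
                f"error {err:.2e} (target outside the arm's convex hull?)")
        # scale so each arm forms a pseudo-population of the full sample size
        w[mask] = p * n
    return WeightSet(weights=w, method="entropy", meta={"moment_names": names})


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = float(np.average(x, weights=w))
    return m, float(np.average((x - m) ** 2, weights=w))


def _smd(x: np.ndarray, sel: np.ndarray, w: np.ndarray) -> float:
    m1, v1 = _weighted_mean_var(x[sel == 1], w[sel == 1])
    m0, v0 = _weighted_mean_var(x[sel == 0], w[sel == 0])
    pooled = (v1 + v0) / 2.0
    if pooled == 0.0:
        if m1 == m0:
            return 0.0
        raise ValueError("constant but unequal arms: SMD undefined")
    return (m1 - m0) / np.sqrt(pooled)


@dataclass
class BalanceReport:
    """Before/after balance diagnostics mirroring a cohort baseline table."""

    table: pd.DataFrame  # variable, level, all_pct, comp/sel before, comp/sel after
    smd: pd.DataFrame    # variable, level, smd_before, smd_after
    pseudo_n: dict       # arm -> weighted size (after), plus unweighted sizes

    @property
    def mean_abs_smd_after(self) -> float:
        return float(self.smd["smd_after"].abs().mean())

    @property
    def mean_abs_smd_before(self) -> float:
        return float(self.smd["smd_before"].abs().mean())


def balance_report(table: pd.DataFrame, weights: WeightSet | np.ndarray,
                   confounder_names: Sequence[str]) -> BalanceReport:
    """Weighted/unweighted percentages per confounder level and standardized
    mean differences before/after weighting; includes pseudo-population sizes."""
    w_after = weights.weights if isinstance(weights, WeightSet) else np.asarray(weights, float)
    if len(w_after) != len(table):
        raise ValueError("weights not aligned to table rows")
    sel = _exposure_indicator(table)
    w_before = np.ones(len(table))

    # full-levels design for percentages and level-wise SMDs
    X, names = build_design(table, confounder_names, drop_first=False)
    rows, smd_rows = [], []
    for j, label in enumerate(names):
        x = X[:, j]
        var, _, level = label.partition("=")
        is_indicator = level != ""
        scale = 100.0 if is_indicator else 1.0
        rows.append({
            "variable": var if is_indicator else label,
            "level": level if is_indicator else "(mean)",
            "all": scale * float(np.average(x)),
            "comp_before": scale * float(np.average(x[sel == 0])),
            "sel_before": scale * float(np.average(x[sel == 1])),
            "comp_after": scale * float(np.average(x[sel == 0], weights=w_after[sel == 0])),
            "sel_after": scale * float(np.average(x[sel == 1], weights=w_after[sel == 1])),
        })
        smd_rows.append({
            "variable": var if is_indicator else label,
            "level": level if is_indicator else "(mean)",
            "smd_before": _smd(x, sel, w_before),
            "smd_after": _smd(x, sel, w_after),
        })
    pseudo_n = {
        "n": int(len(table)),
        "n_comprehensive": int((sel == 0).sum()),
        "n_selective": int((sel == 1).sum()),
        "pseudo_comprehensive": float(w_after[sel == 0].sum()),
        "pseudo_selective": float(w_after[sel == 1].sum()),
    }
    return BalanceReport(table=pd.DataFrame(rows), smd=pd.DataFrame(smd_rows),
                         pseudo_n=pseudo_n)


def select_weights(candidates: Sequence[WeightSet], table: pd.DataFrame,
                   confounder_names: Sequence[str]) -> WeightSet:
    """Pick the candidate with the smallest mean absolute SMD across all
    confounder levels; ties broken by the smaller weight coefficient of
    variation.  The criterion value is recorded on every candidate."""
    if len(candidates) == 0:
        raise ValueError("empty candidate list")
    scored = []
    for cand in candidates:
        rep = balance_report(table, cand, confounder_names)
        cand.criterion = rep.mean_abs_smd_after
        scored.append((cand.criterion, cand.cv, cand))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]
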