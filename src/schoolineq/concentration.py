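"""Weighted regression-based concentration indices of health inequality.

The concentration index (CI) measures how a health outcome is distributed
across an ordered socio-economic gradient: it equals twice the (weighted)
covariance between the 0-1-scaled outcome and the individual's fractional
socio-economic rank, divided by the outcome mean.  Positive values mean good
health is concentrated among the advantaged.

Estimation follows the convenient-regression route: each ordered group is
coded at the midpoint of its ranked cumulative (weighted) proportion, the
scaled outcome is multiplied by 2*var_w(rank)/mu_w (relative index) and
additionally by 4*mu_w (absolute, Erreygers-type index for a 0-1 bounded
outcome), and the index is the slope of the weighted least-squares regression
of that transformed variable on the rank.  The slope is algebraically equal to
2*cov_w(y, r)/mu_w (relative) and 8*cov_w(y, r) (absolute).

Outcomes are analysed both as attainment (oriented worse -> best) and as
shortfall (1 - attainment); relative indices differ between the orientations
while the absolute index only flips sign.  A school-system interaction model
contrasts inequality between the comprehensive and selective systems, with the
transform's mean and rank variance computed within each system arm so the
interaction coefficient is exactly the difference of the stand-alone arm
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import COMPREHENSIVE, SELECTIVE

__all__ = [
    "RankCoding",
    "OutcomeCoding",
    "CIEstimate",
    "SystemContrast",
    "fractional_rank",
    "code_outcome",
    "concentration_index",
    "system_contrast",
    "mirror_checks",
    "grouped_means",
    "VARIANTS",
]

VARIANTS = ("relative_attainment", "relative_shortfall", "absolute")


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights not aligned to data rows")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    return w


@dataclass
class RankCoding:
    """Fractional midpoint ranks for an ordered socio-economic variable."""

    ranks: np.ndarray
    groups: pd.DataFrame  # columns: label, share, midpoint (disadvantaged first)
    codes: np.ndarray = field(repr=False, default=None)


def fractional_rank(class_values, weights=None) -> RankCoding:
    """Code an ordered categorical at the midpoint of its ranked cumulative
    weighted proportion, most disadvantaged first.

    ``class_values`` must be an *ordered* pandas Categorical (or Series of
    one), ordered from most disadvantaged to most advantaged.  All members of
    a group share the group midpoint; the weighted mean of the returned ranks
    is exactly 0.5.
    """
    if isinstance(class_values, pd.Series):
        class_values = class_values.array
    if not isinstance(class_values, pd.Categorical):
        raise TypeError("class_values must be a pandas Categorical")
    if not class_values.ordered:
        raise ValueError("class variable must carry a declared "
                         "disadvantaged->advantaged order")
    n = len(class_values)
    if n == 0:
        raise ValueError("empty input")
    if class_values.isna().any():
        raise ValueError("missing class values; handle missingness upstream")
    w = _as_weights(weights, n)

    codes = np.asarray(class_values.codes)
    k = len(class_values.categories)
    totals = np.bincount(codes, weights=w, minlength=k)
    shares = totals / totals.sum()
    mids = np.cumsum(shares) - shares / 2.0
    present = shares > 0  # empty declared categories carry no rank
    groups = pd.DataFrame({
        "label": np.asarray(class_values.categories)[present],
        "share": shares[present],
        "midpoint": mids[present],
    })
    return RankCoding(ranks=mids[codes], groups=groups, codes=codes)


@dataclass
class OutcomeCoding:
    """An outcome oriented and scaled for concentration-index estimation.

    ``attainment`` is the 0-1-scaled outcome with larger = better health;
    ``shortfall`` its element-wise complement 1 - attainment.
    """

    attainment: np.ndarray
    shortfall: np.ndarray
    bounds: tuple
    bounds_source: str  # "theoretical" | "observed"
    kind: str
    raw: np.ndarray = field(repr=False, default=None)

    def values(self, orientation: str) -> np.ndarray:
        if orientation == "attainment":
            return self.attainment
        if orientation == "shortfall":
            return self.shortfall
        raise ValueError(f"unknown orientation {orientation!r}")


def code_outcome(values, kind: str = "continuous", higher_is_better: bool = True,
                 bounds: tuple | None = None, weights=None) -> OutcomeCoding:
    """Orient an outcome as attainment/shortfall and scale it to [0, 1].

    Scaling uses theoretical ``bounds`` when supplied (all values must lie
    within them), else the observed weighted range.  Binary outcomes must be
    coded {0, 1} already.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("values must be a non-empty vector")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing or non-finite outcome values; "
                         "handle missingness upstream")
    w = _as_weights(weights, y.size)

    if kind == "binary":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("binary outcome must be coded 0/1")
        scaled = y
        used = (0.0, 1.0)
        source = "theoretical"
    else:
        if bounds is not None:
            lo, hi = float(bounds[0]), float(bounds[1])
            if hi <= lo:
                raise ValueError("bounds must satisfy min < max")
            if y.min() < lo - 1e-12 or y.max() > hi + 1e-12:
                raise ValueError("values outside declared theoretical bounds")
            source = "theoretical"
        else:
            mask = w > 0
            lo, hi = float(y[mask].min()), float(y[mask].max())
            source = "observed"
            if hi == lo:
                raise ValueError("constant outcome: relative indices undefined")
        scaled = (y - lo) / (hi - lo)
        used = (lo, hi)

    att = scaled if higher_is_better else 1.0 - scaled
    return OutcomeCoding(attainment=att, shortfall=1.0 - att, bounds=used,
                         bounds_source=source, kind=kind, raw=y)


@dataclass
class CIEstimate:
    """One concentration-index estimate with its 95% interval."""

    variant: str
    estimate: float
    lo95: float
    hi95: float
    se: float
    se_method: str
    mu: float
    var_rank: float
    n_eff: float
    n: int
    n_boot: int | None = None


def _weighted_moments(y: np.ndarray, r: np.ndarray, w: np.ndarray):
    sw = w.sum()
    mu = float(w @ y / sw)
    rbar = float(w @ r / sw)
    var_r = float(w @ (r - rbar) ** 2 / sw)
    cov = float(w @ (y * r) / sw) - mu * rbar
    return mu, rbar, var_r, cov

def _transform_factor(variant: str, mu: float, var_r: float) -> float:
    if variant in ("relative_attainment", "relative_shortfall"):
        if not 0.0 < mu < 1.0:
            raise ValueError(f"mean {mu:.4f} outside (0,1): relative index undefined")
        return 2.0 * var_r / mu
    if variant == "absolute":
        if mu <= 0.0:
            raise ValueError("mean must be positive")
        return (2.0 * var_r / mu) * (4.0 * mu)
    raise ValueError(f"unknown variant {variant!r}")


def _orientation(variant: str) -> str:
    return "shortfall" if variant == "relative_shortfall" else "attainment"


def _ci_point(y: np.ndarray, r: np.ndarray, w: np.ndarray, variant: str) -> float:
    # covariance form; equal to the WLS transform-slope to machine precision
    mu, _, var_r, cov = _weighted_moments(y, r, w)
    if variant == "absolute":
        return 8.0 * cov
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mean {mu:.4f} outside (0,1): relative index undefined")
    return 2.0 * cov / mu


def _wls_slope(y_trans: np.ndarray, r: np.ndarray, w: np.ndarray):
    X = sm.add_constant(r)
    fit = sm.WLS(y_trans, X, weights=w).fit()
    return fit


def concentration_index(coding: OutcomeCoding, ranks: RankCoding, weights=None,
                        variant: str = "relative_attainment",
                        se_method: str = "bootstrap", n_boot: int = 999,
                        seed: int | None = None) -> CIEstimate:
    """Estimate one concentration-index variant by the regression transform.

    The scaled, oriented outcome is multiplied by 2*var_w(rank)/mu_w (and by
    4*mu_w for the absolute variant) and regressed on the fractional rank by
    weighted least squares; the slope is the index.  Intervals come from a
    nonparametric bootstrap (records resampled, rank coding and moments
    recomputed; supplied weights carried along) or, with
    ``se_method="robust"``, from the HC1 sandwich of the final regression.
    """
    y = coding.values(_orientation(variant))
    r = np.asarray(ranks.ranks, dtype=float)
    if y.shape != r.shape:
        raise ValueError("outcome coding and rank coding are not row-aligned")
    if len(np.unique(r)) < 2:
        raise ValueError("fewer than 2 distinct rank values")
    w = _as_weights(weights, y.size)

    mu, _, var_r, _ = _weighted_moments(y, r, w)
    factor = _transform_factor(variant, mu, var_r)
    fit = _wls_slope(y * factor, r, w)
    est = float(fit.params[1])
    n_eff = float(w.sum() ** 2 / (w ** 2).sum())

    if se_method == "robust":
        rob = fit.get_robustcov_results(cov_type="HC1")
        se = float(np.asarray(rob.bse)[1])
        lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
        nb = None
    elif se_method == "bootstrap":
        codes = ranks.codes
        if codes is None:
            raise ValueError("rank coding lacks group codes needed for bootstrap")
        rng = np.random.default_rng(seed)
        k = int(codes.max()) + 1
        n = y.size
        stats = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            cb, wb, yb = codes[idx], w[idx], y[idx]
            totals = np.bincount(cb, weights=wb, minlength=k)
            shares = totals / totals.sum()
            mids = np.cumsum(shares) - shares / 2.0
            stats[b] = _ci_point(yb, mids[cb], wb, variant)
        se = float(stats.std(ddof=1))
        lo, hi = (float(np.percentile(stats, 2.5)),
                  float(np.percentile(stats, 97.5)))
        nb = n_boot
    else:
        raise ValueError(f"unknown se_method {se_method!r}")

    return CIEstimate(variant=variant, estimate=est, lo95=lo, hi95=hi, se=se,
                      se_method=se_method, mu=mu, var_rank=var_r, n_eff=n_eff,
                      n=y.size, n_boot=nb)


@dataclass
class SystemContrast:
    """Arm-wise concentration indices and their selective - comprehensive
    difference from the school-system interaction model."""

    variant: str
    comprehensive: CIEstimate
    selective: CIEstimate
    difference: float
    lo95: float
    hi95: float
    se: float
    se_method: str


def system_contrast(table: pd.DataFrame, outcome: str, strat_var: str,
                    weights=None, variant: str = "relative_attainment",
                    kind: str | None = None, higher_is_better: bool | None = None,
                    bounds: tuple | None = None, system_col: str = "system",
                    se_method: str = "bootstrap", n_boot: int = 999,
                    seed: int | None = None) -> SystemContrast:
    """Contrast inequality between school systems via one interacted WLS fit.

    Fits transformed_outcome ~ rank + system + rank x system with the
    transform's mean and rank variance — and the rank coding itself — computed
    within each system arm, so each arm's slope equals its stand-alone index
    and the interaction coefficient equals CI_selective - CI_comprehensive.
    Outcome metadata (kind / direction / bounds) defaults to the table's
    ``outcome_meta`` attrs; scaling bounds fall back to the pooled observed
    range so both arms share one scale.
    """
    meta = table.attrs.get("outcome_meta", {}).get(outcome, {})
    kind = kind if kind is not None else meta.get("kind", "continuous")
    if higher_is_better is None:
        higher_is_better = meta.get("higher_is_better", True)
    if bounds is None:
        b = meta.get("bounds")
        bounds = tuple(b) if b is not None else None

    sys_vals = table[system_col].astype(str).to_numpy()
    labels = set(sys_vals)
    if not labels <= {COMPREHENSIVE, SELECTIVE} or len(labels) != 2:
        raise ValueError("both school systems must be present")
    sel = sys_vals == SELECTIVE
    w = _as_weights(weights, len(table))
    yraw = table[outcome].to_numpy(float)
    if bounds is None and kind != "binary":
        mask = w > 0
        bounds = (float(yraw[mask].min()), float(yraw[mask].max()))

    strat = table[strat_var]
    if not isinstance(strat.dtype, pd.CategoricalDtype) or not strat.array.ordered:
        raise ValueError(f"stratifier {strat_var!r} must be an ordered categorical")

    arm_est: dict[str, CIEstimate] = {}
    r_all = np.empty(len(table))
    y_trans = np.empty(len(table))
    rng = np.random.default_rng(seed)
    for label, mask in ((COMPREHENSIVE, ~sel), (SELECTIVE, sel)):
        sub = strat[mask]
        if len(pd.unique(sub.array.codes)) < 2:
            raise ValueError(f"{label} arm has a single stratifier level")
        rank = fractional_rank(sub.array, w[mask])
        coding = code_outcome(yraw[mask], kind=kind,
                              higher_is_better=higher_is_better,
                              bounds=bounds, weights=w[mask])
        arm_est[label] = concentration_index(
            coding, rank, w[mask], variant=variant, se_method=se_method,
            n_boot=n_boot, seed=int(rng.integers(2 ** 31)))
        yv = coding.values(_orientation(variant))
        mu, _, var_r, _ = _weighted_moments(yv, rank.ranks, w[mask])
        r_all[mask] = rank.ranks
        y_trans[mask] = yv * _transform_factor(variant, mu, var_r)

    s = sel.astype(float)
    X = sm.add_constant(np.column_stack([r_all, s, r_all * s]))
    fit = sm.WLS(y_trans, X, weights=w).fit()
    diff = float(fit.params[3])

    if se_method == "robust":
        rob = fit.get_robustcov_results(cov_type="HC1")
        se = float(np.asarray(rob.bse)[3])
        lo, hi = diff - 1.959963984540054 * se, diff + 1.959963984540054 * se
    else:
        # bootstrap the difference by resampling records within each arm
        parts = []
        for label, mask in ((COMPREHENSIVE, ~sel), (SELECTIVE, sel)):
            sub = strat[mask].array
            codes = np.asarray(sub.codes)
            coding = code_outcome(yraw[mask], kind=kind,
                                  higher_is_better=higher_is_better,
                                  bounds=bounds, weights=w[mask])
            parts.append((codes, coding.values(_orientation(variant)), w[mask],
                          len(sub.categories)))
        stats = np.empty(n_boot)
        for bidx in range(n_boot):
            vals = []
            for codes, yv, wv, k in parts:
                n_arm = len(codes)
                idx = rng.integers(0, n_arm, size=n_arm)
                cb, wb, yb = codes[idx], wv[idx], yv[idx]
                totals = np.bincount(cb, weights=wb, minlength=k)
                shares = totals / totals.sum()
                mids = np.cumsum(shares) - shares / 2.0
                vals.append(_ci_point(yb, mids[cb], wb, variant))
            stats[bidx] = vals[1] - vals[0]
        se = float(stats.std(ddof=1))
        lo, hi = (float(np.percentile(stats, 2.5)),
                  float(np.percentile(stats, 97.5)))

    return SystemContrast(variant=variant,
                          comprehensive=arm_est[COMPREHENSIVE],
                          selective=arm_est[SELECTIVE],
                          difference=diff, lo95=lo, hi95=hi, se=se,
                          se_method=se_method)


def mirror_checks(relative_attainment: CIEstimate,
                  relative_shortfall: CIEstimate,
                  absolute_attainment: CIEstimate | None = None,
                  absolute_shortfall: CIEstimate | None = None,
                  tol: float = 1e-10) -> dict:
    """Verify the attainment/shortfall mirror identities on aligned estimates.

    mu * C_attain = -(1 - mu) * C_shortfall for the relative pair, and the
    absolute index only switches sign between orientations.
    """
    a, s = relative_attainment, relative_shortfall
    if a.n != s.n:
        raise ValueError("orientation pair not row-aligned")
    rel_resid = a.mu * a.estimate + (1.0 - a.mu) * s.estimate
    report = {
        "mu": a.mu,
        "relative_identity_residual": rel_resid,
        "relative_identity_ok": abs(rel_resid) <= tol,
    }
    if absolute_attainment is not None and absolute_shortfall is not None:
        abs_resid = absolute_attainment.estimate + absolute_shortfall.estimate
        report["absolute_mirror_residual"] = abs_resid
        report["absolute_mirror_ok"] = abs(abs_resid) <= tol
    return report


def grouped_means(table: pd.DataFrame, outcome: str, weights=None,
                  by_system: bool = True, ability_bins: bool = False,
                  ability_col: str = "ability_std", bin_width: float = 5.0,
                  min_cell: int = 50, system_col: str = "system") -> pd.DataFrame:
    """Weighted means of an outcome by school system and/or ability bins.

    Ability is cut into ``bin_width``-point bins; sparse bins at either margin
    (fewer than ``min_cell`` records) are merged inward.  Intervals are normal
    approximations using the effective sample size.
    """
    w = _as_weights(weights, len(table))
    y = table[outcome].to_numpy(float)
    if np.any(~np.isfinite(y)):
        raise ValueError("missing outcome values; handle missingness upstream")

    frames: list[dict] = []
    groups: list[np.ndarray] = []
    labels: list[tuple] = []

    if ability_bins:
        a = table[ability_col].to_numpy(float)
        lo = np.floor(a.min() / bin_width) * bin_width
        hi = np.ceil(a.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        idx = np.clip(np.digitize(a, edges) - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        # merge sparse margins inward
        first, last = 0, len(counts) - 1
        while first < last and counts[: first + 1].sum() < min_cell:
            first += 1
        while last > first and counts[last:].sum() < min_cell:
            last -= 1
        idx = np.clip(idx, first, last)
        bin_ids = np.unique(idx)
        if any(np.sum(idx == b) == 0 for b in bin_ids):
            raise ValueError("empty ability cell after merging")
        bin_label = {b: f"[{edges[b] if b > first else edges[0]:g},"
                        f"{edges[b + 1] if b < last else edges[-1]:g})"
                     for b in bin_ids}
    else:
        idx = np.zeros(len(table), dtype=int)
        bin_ids = np.array([0])
        bin_label = {0: "all"}

    if by_system:
        sys_vals = table[system_col].astype(str).to_numpy()
        systems = [COMPREHENSIVE, SELECTIVE]
    else:
        sys_vals = np.full(len(table), "all")
        systems = ["all"]

    for b in bin_ids:
        for system in systems:
            mask = (idx == b) & (sys_vals == system)
            if not mask.any():
                raise ValueError(f"empty cell: system={system}, bin={bin_label[b]}")
            wm, ym = w[mask], y[mask]
            mean = float(np.average(ym, weights=wm))
            n_eff = float(wm.sum() ** 2 / (wm ** 2).sum())
            sd = float(np.sqrt(np.average((ym - mean) ** 2, weights=wm)))
            se = sd / np.sqrt(n_eff)
            frames.append({
                "outcome": outcome, "system": system, "ability_bin": bin_label[b],
                "mean": mean, "lo95": mean - 1.959963984540054 * se,
                "hi95": mean + 1.959963984540054 * se,
                "n": int(mask.sum()), "n_eff": n_eff,
            })
    return pd.DataFrame(frames)
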