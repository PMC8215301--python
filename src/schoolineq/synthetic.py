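"""Synthetic birth-cohort generator with planted, recoverable health inequality.

Emulates the structure of a UK-style birth cohort followed from childhood into
mid-adulthood: baseline confounders (sex, ethnicity, region, parental education
and interest, state primary schooling, a cognitive ability score and a
four-category ordered origin social class), a binary secondary school-system
exposure (comprehensive vs selective) whose probability depends on those
confounders, and adult outcomes whose socio-economic gradient — and hence true
concentration index — is known in closed form.  Optional missing-at-random
attrition and item non-response can be layered on top.

Every downstream stage of the analysis (balancing, concentration indices,
missing-data handling) is testable against the :class:`SimulationTruth`
returned alongside each table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "ConfounderSpec",
    "ExposureSpec",
    "OutcomeSpec",
    "SimulationTruth",
    "TruthEntry",
    "generate_cohort",
    "standardise_ability",
    "impose_missingness",
    "planted_continuous_outcome",
    "midpoint_ranks",
    "write_cohort",
    "read_cohort",
    "DEFAULT_CONFOUNDERS",
    "DEFAULT_EXPOSURE",
    "CONTROL_COLUMN",
]

COMPREHENSIVE = "comprehensive"
SELECTIVE = "selective"

#: Baseline negative-control column: childhood BMI generated independently of
#: origin class, so any estimated class gradient in it reflects bias.
CONTROL_COLUMN = "bmi_age11"

_PROB_TOL = 1e-12


def midpoint_ranks(probs: Sequence[float]) -> np.ndarray:
    """Cumulative-proportion midpoint ranks for ordered group probabilities.

    Group g (ordered most disadvantaged first) is coded at the cumulative share
    of groups below it plus half its own share; five equal groups give
    0.1, 0.3, 0.5, 0.7, 0.9.
    """
    p = np.asarray(probs, dtype=float)
    return np.cumsum(p) - p / 2.0


def _check_probs(name: str, probs: Sequence[float]) -> None:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name}: probabilities must be non-negative")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name}: probabilities sum to {p.sum()!r}, not 1")


@dataclass(frozen=True)
class ConfounderSpec:
    """Joint distribution of the baseline confounders.

    ``class_labels``/``class_probs`` are listed from most to least advantaged
    (four ordered occupational classes).  Categorical confounders are mutually
    independent; the raw ability score and origin class share a latent
    advantage factor with correlation ``ability_class_corr``.
    """

    categorical_vars: tuple = (
        ("sex", ("female", "male"), (0.49, 0.51)),
        ("ethnicity", ("white", "other"), (0.96, 0.04)),
        ("region", ("north", "midlands", "south", "wales_scotland"),
         (0.30, 0.22, 0.35, 0.13)),
        ("parent_left_edu", ("15_or_below", "16_to_18", "19_plus"),
         (0.73, 0.21, 0.06)),
        ("parental_interest", ("little", "some", "very"), (0.15, 0.43, 0.42)),
        ("state_primary", ("yes", "no"), (0.94, 0.06)),
    )
    ability_mean_raw: float = 100.0
    ability_sd_raw: float = 15.0
    class_labels: tuple = ("higher_managerial", "lower_managerial",
                           "intermediate", "routine")
    class_probs: tuple = (0.16, 0.05, 0.21, 0.58)
    ability_class_corr: float = 0.3

    def __post_init__(self) -> None:
        if len(self.class_labels) != 4 or len(self.class_probs) != 4:
            raise ValueError("exactly 4 ordered origin classes are required")
        _check_probs("class_probs", self.class_probs)
        for name, labels, probs in self.categorical_vars:
            if len(labels) != len(probs):
                raise ValueError(f"{name}: labels and probabilities differ in length")
            _check_probs(name, probs)
        if not 0.0 <= self.ability_class_corr < 1.0:
            raise ValueError("ability_class_corr must be in [0, 1)")
        if self.ability_sd_raw <= 0:
            raise ValueError("ability_sd_raw must be positive")

    @property
    def ordered_class_labels(self) -> tuple:
        """Class labels ordered most disadvantaged -> most advantaged."""
        return tuple(reversed(self.class_labels))

    @property
    def ordered_class_probs(self) -> np.ndarray:
        return np.asarray(tuple(reversed(self.class_probs)), dtype=float)

    @property
    def class_ranks(self) -> np.ndarray:
        """Population fractional midpoint rank of each ordered class."""
        return midpoint_ranks(self.ordered_class_probs)


@dataclass(frozen=True)
class ExposureSpec:
    """Log-odds model for selective-system attendance.

    Coefficient keys are either ``"ability"`` (applies to the z-scored
    standardised ability, (score-100)/15), ``"class_rank"`` (the population
    fractional rank of origin class, advantaged high) or an indicator
    ``"<variable>=<level>"``.
    """

    intercept: float = -1.35
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {
            "ability": 0.45,
            "class_rank": 1.2,
            "state_primary=no": 1.2,
            "parental_interest=very": 0.4,
        }
    )


@dataclass(frozen=True)
class OutcomeSpec:
    """One adult outcome with a planted socio-economic gradient.

    ``alpha`` is the outcome level (linear predictor for binary/ordinal) at
    fractional origin-class rank 0, ``beta`` the linear effect of the rank —
    the planted inequality.  ``system_shift`` and ``system_beta_shift`` move
    the level and the rank slope under the selective system.  Continuous
    outcomes live on the [0, 1] scale with mean-zero uniform noise of standard
    deviation ``noise_sd`` (bounded support keeps closed-form truths exact);
    binary outcomes use a logistic link; ordinal outcomes a proportional-odds
    construction with ``n_levels`` levels and cutpoints ``thresholds``.
    """

    name: str
    kind: str = "continuous"
    higher_is_better: bool = True
    alpha: float = 0.3
    beta: float = 0.3
    system_shift: float = 0.0
    system_beta_shift: float = 0.0
    noise_sd: float = 0.05
    n_levels: int = 4
    thresholds: tuple = (-1.2, 0.0, 1.2)

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind == "ordinal":
            if len(self.thresholds) != self.n_levels - 1:
                raise ValueError("need n_levels - 1 ordered thresholds")
            if not np.all(np.diff(self.thresholds) > 0):
                raise ValueError("thresholds must be strictly increasing")
        if self.kind == "continuous" and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def bounds(self) -> tuple:
        if self.kind == "continuous":
            return (0.0, 1.0)
        if self.kind == "binary":
            return (0.0, 1.0)
        return (1.0, float(self.n_levels))

    def _arm_params(self, selective: bool) -> tuple:
        s = 1.0 if selective else 0.0
        return (self.alpha + s * self.system_shift,
                self.beta + s * self.system_beta_shift)

    def class_attainment_means(self, ranks: np.ndarray, selective: bool) -> np.ndarray:
        """Expected 0-1-scaled attainment value within each ordered class."""
        a, b = self._arm_params(selective)
        eta = a + b * ranks
        if self.kind == "continuous":
            raw = eta
        elif self.kind == "binary":
            raw = expit(eta)
        else:
            # proportional odds: P(Y<=k) = expit(c_k - eta); scaled level
            # values are (k-1)/(K-1)
            cum = expit(np.subtract.outer(np.asarray(self.thresholds), eta))
            level_p = np.diff(np.vstack([np.zeros_like(eta)[None, :], cum,
                                         np.ones_like(eta)[None, :]]), axis=0)
            scale = np.arange(self.n_levels) / (self.n_levels - 1)
            raw = scale @ level_p
        return raw if self.higher_is_better else 1.0 - raw


@dataclass(frozen=True)
class TruthEntry:
    mean: float
    relative_attainment: float
    relative_shortfall: float
    absolute: float


@dataclass
class SimulationTruth:
    """Closed-form truth per (outcome, system): attainment mean, relative
    attainment/shortfall CIs, and the absolute index = 4 * mean * relative."""

    entries: dict = field(default_factory=dict)

    def get(self, outcome: str, system: str) -> TruthEntry:
        return self.entries[(outcome, system)]

    def to_dict(self) -> dict:
        return {f"{o}|{s}": asdict(e) for (o, s), e in self.entries.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationTruth":
        ent = {}
        for key, val in d.items():
            o, s = key.split("|")
            ent[(o, s)] = TruthEntry(**val)
        return cls(ent)


def _truth_for(out: OutcomeSpec, probs: np.ndarray, ranks: np.ndarray,
               selective: bool) -> TruthEntry:
    """Enumerate the four classes: mu = sum pi*m, cov = sum pi*r*m - 0.5*mu."""
    m = out.class_attainment_means(ranks, selective)
    mu = float(probs @ m)
    if not 0.0 < mu < 1.0:
        raise ValueError(
            f"outcome {out.name!r}: implied scaled mean {mu:.4f} outside (0,1)")
    cov = float(probs @ (ranks * m)) - 0.5 * mu
    rel = 2.0 * cov / mu
    return TruthEntry(mean=mu,
                      relative_attainment=rel,
                      relative_shortfall=-mu * rel / (1.0 - mu),
                      absolute=4.0 * mu * rel)


def standardise_ability(scores, weights=None) -> np.ndarray:
    """Affine-rescale ability scores to (weighted) mean 100 and SD 15.

    The SD uses the Σw(x-m)²/Σw convention.  Raises on a constant vector.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a vector of at least 2 scores")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative, aligned, with positive total")
    m = np.average(x, weights=w)
    sd = np.sqrt(np.average((x - m) ** 2, weights=w))
    if sd == 0.0:
        raise ValueError("cannot standardise a constant score vector")
    return 100.0 + 15.0 * (x - m) / sd


def _exact_class_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n across classes."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _linear_predictor(intercept: float, coefficients: Mapping[str, float],
                      table: pd.DataFrame, class_ranks: Mapping[str, float] | None = None
                      ) -> np.ndarray:
    """Evaluate an intercept + coefficient map on a cohort table.

    Keys: ``ability`` (z of ability_std), ``class_rank`` (origin-class
    fractional rank; from ``class_ranks`` if given, else realized unweighted
    shares), ``var=level`` indicators.
    """
    lp = np.full(len(table), float(intercept))
    for key, coef in coefficients.items():
        if key == "ability":
            lp += coef * (table["ability_std"].to_numpy(float) - 100.0) / 15.0
        elif key == "class_rank":
            cls = table["origin_class"]
            if class_ranks is None:
                shares = cls.value_counts(normalize=True, sort=False)
                shares = shares.reindex(cls.cat.categories).fillna(0.0)
                mids = midpoint_ranks(shares.to_numpy())
                class_ranks_eval = dict(zip(cls.cat.categories, mids))
            else:
                class_ranks_eval = class_ranks
            lp += coef * cls.map(class_ranks_eval).to_numpy(float)
        elif "=" in key:
            var, level = key.split("=", 1)
            if var not in table.columns:
                raise KeyError(f"exposure/missingness term references unknown column {var!r}")
            lp += coef * (table[var].astype(str) == level).to_numpy(float)
        else:
            raise KeyError(f"unrecognised coefficient key {key!r}")
    return lp


def generate_cohort(spec: ConfounderSpec | None = None,
                    exp: ExposureSpec | None = None,
                    outs: Sequence[OutcomeSpec] | None = None,
                    n: int = 10_000,
                    seed: int = 0,
                    exact_class_counts: bool = False,
                    ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a cohort table of ``n`` records plus its closed-form truth.

    Deterministic given (spec, exp, outs, n, seed).  ``exact_class_counts``
    apportions origin classes deterministically to their population shares
    (largest-remainder), which makes realized fractional ranks equal the
    population ranks — useful when checking estimators against the truth at
    machine precision.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    spec = spec or ConfounderSpec()
    exp = exp or ExposureSpec()
    if outs is None:
        outs = (OutcomeSpec(name="wellbeing"),)
    names = [o.name for o in outs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate outcome names")

    rng = np.random.default_rng(seed)
    table = pd.DataFrame({"id": np.arange(n)})

    for name, labels, probs in spec.categorical_vars:
        codes = rng.choice(len(labels), size=n, p=np.asarray(probs, float))
        table[name] = pd.Categorical.from_codes(codes, categories=list(labels))

    # latent advantage factor links ability and origin class
    rho = spec.ability_class_corr
    z = rng.standard_normal(n)
    a_lat = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n)
    c_lat = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.standard_normal(n)

    ordered = list(spec.ordered_class_labels)
    probs_ord = spec.ordered_class_probs
    if exact_class_counts:
        counts = _exact_class_counts(probs_ord, n)
        # rank records by the class latent so advantage ordering is preserved
        codes = np.empty(n, dtype=int)
        order = np.argsort(c_lat)
        codes[order] = np.repeat(np.arange(4), counts)
    else:
        cum = np.cumsum(probs_ord)
        codes = np.searchsorted(cum, norm.cdf(c_lat), side="left").clip(0, 3)
    table["origin_class"] = pd.Categorical.from_codes(
        codes, categories=ordered, ordered=True)

    table["ability_raw"] = spec.ability_mean_raw + spec.ability_sd_raw * a_lat
    table["ability_std"] = standardise_ability(table["ability_raw"].to_numpy())

    # negative-control variable: independent of class, ability and system
    table[CONTROL_COLUMN] = 17.5 + 2.0 * rng.standard_normal(n)

    class_rank_map = dict(zip(ordered, spec.class_ranks))
    p_sel = expit(_linear_predictor(exp.intercept, exp.coefficients, table,
                                    class_ranks=class_rank_map))
    if not np.all((p_sel > 0.0) & (p_sel < 1.0)):
        raise ValueError("exposure model violates positivity (probability 0 or 1)")
    sel = rng.random(n) < p_sel
    table["system"] = pd.Categorical(
        np.where(sel, SELECTIVE, COMPREHENSIVE),
        categories=[COMPREHENSIVE, SELECTIVE])

    r = np.asarray([class_rank_map[c] for c in ordered])[codes]
    s = sel.astype(float)
    truth = SimulationTruth()
    for out in outs:
        a_arm = out.alpha + s * out.system_shift
        b_arm = out.beta + s * out.system_beta_shift
        eta = a_arm + b_arm * r
        if out.kind == "continuous":
            half = out.noise_sd * np.sqrt(3.0)
            lo = eta.min() - half
            hi = eta.max() + half
            if lo < 0.0 or hi > 1.0:
                raise ValueError(
                    f"outcome {out.name!r}: support [{lo:.3f}, {hi:.3f}] exceeds [0, 1]; "
                    "reduce |alpha|, |beta| or noise_sd")
            g = eta + rng.uniform(-half, half, size=n)
            raw = g if out.higher_is_better else 1.0 - g
        elif out.kind == "binary":
            p1 = expit(eta)
            raw = (rng.random(n) < p1).astype(int)
        else:
            cum = expit(np.subtract.outer(np.asarray(out.thresholds), eta))
            u = rng.random(n)
            raw = 1 + (u > cum).sum(axis=0)
        table[out.name] = raw
        for system, is_sel in ((COMPREHENSIVE, False), (SELECTIVE, True)):
            truth.entries[(out.name, system)] = _truth_for(
                out, probs_ord, spec.class_ranks, is_sel)

    table.attrs["confounder_names"] = (
        [v[0] for v in spec.categorical_vars] + ["ability_std", "origin_class"])
    table.attrs["outcome_names"] = names
    table.attrs["outcome_meta"] = {
        o.name: {"kind": o.kind, "higher_is_better": o.higher_is_better,
                 "bounds": list(o.bounds)} for o in outs}
    return table, truth


def planted_continuous_outcome(name: str, ci_comprehensive: float,
                               ci_selective: float | None = None,
                               mu: float = 0.5, noise_sd: float = 0.05,
                               spec: ConfounderSpec | None = None,
                               higher_is_better: bool = True) -> OutcomeSpec:
    """Continuous OutcomeSpec whose true relative attainment CI equals
    ``ci_comprehensive`` (and ``ci_selective`` under the selective system),
    holding the attainment mean at ``mu`` in both arms.

    Inverts CI = 2*beta*var(r)/mu for the class distribution of ``spec``.
    """
    spec = spec or ConfounderSpec()
    ranks = spec.class_ranks
    var_r = float(spec.ordered_class_probs @ (ranks - 0.5) ** 2)
    if ci_selective is None:
        ci_selective = ci_comprehensive
    beta_c = ci_comprehensive * mu / (2.0 * var_r)
    beta_s = ci_selective * mu / (2.0 * var_r)
    alpha_c = mu - 0.5 * beta_c
    alpha_s = mu - 0.5 * beta_s
    return OutcomeSpec(name=name, kind="continuous",
                       higher_is_better=higher_is_better,
                       alpha=alpha_c, beta=beta_c,
                       system_shift=alpha_s - alpha_c,
                       system_beta_shift=beta_s - beta_c,
                       noise_sd=noise_sd)


def impose_missingness(table: pd.DataFrame,
                       attrition_model: Mapping | None = None,
                       item_models: Mapping[str, Mapping] | None = None,
                       seed: int = 0,
                       outcome_names: Sequence[str] | None = None,
                       ) -> pd.DataFrame:
    """Overlay MAR attrition and item non-response on a cohort table.

    ``attrition_model`` is ``{"intercept": b0, "coefficients": {...}}`` on the
    log-odds of *wave non-response*; affected records have every outcome column
    blanked and ``wave_nonresponse = 1``.  ``item_models`` maps outcome columns
    to models of the same form for single-cell missingness.  Models may only
    reference baseline confounders (which are never blanked); referencing an
    outcome raises, since that column could itself be missing.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    if outcome_names is None:
        outcome_names = table.attrs.get("outcome_names")
    if outcome_names is None:
        raise ValueError("outcome_names required (not found in table.attrs)")
    outcome_set = set(outcome_names)

    def _probs(model: Mapping, label: str) -> np.ndarray:
        for key in model.get("coefficients", {}):
            var = key.split("=", 1)[0]
            if var in outcome_set:
                raise ValueError(
                    f"{label}: model references outcome column {var!r}, which may "
                    "itself be missing at baseline")
        p = expit(_linear_predictor(model.get("intercept", 0.0),
                                    model.get("coefficients", {}), out))
        if not np.all((p > 0.0) & (p < 1.0)):
            raise ValueError(f"{label}: degenerate missingness probability 0 or 1")
        return p

    out["wave_nonresponse"] = 0
    if attrition_model is not None:
        p_miss = _probs(attrition_model, "attrition_model")
        gone = rng.random(len(out)) < p_miss
        out.loc[gone, list(outcome_names)] = np.nan
        out["wave_nonresponse"] = gone.astype(int)

    for var, model in (item_models or {}).items():
        if var not in out.columns:
            raise KeyError(f"item model references unknown column {var!r}")
        p_miss = _probs(model, f"item_models[{var}]")
        hit = rng.random(len(out)) < p_miss
        out.loc[hit, var] = np.nan
        out[f"{var}_missing"] = (hit | (out["wave_nonresponse"] == 1)).astype(int)

    out.attrs = dict(table.attrs)
    return out


def write_cohort(table: pd.DataFrame, truth: SimulationTruth | None,
                 out_dir: str | Path, stem: str = "cohort") -> Path:
    """Write a cohort as CSV plus a JSON sidecar (truth + column metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    table.to_csv(csv_path, index=False)
    sidecar = {
        "confounder_names": table.attrs.get("confounder_names"),
        "outcome_names": table.attrs.get("outcome_names"),
        "outcome_meta": table.attrs.get("outcome_meta"),
        "truth": truth.to_dict() if truth is not None else None,
        "ordered_class_labels": list(table["origin_class"].cat.categories)
        if "origin_class" in table else None,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_cohort(csv_path: str | Path) -> tuple[pd.DataFrame, SimulationTruth | None]:
    """Read a cohort CSV written by :func:`write_cohort` (sidecar optional)."""
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    truth = None
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        for key in ("confounder_names", "outcome_names", "outcome_meta"):
            if sidecar.get(key) is not None:
                table.attrs[key] = sidecar[key]
        if sidecar.get("ordered_class_labels"):
            table["origin_class"] = pd.Categorical(
                table["origin_class"],
                categories=sidecar["ordered_class_labels"], ordered=True)
        if sidecar.get("truth"):
            truth = SimulationTruth.from_dict(sidecar["truth"])
    if "system" in table.columns and not isinstance(table["system"].dtype,
                                                    pd.CategoricalDtype):
        table["system"] = pd.Categorical(table["system"],
                                         categories=[COMPREHENSIVE, SELECTIVE])
    return table, truth


DEFAULT_CONFOUNDERS = ConfounderSpec()
DEFAULT_EXPOSURE = ExposureSpec()
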