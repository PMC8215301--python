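"""End-to-end pipeline: simulate -> missingness -> weights -> concentration.

A single :class:`RunConfig` drives every stage; the result is a
:class:`ResultsBundle` holding the balance report, a long-format table of
arm-wise concentration indices and their school-system contrasts per outcome,
stratifier and variant, grouped weighted means, the negative-control check and
a reproducibility manifest.  Identical config + seeds give identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .synthetic import (ConfounderSpec, ExposureSpec, OutcomeSpec,
                        SimulationTruth, generate_cohort, impose_missingness,
                        planted_continuous_outcome, read_cohort, write_cohort,
                        CONTROL_COLUMN, COMPREHENSIVE, SELECTIVE)
from .balance import (BalanceReport, WeightSet, balance_report, entropy_balance,
                      fit_propensity, make_ipw, select_weights,
                      InfeasibleBalanceError, PROPENSITY_METHODS)
from .concentration import (CIEstimate, SystemContrast, VARIANTS, code_outcome,
                            concentration_index, fractional_rank, grouped_means,
                            system_contrast)
from .missingness import impute, pool, response_weights

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "negative_control",
           "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class RunConfig:
    """Configuration for one full pipeline run (YAML round-trippable)."""

    n: int = 10_000
    seed: int = 0
    input_path: str | None = None          # load a cohort instead of simulating
    outcomes: list = field(default_factory=lambda: [
        {"name": "wellbeing", "planted_ci": {"comprehensive": 0.10,
                                             "selective": 0.10},
         "mu": 0.5, "noise_sd": 0.05},
        {"name": "smoker", "kind": "binary", "higher_is_better": False,
         "alpha": -2.0, "beta": 1.6},
    ])
    confounders: list | None = None        # default: generator's confounders
    strat_vars: list = field(default_factory=lambda: ["origin_class"])
    variants: list = field(default_factory=lambda: list(VARIANTS))
    methods: list = field(default_factory=lambda: ["logistic", "spline",
                                                   "ridge", "entropy"])
    se_method: str = "bootstrap"
    n_boot: int = 999
    missingness: dict | None = None        # attrition_model / item_models
    m: int = 5
    iterations: int = 10
    negative_control_var: str = CONTROL_COLUMN
    ability_bins: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def outcome_specs(self) -> list:
        specs = []
        for entry in self.outcomes:
            entry = dict(entry)
            if "planted_ci" in entry:
                planted = entry.pop("planted_ci")
                specs.append(planted_continuous_outcome(
                    entry["name"],
                    ci_comprehensive=planted["comprehensive"],
                    ci_selective=planted.get("selective"),
                    mu=entry.get("mu", 0.5),
                    noise_sd=entry.get("noise_sd", 0.05),
                    higher_is_better=entry.get("higher_is_better", True)))
            else:
                specs.append(OutcomeSpec(**entry))
        return specs


@dataclass
class ResultsBundle:
    balance: BalanceReport
    results: pd.DataFrame          # long format: outcome x strat x variant x system
    means: pd.DataFrame
    negative_control: dict
    manifest: dict
    weights: WeightSet
    truth: SimulationTruth | None = None

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "concentration_results.csv", index=False)
        self.means.to_csv(out / "grouped_means.csv", index=False)
        self.balance.table.to_csv(out / "balance_table.csv", index=False)
        self.balance.smd.to_csv(out / "balance_smd.csv", index=False)
        payload = {
            "manifest": self.manifest,
            "negative_control": self.negative_control,
            "pseudo_n": self.balance.pseudo_n,
        }
        (out / "manifest.json").write_text(json.dumps(payload, indent=2))
        return out


def _row(outcome: str, strat: str, variant: str, system: str,
         est: CIEstimate | None, diff: tuple | None = None) -> dict:
    if est is not None:
        return {"outcome": outcome, "stratifier": strat, "variant": variant,
                "system": system, "estimate": est.estimate, "lo95": est.lo95,
                "hi95": est.hi95, "mu": est.mu, "n_eff": est.n_eff}
    d, lo, hi = diff
    return {"outcome": outcome, "stratifier": strat, "variant": variant,
            "system": system, "estimate": d, "lo95": lo, "hi95": hi,
            "mu": np.nan, "n_eff": np.nan}


def _pool_contrasts(contrasts: Sequence[SystemContrast]) -> tuple:
    """Rubin-pool the arm estimates and the difference across imputations."""
    comp = pool([c.comprehensive for c in contrasts])
    selv = pool([c.selective for c in contrasts])
    m = len(contrasts)
    points = np.array([c.difference for c in contrasts])
    within = float(np.mean([c.se ** 2 for c in contrasts]))
    between = float(points.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    d = float(points.mean())
    half = 1.959963984540054 * np.sqrt(total)
    return comp, selv, (d, d - half, d + half)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 ) -> ResultsBundle:
    """Execute every stage of the analysis under one configuration."""
    t0 = time.time()
    stage_log: list[dict] = []
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]

    # ---- stage 1: cohort -------------------------------------------------
    stage = "simulate"
    try:
        if config.input_path:
            table, truth = read_cohort(config.input_path)
        else:
            table, truth = generate_cohort(outs=config.outcome_specs(),
                                           n=config.n, seed=sub[0])
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    confounders = config.confounders or table.attrs.get("confounder_names")
    if not confounders:
        raise PipelineError(stage, "no confounder list available")
    missing_cols = [c for c in confounders if c not in table.columns]
    if missing_cols:
        raise PipelineError(stage, f"config references missing columns {missing_cols}")
    outcome_names = [o["name"] for o in config.outcomes]
    stage_log.append({"stage": stage, "rows": len(table),
                      "seconds": round(time.time() - t0, 3)})

    # ---- stage 2: missingness -------------------------------------------
    stage = "missingness"
    t1 = time.time()
    try:
        if config.missingness:
            table = impose_missingness(
                table,
                attrition_model=config.missingness.get("attrition_model"),
                item_models=config.missingness.get("item_models"),
                seed=sub[1], outcome_names=outcome_names)
            resp_ws = response_weights(table, confounders,
                                       outcome_names=outcome_names)
        else:
            resp_ws = WeightSet(weights=np.ones(len(table)), method="response-ipw",
                                meta={"response_rate": 1.0})
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    stage_log.append({"stage": stage, "rows": len(table),
                      "seconds": round(time.time() - t1, 3)})

    # ---- stage 3: confounder-balancing weights --------------------------
    stage = "weights"
    t1 = time.time()
    try:
        candidates = []
        for method in config.methods:
            if method == "entropy":
                try:
                    candidates.append(entropy_balance(table, confounders))
                except InfeasibleBalanceError:
                    continue
            elif method in PROPENSITY_METHODS:
                model = fit_propensity(table, confounders, method=method,
                                       ridge_seed=sub[2])
                candidates.append(make_ipw(model, table))
            else:
                raise ValueError(f"unknown weighting method {method!r}")
        selected = select_weights(candidates, table, confounders)
        bal = balance_report(table, selected, confounders)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    stage_log.append({"stage": stage, "rows": len(table),
                      "selected": selected.method,
                      "seconds": round(time.time() - t1, 3)})

    # ---- stage 4: imputation of item non-response -----------------------
    stage = "impute"
    t1 = time.time()
    responders = resp_ws.weights > 0
    analysis_w = selected.weights * resp_ws.weights
    work = table.loc[responders].reset_index(drop=True)
    work.attrs = dict(table.attrs)
    w_work = analysis_w[responders]
    has_item_missing = work[outcome_names].isna().any().any()
    try:
        if has_item_missing:
            imps = impute(work, m=config.m, iterations=config.iterations,
                          seed=sub[3], predictor_names=confounders,
                          weights=w_work)
            analysis_tables = imps.tables
        else:
            analysis_tables = [work]
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    stage_log.append({"stage": stage, "rows": len(work),
                      "m": len(analysis_tables),
                      "seconds": round(time.time() - t1, 3)})

    # ---- stage 5: concentration indices ---------------------------------
    stage = "concentration"
    t1 = time.time()
    rows = []
    try:
        for outcome in outcome_names:
            for strat in config.strat_vars:
                for variant in config.variants:
                    contrasts = [
                        system_contrast(tab, outcome, strat, weights=w_work,
                                        variant=variant,
                                        se_method=config.se_method,
                                        n_boot=config.n_boot, seed=sub[4])
                        for tab in analysis_tables]
                    if len(contrasts) > 1:
                        comp, selv, diff = _pool_contrasts(contrasts)
                    else:
                        c = contrasts[0]
                        comp, selv = c.comprehensive, c.selective
                        diff = (c.difference, c.lo95, c.hi95)
                    rows.append(_row(outcome, strat, variant, COMPREHENSIVE, comp))
                    rows.append(_row(outcome, strat, variant, SELECTIVE, selv))
                    rows.append(_row(outcome, strat, variant, "difference",
                                     None, diff))
        results = pd.DataFrame(rows)
        means = pd.concat([
            grouped_means(analysis_tables[0], outcome, weights=w_work,
                          by_system=True, ability_bins=config.ability_bins)
            for outcome in outcome_names], ignore_index=True)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    stage_log.append({"stage": stage, "rows": len(results),
                      "seconds": round(time.time() - t1, 3)})

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": sub,
        "stages": stage_log,
        "selected_weights": selected.method,
        "candidate_criteria": {c.method: c.criterion for c in candidates},
    }
    bundle = ResultsBundle(balance=bal, results=results, means=means,
                           negative_control={}, manifest=manifest,
                           weights=WeightSet(weights=analysis_w,
                                             method=selected.method,
                                             criterion=selected.criterion),
                           truth=truth)

    # ---- stage 6: negative control --------------------------------------
    bundle.negative_control = negative_control(
        config, bundle, table=work, weights=w_work, seed=sub[5])

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def negative_control(config: RunConfig, bundle: ResultsBundle,
                     table: pd.DataFrame | None = None,
                     weights: np.ndarray | None = None,
                     seed: int | None = None) -> dict:
    """Estimate the class gradient of a pre-exposure control variable.

    The control must be excluded from the confounding model; any class
    inequality found in it signals residual confounding.  Flags (never fails)
    when the 95% interval excludes 0.
    """
    var = config.negative_control_var
    confounders = config.confounders or (
        table.attrs.get("confounder_names") if table is not None else None)
    if confounders and var in confounders:
        raise PipelineError(
            "negative_control",
            f"control variable {var!r} appears among the confounders; a "
            "negative control must be excluded from the propensity model")
    if table is None or var not in table.columns:
        return {"variable": var, "available": False}
    rank = fractional_rank(table["origin_class"].array, weights)
    coding = code_outcome(table[var].to_numpy(float), kind="continuous",
                          weights=weights)
    est = concentration_index(coding, rank, weights,
                              variant="relative_attainment",
                              se_method=config.se_method,
                              n_boot=config.n_boot, seed=seed)
    flagged = not (est.lo95 <= 0.0 <= est.hi95)
    return {"variable": var, "available": True, "estimate": est.estimate,
            "lo95": est.lo95, "hi95": est.hi95, "flagged": flagged}
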