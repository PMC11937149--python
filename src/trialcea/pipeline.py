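"""End-to-end orchestration and publication-style reporting.

``run_pipeline`` chains the analysis stages on a participant-level cluster
trial: cost construction → QALY construction → complete-case estimation →
multiple imputation → pooled estimation → net-benefit / CEAC analysis,
and emits a report bundle: a descriptive table (per arm and period mean
(SD) usage and cost), an incremental results table with complete-case and
multiple-imputation columns, a CEAC table and plot, and a manifest with
every seed and the software versions, sufficient to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cea as cea_mod
from .costing import (DEFAULT_HORIZON_DAYS, InterventionCostSpec,
                      UnitCostTable, cost_dataset, default_unit_costs)
from .estimation import IncrementalEstimate, ModelSpec, incremental_estimate, mi_estimate
from .imputation import ImputationSpec, MICollection, pmm_impute
from .outcomes import ValueSet, qaly_dataset, synthetic_value_set
from .synthetic import SERVICE_ITEMS, SimConfig, TrialDataset, simulate_trial

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
            "prepare_analysis_frame", "descriptive_table",
            "default_intervention_spec"]

#: Implementation-cost inputs emulating the reference trial's €53,492
#: spread over 208 intervention participants (€257 per head).
def default_intervention_spec(n_intervention: int = 208) -> InterventionCostSpec:
    return InterventionCostSpec(fixed_total=30_000.0, variable_total=23_492.0,
                                n_intervention_participants=n_intervention)


@dataclass
class PipelineConfig:
    """Everything a run needs besides the data."""

    unit_costs: UnitCostTable = field(default_factory=default_unit_costs)
    intervention_cost: Optional[InterventionCostSpec] = None  # None -> default
    value_set: ValueSet = field(default_factory=synthetic_value_set)
    horizon_days: int = DEFAULT_HORIZON_DAYS
    horizon_years: float = 0.5
    death_rule: str = "zero_from_death"
    m_imputations: int = 10
    knn: int = 5
    imputation_predictors: Optional[Sequence[str]] = None
    imputation_targets: Optional[Sequence[str]] = None
    cost_family: str = "gamma"
    cost_link: str = "identity"
    cost_covariates: Sequence[str] = ("arm_int", "total_cost_baseline")
    qaly_covariates: Sequence[str] = ("arm_int", "eq5d_baseline")
    inb_covariates: Sequence[str] = ("arm_int",)
    lambda_grid: Sequence[float] = cea_mod.DEFAULT_LAMBDA_GRID
    key_thresholds: Sequence[float] = (20_000.0, 45_000.0)
    b_bootstrap: int = 2000
    n_monte_carlo: int = 2000
    methods: Sequence[str] = ("two_stage_bootstrap", "parametric", "monte_carlo")
    bootstrap_variant: str = "refit"
    exclude_components: Sequence[str] = ()
    exclude_negative_totals: bool = False
    subgroup_post_covid: bool = False
    seed: int = 0

    def cost_spec(self) -> ModelSpec:
        return ModelSpec(outcome="total_cost_followup",
                         covariates=tuple(self.cost_covariates),
                         family=self.cost_family, link=self.cost_link)

    def qaly_spec(self) -> ModelSpec:
        return ModelSpec(outcome="qalys", covariates=tuple(self.qaly_covariates),
                         family="gaussian", link="identity")


def prepare_analysis_frame(data: TrialDataset, config: PipelineConfig) -> pd.DataFrame:
    """Participant table joined with per-participant costs and QALYs.

    Adds ``arm_int`` (1 = intervention), per-item cost columns, totals,
    utility columns and ``qalys``; missing items leave totals/QALYs NaN for
    the imputation stage to resolve.
    """
    df = data.participants.copy()
    df["arm_int"] = (df["arm"] == "intervention").astype(int)

    iv_spec = config.intervention_cost
    if iv_spec is None:
        iv_spec = default_intervention_spec(int((df["arm_int"] == 1).sum()) or 1)

    costs = cost_dataset(data, config.unit_costs, iv_spec,
                         horizon_days=config.horizon_days,
                         exclude_components=tuple(config.exclude_components))
    qalys = qaly_dataset(df, value_set=config.value_set,
                         rule=config.death_rule,
                         horizon_years=config.horizon_years)
    out = df.merge(costs.drop(columns=["participant_id"]),
                   left_index=True, right_index=True)
    out = out.merge(qalys.drop(columns=["participant_id"]),
                    left_index=True, right_index=True)
    # analysis uses index-scored utilities regardless of input coding
    out["eq5d_baseline"] = qalys["u_baseline"].to_numpy()
    out["eq5d_followup"] = qalys["u_followup"].to_numpy()
    if config.subgroup_post_covid:
        out = out[out["followup_after_covid"] == 1].reset_index(drop=True)
    if config.exclude_negative_totals:
        out = out[~(out["total_cost_followup"] < 0)].reset_index(drop=True)
    return out


def _default_targets(config: PipelineConfig) -> List[str]:
    targets = [f"cost_{item}_{period}" for period in ("baseline", "followup")
               for item in SERVICE_ITEMS]
    targets += ["eq5d_baseline", "eq5d_followup"]
    return targets


def _recompute_derived(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Re-derive totals and QALYs from (possibly imputed) item costs and
    utilities: imputed items are summed into the imputed total."""
    out = df.copy()
    service_b = sum(out[f"cost_{item}_baseline"] for item in SERVICE_ITEMS)
    service_f = sum(out[f"cost_{item}_followup"] for item in SERVICE_ITEMS)
    out["service_cost_baseline"] = service_b
    out["service_cost_followup"] = service_f
    out["total_cost_baseline"] = service_b
    out["total_cost_followup"] = (service_f + out["intervention_cost"]
                                  + out["cost_started"] - out["cost_stopped"])
    h = config.horizon_years
    died = out["died"].to_numpy(bool)
    u1 = np.where(died, 0.0, out["eq5d_followup"].to_numpy(float))
    if config.death_rule == "midpoint":
        out["qalys"] = np.where(died, (h / 2.0) * out["eq5d_baseline"] / 2.0,
                                h * (out["eq5d_baseline"] + u1) / 2.0)
    elif config.death_rule == "exclude":
        out["qalys"] = np.where(died, np.nan,
                                h * (out["eq5d_baseline"] + u1) / 2.0)
    else:
        out["qalys"] = h * (out["eq5d_baseline"] + u1) / 2.0
    return out


def impute(frame: pd.DataFrame, config: PipelineConfig) -> MICollection:
    """PMM-impute item costs and utilities, then recompute the derived
    totals and QALYs in every completed dataset."""
    targets = list(config.imputation_targets
                   if config.imputation_targets is not None
                   else _default_targets(config))
    predictors = tuple(config.imputation_predictors
                       if config.imputation_predictors is not None
                       else ("age", "sex", "arm_int", "n_baseline_medications",
                             "private_insurance", "medical_card", "cluster_id"))
    spec = ImputationSpec(targets=targets, m=config.m_imputations,
                          knn=config.knn, predictors=predictors,
                          seed=config.seed)
    mi = pmm_impute(frame, spec)
    mi.datasets = [_recompute_derived(d, config) for d in mi.datasets]
    return mi


@dataclass
class PipelineResult:
    """Report bundle of a full run."""

    frame: pd.DataFrame
    mi: MICollection
    descriptives: pd.DataFrame
    cc_cost: Optional[IncrementalEstimate]
    cc_qaly: Optional[IncrementalEstimate]
    mi_cost: IncrementalEstimate
    mi_qaly: IncrementalEstimate
    inb: Dict[float, IncrementalEstimate]
    ceacs: Dict[str, cea_mod.CEACResult]
    dominance: cea_mod.Dominance
    manifest: dict

    def incremental_table(self) -> pd.DataFrame:
        rows = []
        for label, est in (("cost_complete_case", self.cc_cost),
                           ("cost_multiple_imputation", self.mi_cost),
                           ("qaly_complete_case", self.cc_qaly),
                           ("qaly_multiple_imputation", self.mi_qaly)):
            if est is None:
                continue
            rows.append({"analysis": label, **est.as_dict()})
        for lam, est in self.inb.items():
            rows.append({"analysis": f"inb_{int(lam)}", **est.as_dict()})
        return pd.DataFrame(rows)

    def ceac_table(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.ceacs.values()],
                         ignore_index=True)

    def write_bundle(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.descriptives.to_csv(directory / "descriptive_table.csv", index=False)
        self.incremental_table().to_csv(directory / "incremental_results.csv",
                                        index=False)
        self.ceac_table().to_csv(directory / "ceac_table.csv", index=False)
        cea_mod.plot_ceac(list(self.ceacs.values()), directory / "ceac.png")
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str))


def descriptive_table(frame: pd.DataFrame,
                      horizon_years: float = 0.5) -> pd.DataFrame:
    """Mean (SD) usage and cost per item, per arm and period, plus totals,
    utilities, QALYs and percent missing — the descriptive layout of a
    within-trial evaluation report."""
    rows = []

    def add(arm: str, period: str, item: str, usage, cost):
        usage = pd.Series(usage, dtype=float)
        cost = pd.Series(cost, dtype=float) if cost is not None else None
        rows.append({
            "arm": arm, "period": period, "item": item,
            "usage_mean": usage.mean(), "usage_sd": usage.std(),
            "cost_mean": cost.mean() if cost is not None else np.nan,
            "cost_sd": cost.std() if cost is not None else np.nan,
            "pct_missing": 100.0 * usage.isna().mean(),
        })

    for arm in ("intervention", "control"):
        sub = frame[frame["arm"] == arm]
        for period in ("baseline", "followup"):
            for item in SERVICE_ITEMS:
                add(arm, period, item, sub[f"{item}_{period}"],
                    sub[f"cost_{item}_{period}"])
            add(arm, period, "total_cost", sub[f"total_cost_{period}"],
                sub[f"total_cost_{period}"])
            add(arm, period, "eq5d_index", sub[f"eq5d_{period}"], None)
        add(arm, "followup", "medication_started", sub["cost_started"],
            sub["cost_started"])
        add(arm, "followup", "medication_stopped", sub["cost_stopped"],
            sub["cost_stopped"])
        add(arm, "followup", "intervention_cost", sub["intervention_cost"],
            sub["intervention_cost"])
        add(arm, "followup", "qalys", sub["qalys"], None)
    return pd.DataFrame(rows)


def run_pipeline(data: TrialDataset | SimConfig,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Execute the full evaluation and return the report bundle.

    Accepts a :class:`TrialDataset` or a :class:`SimConfig` (simulated and
    MAR-masked first). Complete-case and multiple-imputation estimates are
    both produced; net-benefit and CEAC analysis uses the imputed data.
    """
    config = config or PipelineConfig()
    if isinstance(data, SimConfig):
        from .synthetic import apply_missingness
        data = apply_missingness(simulate_trial(data), data)

    frame = prepare_analysis_frame(data, config)
    mi = impute(frame, config)

    cost_spec = config.cost_spec()
    qaly_spec = config.qaly_spec()

    def _safe_cc(spec):
        try:
            return incremental_estimate(frame, spec)
        except (RuntimeError, ValueError):
            return None

    cc_cost = _safe_cc(cost_spec)
    cc_qaly = _safe_cc(qaly_spec)
    mi_cost = mi_estimate(mi, cost_spec)
    mi_qaly = mi_estimate(mi, qaly_spec)

    inb = {float(lam): cea_mod.inb_mi(mi, lam,
                                      covariates=tuple(config.inb_covariates))
           for lam in config.key_thresholds}

    ceacs: Dict[str, cea_mod.CEACResult] = {}
    if "two_stage_bootstrap" in config.methods:
        ceacs["two_stage_bootstrap"] = cea_mod.two_stage_bootstrap(
            mi, cost_spec, qaly_spec, lambda_grid=config.lambda_grid,
            b=config.b_bootstrap, seed=config.seed,
            variant=config.bootstrap_variant)
    if "parametric" in config.methods:
        inb_grid = {float(lam): cea_mod.inb_mi(
            mi, float(lam), covariates=tuple(config.inb_covariates))
            for lam in config.lambda_grid}
        ceacs["parametric"] = cea_mod.parametric_ceac(inb_grid)
    if "monte_carlo" in config.methods:
        ceacs["monte_carlo"] = cea_mod.monte_carlo_ceac(
            mi_cost.delta, mi_cost.se, mi_qaly.delta, mi_qaly.se,
            lambda_grid=config.lambda_grid, n_sims=config.n_monte_carlo,
            seed=config.seed)

    manifest = {
        "seed": config.seed,
        "m_imputations": config.m_imputations,
        "knn": config.knn,
        "b_bootstrap": config.b_bootstrap,
        "n_monte_carlo": config.n_monte_carlo,
        "horizon_days": config.horizon_days,
        "horizon_years": config.horizon_years,
        "death_rule": config.death_rule,
        "cost_model": dataclasses.asdict(cost_spec),
        "qaly_model": dataclasses.asdict(qaly_spec),
        "lambda_grid": list(map(float, config.lambda_grid)),
        "n_participants": int(len(frame)),
        "n_clusters": int(frame["cluster_id"].nunique()),
        "python": platform.python_version(),
        "versions": _versions(),
    }
    if isinstance(data, TrialDataset) and data.config is not None:
        manifest["generator"] = dataclasses.asdict(data.config)

    return PipelineResult(frame=frame, mi=mi,
                          descriptives=descriptive_table(frame,
                                                         config.horizon_years),
                          cc_cost=cc_cost, cc_qaly=cc_qaly,
                          mi_cost=mi_cost, mi_qaly=mi_qaly, inb=inb,
                          ceacs=ceacs,
                          dominance=cea_mod.classify_dominance(mi_cost.delta,
                                                               mi_qaly.delta),
                          manifest=manifest)


def _versions() -> dict:
    import numpy, scipy, pandas, statsmodels
    return {"numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "statsmodels": statsmodels.__version__}
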