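"""Multiple imputation by predictive mean matching (PMM) and Rubin pooling.

Item-level resource costs and EQ-5D-5L index scores are imputed
independently, one target variable at a time (single pass, fixed order —
not full chained equations): a linear imputation model on the complete
cases yields predicted means for every row, each missing row borrows the
observed value of one of the ``knn`` complete cases with the closest
predicted mean, and the whole procedure is repeated M times with distinct
sub-seeds. The cluster (practice) identifier enters the imputation model as
fixed-effect indicators so the imputation reflects the multilevel design;
this is a pragmatic choice with known caveats in small clusters.

Two matching variants are available: ``"bootstrap"`` (default) refits the
imputation model on a bootstrap resample of the complete cases in every
imputation, propagating model uncertainty into the donor ranking;
``"plain"`` keeps the single complete-case fit, so only the donor draw
varies across imputations.

Pooling across the M completed datasets follows Rubin's rules: the pooled
point estimate is the mean of the per-dataset estimates, the total variance
is the within-imputation mean plus (1 + 1/M) times the between-imputation
variance, with the standard small-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImputationSpec",
    "MICollection",
    "PooledEstimate",
    "pmm_impute",
    "rubin_pool",
    "DEFAULT_PREDICTORS",
]

DEFAULT_PREDICTORS = ("age", "sex", "arm_int", "n_baseline_medications",
                      "private_insurance", "medical_card", "cluster_id")


@dataclass
class ImputationSpec:
    """PMM configuration: M completed datasets, knn donors, predictor set
    (``cluster_id`` expands to fixed-effect indicators), targets, seed."""

    targets: Sequence[str]
    m: int = 10
    knn: int = 5
    predictors: Sequence[str] = DEFAULT_PREDICTORS
    seed: int = 0
    matching: str = "bootstrap"  # "bootstrap" | "plain"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("M must be >= 2")
        if self.knn < 1:
            raise ValueError("knn must be >= 1")
        if self.matching not in ("bootstrap", "plain"):
            raise ValueError("matching must be 'bootstrap' or 'plain'")
        if len(self.targets) == 0:
            raise ValueError("at least one imputation target is required")


@dataclass
class MICollection:
    """M completed copies of the analysis table plus an imputation log.

    Observed cells are identical across copies; imputed cells always hold
    observed donor values of the same variable.
    """

    datasets: List[pd.DataFrame]
    spec: ImputationSpec
    log: Dict[str, dict] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def write(self, directory, prefix: str = "imputed") -> None:
        from pathlib import Path
        import json
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets, start=1):
            df.to_csv(directory / f"{prefix}_{i:02d}.csv", index=False)
        manifest = {"m": self.m, "knn": self.spec.knn, "seed": self.spec.seed,
                    "matching": self.spec.matching,
                    "targets": list(self.spec.targets),
                    "predictors": list(self.spec.predictors),
                    "log": self.log}
        (directory / f"{prefix}_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))


def _design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    """Intercept + numeric predictors, with cluster_id expanded to
    indicator columns (first cluster as reference)."""
    cols = [np.ones(len(df))]
    for p in predictors:
        if p == "cluster_id":
            dummies = pd.get_dummies(df["cluster_id"], drop_first=True)
            cols.extend(dummies[c].to_numpy(float) for c in dummies.columns)
        else:
            cols.append(df[p].to_numpy(float))
    return np.column_stack(cols)


def _fit_predict(X_fit: np.ndarray, y_fit: np.ndarray,
                 X_all: np.ndarray, target: str,
                 log: dict) -> np.ndarray:
    """Least-squares fit with rank-deficiency tolerated (minimum-norm
    solution; logged as dropped directions)."""
    beta, _, rank, _ = np.linalg.lstsq(X_fit, y_fit, rcond=None)
    if rank < X_fit.shape[1]:
        # bootstrap refits routinely lose a cluster indicator or two; the
        # minimum-norm solution absorbs the dropped directions (logged)
        log["rank_deficient_fits"] = log.get("rank_deficient_fits", 0) + 1
    return X_all @ beta


def pmm_impute(data: pd.DataFrame, spec: ImputationSpec) -> MICollection:
    """Impute every target by predictive mean matching, M times.

    Requires at least ``knn`` complete cases per target and complete
    predictors. Returns an :class:`MICollection`; when nothing is missing
    the M copies equal the input.
    """
    df = data.reset_index(drop=True)
    for p in spec.predictors:
        if df[p].isna().any():
            raise ValueError(f"predictor {p!r} has missing values")

    X_all = _design_matrix(df, spec.predictors)
    # in a cluster-randomised design the arm indicator is spanned by the
    # cluster indicators; that deficiency is structural and expected
    structural = 1 if ("cluster_id" in spec.predictors
                       and any(p in spec.predictors
                               for p in ("arm_int", "arm"))) else 0
    if np.linalg.matrix_rank(X_all) < X_all.shape[1] - structural:
        warnings.warn("collinear imputation predictor matrix; redundant "
                      "directions will be dropped (minimum-norm fits)",
                      stacklevel=2)

    log: Dict[str, dict] = {}
    target_info = {}
    for target in spec.targets:
        y = df[target].to_numpy(float)
        obs = ~np.isnan(y)
        n_missing = int((~obs).sum())
        if n_missing and obs.sum() < spec.knn:
            raise ValueError(
                f"target {target!r} has only {int(obs.sum())} complete cases, "
                f"fewer than knn={spec.knn}")
        target_info[target] = (y, obs)
        log[target] = {"n_missing": n_missing, "n_complete": int(obs.sum()),
                       "knn": spec.knn}

    datasets = []
    for m_idx in range(spec.m):
        completed = df.copy()
        for target in spec.targets:
            y, obs = target_info[target]
            if obs.all():
                continue
            # independent, name-keyed substream per (imputation, target):
            # one target's missingness pattern never perturbs another's draws
            rng = np.random.default_rng(np.random.SeedSequence(
                [spec.seed, 2077, m_idx, zlib.crc32(target.encode())]))
            obs_idx = np.flatnonzero(obs)
            if spec.matching == "bootstrap":
                boot = rng.choice(obs_idx, size=len(obs_idx), replace=True)
                yhat = _fit_predict(X_all[boot], y[boot], X_all, target,
                                    log[target])
            else:
                yhat = _fit_predict(X_all[obs_idx], y[obs_idx], X_all, target,
                                    log[target])
            yhat_obs = yhat[obs_idx]
            filled = y.copy()
            for i in np.flatnonzero(~obs):
                d = np.abs(yhat_obs - yhat[i])
                pool = obs_idx[np.argsort(d, kind="stable")[:spec.knn]]
                donor = pool[rng.integers(0, len(pool))]
                filled[i] = y[donor]
            completed[target] = filled
        datasets.append(completed)

    return MICollection(datasets=datasets, spec=spec, log=log)


@dataclass
class PooledEstimate:
    """Rubin-pooled scalar estimate across M imputations."""

    estimate: float
    variance: float  # total: within + (1 + 1/M) * between
    df: float
    within: float
    between: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def rubin_pool(estimates: Sequence[float],
               variances: Sequence[float]) -> PooledEstimate:
    """Combine per-imputation estimates and variances by Rubin's rules.

    pooled = mean(estimates); total variance = W + (1 + 1/M) B with W the
    mean within-imputation variance and B the between-imputation sample
    variance; df = (M − 1)(1 + W / ((1 + 1/M) B))², infinite when B = 0.
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs M >= 2")
    if (w < 0).any():
        raise ValueError("variances must be >= 0")
    pooled = float(q.mean())
    between = float(q.var(ddof=1))
    within = float(w.mean())
    total = within + (1.0 + 1.0 / m) * between
    if between > 0:
        df = (m - 1) * (1.0 + within / ((1.0 + 1.0 / m) * between)) ** 2
    else:
        df = np.inf
    return PooledEstimate(estimate=pooled, variance=total, df=float(df),
                          within=within, between=between, m=m)
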