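"""Cluster-adjusted marginal models and incremental estimates.

Total cost and QALYs are analysed with generalized estimating equations:
an exchangeable working correlation over practice clusters, a gamma
(cost) or gaussian (QALY) variance function, and an identity link by
default, controlling for treatment arm and the baseline analogue of the
outcome. Robust (sandwich) standard errors account for clustering.
Adjusted per-arm means come from recycled predictions (marginal
standardisation): every participant is predicted under each arm assignment
and the predictions averaged; under the identity link the adjusted
difference equals the arm coefficient exactly.

Totals can be negative (stopped-medication savings), which the textbook
gamma variance V(mu) = mu^2 tolerates but a fitted mean near zero does
not; the variance is therefore evaluated at max(|mu|, eps)^2.

Across multiply imputed datasets, the arm contrast and the adjusted means
are pooled by Rubin's rules with t-based inference on the Rubin degrees of
freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.genmod.families import varfuncs
from statsmodels.tools.sm_exceptions import DomainWarning, IterationLimitWarning

from .imputation import MICollection, rubin_pool

__all__ = [
    "ModelSpec",
    "FittedModel",
    "AdjustedMeans",
    "IncrementalEstimate",
    "fit_marginal_model",
    "recycled_predictions",
    "incremental_estimate",
    "mi_estimate",
]

_VAR_EPS = 1e-6


class _GuardedMuSquared(varfuncs.VarianceFunction):
    """Gamma variance evaluated at max(|mu|, eps) so fitted means at or
    below zero do not break the estimating equations."""

    def __call__(self, mu):
        return np.maximum(np.abs(mu), _VAR_EPS) ** 2

    def deriv(self, mu):
        return 2.0 * np.sign(mu) * np.maximum(np.abs(mu), _VAR_EPS)


def _make_family(family: str, link: str):
    links = {
        "identity": sm.families.links.Identity(),
        "log": sm.families.links.Log(),
        "power1.5": sm.families.links.Power(power=1.5),
    }
    if link not in links:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(links)}")
    if family == "gaussian":
        return sm.families.Gaussian(link=links[link])
    if family == "gamma":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DomainWarning)
            fam = sm.families.Gamma(link=links[link])
        fam.variance = _GuardedMuSquared()
        return fam
    raise ValueError(f"unknown variance family {family!r}")


@dataclass
class ModelSpec:
    """Marginal model specification for one outcome."""

    outcome: str
    covariates: Sequence[str] = ("arm_int",)
    family: str = "gaussian"  # "gamma" | "gaussian"
    link: str = "identity"    # "identity" | "log" | "power1.5"
    cluster: str = "cluster_id"
    arm: str = "arm_int"
    bias_reduced_cov: bool = False  # small-sample sandwich correction, off by default

    def __post_init__(self) -> None:
        if self.arm not in self.covariates:
            raise ValueError("the arm indicator must be among the covariates")
        _make_family(self.family, self.link)  # validate the pair eagerly


@dataclass
class FittedModel:
    """Fitted GEE with its design bookkeeping."""

    spec: ModelSpec
    params: np.ndarray
    cov: np.ndarray            # cluster-robust (sandwich) covariance
    colnames: List[str]
    results: object            # statsmodels GEEResults
    n: int
    n_clusters: int
    qic: Optional[float]

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        X = _design(df, self.spec)
        return self._inverse_link(X @ self.params)

    def _inverse_link(self, eta: np.ndarray) -> np.ndarray:
        return self.results.model.family.link.inverse(eta)


def _design(df: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    cols = [np.ones(len(df))]
    cols.extend(df[c].to_numpy(float) for c in spec.covariates)
    return np.column_stack(cols)


def fit_marginal_model(df: pd.DataFrame, spec: ModelSpec,
                       maxiter: int = 100) -> FittedModel:
    """Fit the exchangeable-correlation GEE on complete rows of the
    outcome and covariates; raises on non-convergence."""
    needed = [spec.outcome, *spec.covariates, spec.cluster]
    work = df[needed].dropna()
    n_clusters_per_arm = work.groupby(spec.arm)[spec.cluster].nunique()
    if len(n_clusters_per_arm) < 2 or (n_clusters_per_arm < 2).any():
        raise ValueError("need at least 2 clusters in each arm")

    y = work[spec.outcome].to_numpy(float)
    X = _design(work, spec)
    groups = work[spec.cluster].to_numpy()
    family = _make_family(spec.family, spec.link)
    cov_type = "bias_reduced" if spec.bias_reduced_cov else "robust"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # near-tolerance oscillation of the estimating equations is benign
        # as long as the coefficients are finite; checked below
        warnings.simplefilter("ignore", IterationLimitWarning)
        model = sm.GEE(y, X, groups=groups, family=family,
                       cov_struct=sm.cov_struct.Exchangeable())
        try:
            res = model.fit(maxiter=maxiter, cov_type=cov_type)
        except Exception as exc:  # singular designs, failed irls, ...
            raise RuntimeError(
                f"GEE fit failed for outcome {spec.outcome!r}: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(f"GEE fit for {spec.outcome!r} did not converge "
                           f"(non-finite coefficients)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qic = float(res.qic()[0])
    except Exception:
        qic = None  # undefined e.g. for gamma with negative outcomes
    return FittedModel(spec=spec, params=params,
                       cov=np.asarray(res.cov_params(), dtype=float),
                       colnames=["const", *spec.covariates], results=res,
                       n=len(work), n_clusters=work[spec.cluster].nunique(),
                       qic=qic)


@dataclass
class AdjustedMeans:
    """Recycled-prediction arm means and their contrast with delta-method
    robust variances."""

    mean_intervention: float
    var_intervention: float
    mean_control: float
    var_control: float
    diff: float
    var_diff: float


def _mean_and_gradient(fit: FittedModel, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Average prediction over the rows of X and its gradient wrt the
    coefficients (analytic for identity, finite differences otherwise)."""
    link = fit.results.model.family.link
    beta = fit.params
    mean = float(link.inverse(X @ beta).mean())
    if fit.spec.link == "identity":
        grad = X.mean(axis=0)
    else:
        grad = np.empty_like(beta)
        for j in range(len(beta)):
            h = 1e-6 * max(1.0, abs(beta[j]))
            bp = beta.copy(); bp[j] += h
            bm = beta.copy(); bm[j] -= h
            grad[j] = (link.inverse(X @ bp).mean()
                       - link.inverse(X @ bm).mean()) / (2 * h)
    return mean, grad


def recycled_predictions(fit: FittedModel, df: pd.DataFrame) -> AdjustedMeans:
    """Adjusted arm means by marginal standardisation: predict every row
    with arm set to 1, then to 0, and average; the contrast equals the arm
    coefficient exactly under the identity link."""
    spec = fit.spec
    work = df[[spec.outcome, *spec.covariates, spec.cluster]].dropna()
    arm_pos = 1 + list(spec.covariates).index(spec.arm)  # after intercept

    X1 = _design(work, spec); X1[:, arm_pos] = 1.0
    X0 = _design(work, spec); X0[:, arm_pos] = 0.0
    m1, g1 = _mean_and_gradient(fit, X1)
    m0, g0 = _mean_and_gradient(fit, X0)
    gd = g1 - g0
    return AdjustedMeans(
        mean_intervention=m1, var_intervention=float(g1 @ fit.cov @ g1),
        mean_control=m0, var_control=float(g0 @ fit.cov @ g0),
        diff=m1 - m0, var_diff=float(gd @ fit.cov @ gd),
    )


@dataclass
class IncrementalEstimate:
    """Adjusted between-arm difference with robust uncertainty and the
    per-arm adjusted means behind it."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    mean_intervention: float
    mean_intervention_ci: tuple
    mean_control: float
    mean_control_ci: tuple
    n: int
    qic: Optional[float] = None
    n_imputations: int = 1
    df: float = np.inf

    def as_dict(self) -> dict:
        return {"delta": self.delta, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p": self.p,
                "mean_intervention": self.mean_intervention,
                "mean_control": self.mean_control, "n": self.n,
                "qic": self.qic, "n_imputations": self.n_imputations}


def _wald(est: float, var: float, df: float = np.inf) -> tuple:
    se = float(np.sqrt(max(var, 0.0)))
    dist = stats.t(df) if np.isfinite(df) else stats.norm
    crit = dist.ppf(0.975)
    if se > 0:
        p = 2.0 * dist.sf(abs(est) / se)
    else:
        p = 0.0 if est != 0 else 1.0
    return se, est - crit * se, est + crit * se, float(p)


def incremental_estimate(df: pd.DataFrame, spec: ModelSpec) -> IncrementalEstimate:
    """Complete-case incremental estimate: GEE fit, recycled predictions,
    Wald 95% interval on the robust SE."""
    fit = fit_marginal_model(df, spec)
    adj = recycled_predictions(fit, df)
    se, lo, hi, p = _wald(adj.diff, adj.var_diff)
    _, lo1, hi1, _ = _wald(adj.mean_intervention, adj.var_intervention)
    _, lo0, hi0, _ = _wald(adj.mean_control, adj.var_control)
    return IncrementalEstimate(
        delta=adj.diff, se=se, ci_low=lo, ci_high=hi, p=p,
        mean_intervention=adj.mean_intervention, mean_intervention_ci=(lo1, hi1),
        mean_control=adj.mean_control, mean_control_ci=(lo0, hi0),
        n=fit.n, qic=fit.qic)


def mi_estimate(mi: MICollection, spec: ModelSpec) -> IncrementalEstimate:
    """Rubin-pooled incremental estimate across the M completed datasets;
    a per-dataset failure is reported with its imputation index."""
    diffs, vdiffs = [], []
    m1s, v1s, m0s, v0s = [], [], [], []
    n = 0
    qic = None
    for idx, completed in enumerate(mi.datasets, start=1):
        try:
            fit = fit_marginal_model(completed, spec)
            adj = recycled_predictions(fit, completed)
        except Exception as exc:
            raise RuntimeError(f"model fit failed on imputed dataset "
                               f"{idx}/{mi.m}: {exc}") from exc
        diffs.append(adj.diff); vdiffs.append(adj.var_diff)
        m1s.append(adj.mean_intervention); v1s.append(adj.var_intervention)
        m0s.append(adj.mean_control); v0s.append(adj.var_control)
        n = fit.n
        qic = fit.qic if qic is None else qic
    pooled = rubin_pool(diffs, vdiffs)
    se, lo, hi, p = _wald(pooled.estimate, pooled.variance, pooled.df)
    p1 = rubin_pool(m1s, v1s)
    p0 = rubin_pool(m0s, v0s)
    _, lo1, hi1, _ = _wald(p1.estimate, p1.variance, p1.df)
    _, lo0, hi0, _ = _wald(p0.estimate, p0.variance, p0.df)
    return IncrementalEstimate(
        delta=pooled.estimate, se=se, ci_low=lo, ci_high=hi, p=p,
        mean_intervention=p1.estimate, mean_intervention_ci=(lo1, hi1),
        mean_control=p0.estimate, mean_control_ci=(lo0, hi0),
        n=n, qic=qic, n_imputations=mi.m, df=pooled.df)
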