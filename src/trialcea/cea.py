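"""Net benefit, incremental net benefit, dominance, and CEACs.

The net-benefit framework folds a participant's cost c and effect e
(QALYs) into a single variable at a willingness-to-pay threshold λ,
nb = e·λ − c, so the intervention is cost-effective at λ exactly when the
incremental net benefit (INB, the adjusted arm difference in nb) exceeds
zero. The INB is estimated by a gaussian/identity GEE controlling for
treatment arm and clustering.

Cost-effectiveness acceptability curves (probability of cost-effectiveness
against λ) are produced by three methods:

* two-stage non-parametric bootstrap (default, respects clustering and the
  cost–effect correlation): resample clusters with replacement within each
  arm, then participants with replacement within each sampled cluster,
  refit the cost and QALY models and record the recycled-prediction
  contrasts (ΔĈ_b, ΔQ̂_b); the probability at λ is the fraction of
  replicates with ΔQ̂_b·λ − ΔĈ_b > 0. Across M imputed datasets the B
  replicates are allocated as evenly as possible and the draws stacked.
* parametric: Φ(INB/SE) from the net-benefit regression at each λ.
* Monte Carlo: normal draws around (ΔĈ, ΔQ̂) (independent by default,
  optional correlation), probability as the fraction of draws with
  positive incremental net benefit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (FittedModel, IncrementalEstimate, ModelSpec,
                         fit_marginal_model, incremental_estimate,
                         mi_estimate, recycled_predictions)
from .imputation import MICollection

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "CEACResult",
    "net_benefit",
    "inb_regression",
    "inb_mi",
    "two_stage_bootstrap",
    "parametric_ceac",
    "monte_carlo_ceac",
    "classify_dominance",
    "Dominance",
    "plot_ceac",
]

#: €0–€100,000 in €10,000 steps plus the €45,000 upper Irish reference value.
DEFAULT_LAMBDA_GRID = (0, 10_000, 20_000, 30_000, 40_000, 45_000,
                       50_000, 60_000, 70_000, 80_000, 90_000, 100_000)


def net_benefit(e, c, lam: float):
    """Per-participant net benefit e·λ − c (vectorised)."""
    return np.asarray(e, dtype=float) * lam - np.asarray(c, dtype=float)


def _with_nb(df: pd.DataFrame, lam: float, qaly_col: str,
             cost_col: str) -> pd.DataFrame:
    out = df.copy()
    out["nb"] = net_benefit(out[qaly_col], out[cost_col], lam)
    return out


def inb_regression(df: pd.DataFrame, lam: float, qaly_col: str = "qalys",
                   cost_col: str = "total_cost_followup",
                   covariates: Sequence[str] = ("arm_int",),
                   cluster: str = "cluster_id") -> IncrementalEstimate:
    """Incremental net benefit at λ: gaussian/identity GEE on nb,
    controlling for treatment arm and clustering."""
    spec = ModelSpec(outcome="nb", covariates=tuple(covariates),
                     family="gaussian", link="identity", cluster=cluster)
    return incremental_estimate(_with_nb(df, lam, qaly_col, cost_col), spec)


def inb_mi(mi: MICollection, lam: float, qaly_col: str = "qalys",
           cost_col: str = "total_cost_followup",
           covariates: Sequence[str] = ("arm_int",),
           cluster: str = "cluster_id") -> IncrementalEstimate:
    """Rubin-pooled INB at λ across imputed datasets."""
    spec = ModelSpec(outcome="nb", covariates=tuple(covariates),
                     family="gaussian", link="identity", cluster=cluster)
    nb_mi = MICollection(
        datasets=[_with_nb(d, lam, qaly_col, cost_col) for d in mi.datasets],
        spec=mi.spec, log=mi.log)
    return mi_estimate(nb_mi, spec)


@dataclass
class CEACResult:
    """Per-threshold probability that the intervention is cost-effective."""

    method: str
    grid: np.ndarray
    probabilities: np.ndarray
    n_draws: int
    seed: Optional[int] = None
    delta_cost_draws: Optional[np.ndarray] = None
    delta_qaly_draws: Optional[np.ndarray] = None
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("threshold grid must be strictly increasing")
        if ((self.probabilities < 0) | (self.probabilities > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def probability_at(self, lam: float) -> float:
        i = np.where(np.isclose(self.grid, lam))[0]
        if len(i) == 0:
            raise KeyError(f"threshold {lam} not on the grid")
        return float(self.probabilities[i[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"method": self.method, "lambda": self.grid,
                             "probability": self.probabilities})


def _ceac_from_draws(dc: np.ndarray, dq: np.ndarray,
                     grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    return np.array([(dq * lam - dc > 0).mean() for lam in grid])


def _shrinkage_offsets(df: pd.DataFrame, outcomes: Sequence[str],
                       cluster_rows: Dict, arm_clusters: Dict) -> Dict:
    """Per-cluster additive offsets implementing the shrinkage correction.

    Resampling clusters *and* members both with replacement double-counts
    the within-cluster variance of an arm mean: the variance of a drawn
    cluster's resampled mean is S_b^2 + vbar (between-cluster variance of
    cluster means plus the mean conditional within-resampling variance)
    where the cluster-only bootstrap — the design-consistent reference —
    gives S_b^2 alone. Deflating each cluster's mean deviation by
    c = sqrt(max(0, 1 - vbar/S_b^2)) restores the match, per arm and per
    outcome variable. The offset for cluster j is (c - 1)(ybar_j - ybar),
    added to every resampled member's outcome.
    """
    offsets: Dict[str, Dict] = {var: {} for var in outcomes}
    for var in outcomes:
        y = df[var].to_numpy(float)
        for arm, clusters in arm_clusters.items():
            means = np.array([np.nanmean(y[cluster_rows[c]]) for c in clusters])
            sizes = np.array([len(cluster_rows[c]) for c in clusters])
            center = means.mean()
            s_b2 = means.var(ddof=1) if len(means) > 1 else 0.0
            v = []
            for c, m in zip(clusters, sizes):
                vals = y[cluster_rows[c]]
                v.append(0.0 if m < 2
                         else np.nanvar(vals, ddof=1) * (m - 1) / m ** 2)
            vbar = float(np.mean(v))
            c_shrink = (np.sqrt(max(0.0, 1.0 - vbar / s_b2))
                        if s_b2 > 0 else 1.0)
            for cl, mu in zip(clusters, means):
                offsets[var][cl] = (c_shrink - 1.0) * (mu - center)
    return offsets


def _resample_two_stage(rng: np.random.Generator, df: pd.DataFrame,
                        cluster_rows: Dict, arm_clusters: Dict,
                        offsets: Optional[Dict] = None) -> pd.DataFrame:
    """One two-stage resample: clusters with replacement within arm (arm
    cluster counts preserved), then participants with replacement within
    each drawn cluster to its original size; drawn clusters are relabelled
    so repeats count as distinct clusters. ``offsets`` applies the
    shrinkage correction to the outcome columns."""
    rows: List[np.ndarray] = []
    new_labels: List[np.ndarray] = []
    drawn_from: List[np.ndarray] = []
    label = 0
    for arm, clusters in arm_clusters.items():
        drawn = rng.choice(clusters, size=len(clusters), replace=True)
        for c in drawn:
            members = cluster_rows[c]
            take = members[rng.integers(0, len(members), size=len(members))]
            rows.append(take)
            new_labels.append(np.full(len(take), label))
            drawn_from.append(np.full(len(take), c))
            label += 1
    idx = np.concatenate(rows)
    out = df.iloc[idx].copy()
    out["cluster_id"] = np.concatenate(new_labels)
    if offsets:
        source = np.concatenate(drawn_from)
        for var, by_cluster in offsets.items():
            adj = np.array([by_cluster[c] for c in source])
            out[var] = out[var].to_numpy(float) + adj
    return out


def two_stage_bootstrap(mi: Union[MICollection, pd.DataFrame],
                        cost_spec: ModelSpec, qaly_spec: ModelSpec,
                        lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                        b: int = 2000, seed: int = 0,
                        variant: str = "refit", shrinkage: bool = True,
                        max_redraw_frac: float = 0.05) -> CEACResult:
    """Two-stage cluster bootstrap CEAC with shrinkage correction.

    ``variant="refit"`` (default) refits the cost and QALY GEE models on
    every replicate and records the recycled-prediction contrasts;
    ``variant="resample"`` records raw arm-mean differences of the
    resampled outcomes without refitting. ``shrinkage`` (default on)
    deflates cluster-mean deviations of the outcomes so the two stages do
    not double-count within-cluster variance; ``False`` gives the naive
    scheme. Non-convergent replicates are redrawn (counted; a warning is
    emitted past ``max_redraw_frac``).
    """
    if variant not in ("refit", "resample"):
        raise ValueError("variant must be 'refit' or 'resample'")
    datasets = mi.datasets if isinstance(mi, MICollection) else [mi]
    m = len(datasets)
    alloc = [b // m + (1 if i < b % m else 0) for i in range(m)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4242]))

    dc_draws: List[float] = []
    dq_draws: List[float] = []
    n_redrawn = 0
    for df, n_rep in zip(datasets, alloc):
        df = df.reset_index(drop=True)
        cluster_rows = {c: np.flatnonzero(df["cluster_id"].to_numpy() == c)
                        for c in df["cluster_id"].unique()}
        arm_of = df.groupby("cluster_id")[cost_spec.arm].first()
        arm_clusters = {a: arm_of.index[arm_of == a].to_numpy()
                        for a in sorted(arm_of.unique())}
        offsets = (_shrinkage_offsets(df, (cost_spec.outcome, qaly_spec.outcome),
                                      cluster_rows, arm_clusters)
                   if shrinkage else None)
        done = 0
        while done < n_rep:
            sample = _resample_two_stage(rng, df, cluster_rows, arm_clusters,
                                         offsets)
            try:
                if variant == "refit":
                    cfit = fit_marginal_model(sample, cost_spec)
                    dc = recycled_predictions(cfit, sample).diff
                    qfit = fit_marginal_model(sample, qaly_spec)
                    dq = recycled_predictions(qfit, sample).diff
                else:
                    g = sample.groupby(cost_spec.arm)
                    means_c = g[cost_spec.outcome].mean()
                    means_q = g[qaly_spec.outcome].mean()
                    dc = float(means_c[1] - means_c[0])
                    dq = float(means_q[1] - means_q[0])
            except (RuntimeError, ValueError):
                n_redrawn += 1
                if n_redrawn > max(10, int(np.ceil(b * 0.5))):
                    raise RuntimeError("two-stage bootstrap: too many "
                                       "non-convergent replicates")
                continue
            dc_draws.append(dc)
            dq_draws.append(dq)
            done += 1
    if n_redrawn > max_redraw_frac * b:
        warnings.warn(f"two-stage bootstrap redrew {n_redrawn} replicates "
                      f"(> {max_redraw_frac:.0%} of B={b})")

    dc_arr = np.asarray(dc_draws)
    dq_arr = np.asarray(dq_draws)
    return CEACResult(method="two_stage_bootstrap", grid=lambda_grid,
                      probabilities=_ceac_from_draws(dc_arr, dq_arr, lambda_grid),
                      n_draws=b, seed=seed, delta_cost_draws=dc_arr,
                      delta_qaly_draws=dq_arr, n_redrawn=n_redrawn)


def parametric_ceac(inb_by_lambda: Dict[float, IncrementalEstimate]) -> CEACResult:
    """Normal-approximation CEAC: Φ(INB/SE) at each λ; a zero SE gives a
    degenerate 0/1 probability by the sign of the INB."""
    grid = sorted(inb_by_lambda)
    probs = []
    for lam in grid:
        est = inb_by_lambda[lam]
        if est.se > 0:
            probs.append(float(stats.norm.cdf(est.delta / est.se)))
        else:
            probs.append(1.0 if est.delta > 0 else 0.0)
    return CEACResult(method="parametric", grid=np.asarray(grid, float),
                      probabilities=np.asarray(probs), n_draws=0)


def monte_carlo_ceac(delta_cost: float, se_cost: float,
                     delta_qaly: float, se_qaly: float,
                     lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                     n_sims: int = 2000, correlation: float = 0.0,
                     seed: int = 0) -> CEACResult:
    """CEAC from normal draws around the incremental cost and QALY
    estimates (independent by default; optional correlation)."""
    if se_cost < 0 or se_qaly < 0:
        raise ValueError("standard errors must be >= 0")
    if abs(correlation) > 1:
        raise ValueError("correlation must lie in [-1, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 515]))
    cov = np.array([[se_cost ** 2, correlation * se_cost * se_qaly],
                    [correlation * se_cost * se_qaly, se_qaly ** 2]])
    draws = rng.multivariate_normal([delta_cost, delta_qaly], cov,
                                    size=n_sims, method="cholesky"
                                    if np.linalg.det(cov) > 0 else "svd")
    dc, dq = draws[:, 0], draws[:, 1]
    return CEACResult(method="monte_carlo", grid=np.asarray(lambda_grid, float),
                      probabilities=_ceac_from_draws(dc, dq, lambda_grid),
                      n_draws=n_sims, seed=seed,
                      delta_cost_draws=dc, delta_qaly_draws=dq)


@dataclass
class Dominance:
    """Point-estimate cost-effectiveness classification."""

    status: str  # "dominant" | "dominated" | "icer" | "undefined"
    icer: Optional[float] = None

    def __str__(self) -> str:
        if self.status == "icer":
            return f"ICER €{self.icer:,.0f}/QALY"
        return self.status


def classify_dominance(delta_cost: float, delta_qaly: float) -> Dominance:
    """Dominant (cheaper, more effective), dominated (dearer, less
    effective), otherwise the ICER ΔC/ΔQ (undefined at ΔQ = 0)."""
    if delta_cost < 0 and delta_qaly > 0:
        return Dominance("dominant")
    if delta_cost > 0 and delta_qaly < 0:
        return Dominance("dominated")
    if delta_qaly == 0:
        return Dominance("undefined")
    return Dominance("icer", icer=delta_cost / delta_qaly)


def plot_ceac(results: Sequence[CEACResult], path=None):
    """CEAC plot (probability vs λ) for one or more methods."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        ax.plot(res.grid / 1000.0, res.probabilities, marker="o",
                label=res.method)
    ax.set_xlabel("Willingness to pay, €000 per QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    ax.grid(alpha=0.3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
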