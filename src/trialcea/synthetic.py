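"""Synthetic cluster-RCT generator for within-trial economic evaluation.

Emulates the statistical structure of a two-arm, practice-randomised trial
of a deprescribing intervention in older multimorbid patients: ~50 practice
clusters, ~400 participants, heavily right-skewed six-month healthcare costs
dominated by inpatient nights, EQ-5D-5L utilities bounded on the value-set
range, intra-cluster correlation on both scales, medication change lines,
deaths, and missing-at-random follow-up non-response.

The generator is calibrated so that the configured arm effects are *exact*
estimands of the downstream pipeline:

* service-item counts are derived from a latent gamma utilisation cost
  (multiplicative log-normal cluster frailty) split across items by fixed
  cost shares and converted to integers by randomised rounding, which
  preserves the expected priced cost exactly;
* follow-up utilities are truncated-normal draws whose location is
  numerically calibrated so the post-truncation mean equals the configured
  mean (an uncalibrated truncated draw would attenuate the configured
  effect);
* medication change lines are distributed identically in both arms, so the
  whole configured cost effect flows through the latent utilisation cost.

Every dataset retains a pre-missingness complete copy for oracle tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SERVICE_ITEMS",
    "DEFAULT_ITEM_SHARES",
    "SimConfig",
    "TrialDataset",
    "simulate_trial",
    "apply_missingness",
]

#: Resource-use items priced per unit, in pipeline column order.
SERVICE_ITEMS = (
    "gp_surgery",
    "gp_phone",
    "gp_house_call",
    "gp_out_of_hours",
    "gp_prescription",
    "practice_nurse",
    "outpatient",
    "inpatient_nights",
    "ed_visits",
)

# Share of mean six-month utilisation cost per item (inpatient nights
# dominate), used to split the latent utilisation cost into item costs.
DEFAULT_ITEM_SHARES = {
    "gp_surgery": 0.0733,
    "gp_phone": 0.0143,
    "gp_house_call": 0.0025,
    "gp_out_of_hours": 0.0048,
    "gp_prescription": 0.0409,
    "practice_nurse": 0.0234,
    "outpatient": 0.1200,
    "inpatient_nights": 0.6872,
    "ed_visits": 0.0336,
}

# Reference per-unit euro costs used to convert latent item costs to counts.
DEFAULT_UNIT_COSTS = {
    "gp_surgery": 53.0,
    "gp_phone": 53.0,
    "gp_house_call": 51.0,
    "gp_out_of_hours": 54.0,
    "gp_prescription": 53.0,
    "practice_nurse": 42.0,
    "outpatient": 175.0,
    "inpatient_nights": 987.0,
    "ed_visits": 308.0,
}


@dataclass
class SimConfig:
    """Configuration for one simulated cluster trial.

    Defaults emulate the reference trial's scale: 25–26 practices per arm of
    ~8 participants each, mean six-month utilisation cost around €3,800 with
    gamma shape ~0.3 (coefficient of variation ~1.8), baseline utility
    ~0.48 with SD 0.37 on the range [-0.974, 1], a utilisation-cost saving
    of €658 (≈ −€400 total effect once a ~€257 intervention delivery cost
    is added), a follow-up utility gain of 0.056 (0.014 QALYs over half a
    year), 43% follow-up utility missingness and ~12% cost-item
    missingness, and a ~5% death rate.
    """

    n_clusters_per_arm: int = 25
    cluster_size_mean: float = 8.0
    icc_cost: float = 0.05
    icc_utility: float = 0.05
    baseline_cost_mean: float = 3800.0
    cost_shape: float = 0.3
    true_delta_cost: float = -658.0
    baseline_utility_mean: float = 0.48
    utility_sd: float = 0.37
    true_delta_utility: float = 0.056
    missing_utility_rate: float = 0.43
    missing_cost_rate: float = 0.12
    mar_covariate_weight: float = 0.5
    death_rate: float = 0.052
    seed: int = 12345
    # distributional knobs beyond the headline parameters
    cost_distribution: str = "gamma"  # "gamma" | "gaussian"
    cost_frailty_sd: float = 0.5      # log-normal individual frailty (periods share it)
    utility_min: float = -0.974
    utility_followup_corr: float = 0.5
    covid_followup_rate: float = 0.26
    n_med_stopped_mean: float = 3.4
    n_med_started_mean: float = 2.8
    med_ingredient_cost_mean: float = 18.0
    med_ingredient_cost_shape: float = 0.7

    def __post_init__(self) -> None:
        if self.n_clusters_per_arm < 2:
            raise ValueError("n_clusters_per_arm must be >= 2")
        if self.cluster_size_mean <= 0:
            raise ValueError("cluster_size_mean must be positive")
        for name in ("missing_utility_rate", "missing_cost_rate", "death_rate",
                     "covid_followup_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("icc_cost", "icc_utility"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.cost_shape <= 0 or self.utility_sd <= 0:
            raise ValueError("cost_shape and utility_sd must be positive")
        if not (-1.0 <= self.utility_min < 1.0):
            raise ValueError("utility_min must lie in [-1, 1)")
        if not (self.utility_min < self.baseline_utility_mean < 1.0):
            raise ValueError("baseline_utility_mean must lie inside the utility range")
        if self.cost_distribution not in ("gamma", "gaussian"):
            raise ValueError("cost_distribution must be 'gamma' or 'gaussian'")


@dataclass
class TrialDataset:
    """Participant-level trial data: one row per participant plus a
    long-format medication change-line table keyed by participant_id.

    ``complete`` retains the pre-missingness participant table so simulation
    oracles can compare estimates with generator truth.
    """

    participants: pd.DataFrame
    med_changes: pd.DataFrame
    complete: Optional[pd.DataFrame] = None
    config: Optional[SimConfig] = None

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_clusters(self) -> int:
        return self.participants["cluster_id"].nunique()

    def write(self, directory: str | Path, prefix: str = "trial") -> None:
        """Write the participant and medication tables as CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(directory / f"{prefix}_participants.csv", index=False)
        self.med_changes.to_csv(directory / f"{prefix}_med_changes.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "trial") -> "TrialDataset":
        directory = Path(directory)
        participants = pd.read_csv(directory / f"{prefix}_participants.csv")
        med = pd.read_csv(directory / f"{prefix}_med_changes.csv")
        return cls(participants=participants, med_changes=med)


# ---------------------------------------------------------------------------
# truncated-normal sampling with mean calibration
# ---------------------------------------------------------------------------

def _truncnorm_location(target_mean: np.ndarray, sd: float,
                        low: float, high: float) -> np.ndarray:
    """Location mu such that a N(mu, sd) truncated to [low, high] has the
    requested mean. Vectorised bisection on the closed-form truncated mean;
    targets are clipped a small margin inside the achievable open interval.
    """
    margin = 0.02 * (high - low)
    target = np.clip(np.asarray(target_mean, dtype=float),
                     low + margin, high - margin)

    def trunc_mean(mu: np.ndarray) -> np.ndarray:
        a = (low - mu) / sd
        b = (high - mu) / sd
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        z = np.maximum(z, 1e-300)
        return mu + sd * (stats.norm.pdf(a) - stats.norm.pdf(b)) / z

    lo = target - 8.0 * sd
    hi = target + 8.0 * sd
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = trunc_mean(mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _truncnorm_draw(rng: np.random.Generator, target_mean: np.ndarray,
                    sd: float, low: float, high: float) -> np.ndarray:
    loc = _truncnorm_location(target_mean, sd, low, high)
    a = (low - loc) / sd
    b = (high - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd,
                               size=loc.shape, random_state=rng)


def _randomised_round(rng: np.random.Generator, x: np.ndarray) -> np.ndarray:
    """Integer rounding that preserves expectation: floor(x) + Bern(frac)."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    fl = np.floor(x)
    return (fl + (rng.random(x.shape) < (x - fl))).astype(int)


def _lognormal_frailty(rng: np.random.Generator, sigma: float,
                       size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal frailty with log-sd sigma."""
    if sigma <= 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _cluster_frailty_sigma(icc: float, shape: float) -> float:
    """Log-sd of a unit-mean log-normal cluster frailty giving the requested
    cost-scale ICC when the conditional draw is gamma with the given shape:
    icc = v / (v + (1 + v)/shape) with v the frailty variance."""
    if icc <= 0:
        return 0.0
    denom = 1.0 - icc - icc / shape
    if denom <= 0:
        raise ValueError(f"icc_cost={icc} unattainable at cost_shape={shape}")
    v = (icc / shape) / denom
    return float(np.sqrt(np.log1p(v)))


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_trial(config: SimConfig) -> TrialDataset:
    """Generate one complete cluster trial (no missingness applied).

    Clusters are Poisson-sized (minimum 1) around ``cluster_size_mean``;
    the first half of the clusters form the intervention arm. Follow-up
    utilisation cost carries an additive ``true_delta_cost`` in the
    intervention arm; follow-up utility carries ``true_delta_utility``.
    Decedents (rate ``death_rate``, arm-independent) have follow-up utility
    0 and half the expected follow-up utilisation.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_clusters = 2 * cfg.n_clusters_per_arm
    sizes = np.maximum(1, rng.poisson(cfg.cluster_size_mean, size=n_clusters))
    if sizes.sum() == 0:  # unreachable with the floor, kept as the contract
        raise ValueError("degenerate configuration: all clusters empty")
    n = int(sizes.sum())

    cluster_id = np.repeat(np.arange(n_clusters), sizes)
    arm_int = np.repeat((np.arange(n_clusters) < cfg.n_clusters_per_arm).astype(int),
                        sizes)

    # --- covariates -------------------------------------------------------
    age = rng.normal(76.5, 6.8, size=n).round(1)
    sex = rng.binomial(1, 0.574, size=n)  # 1 = female
    medical_card = rng.binomial(1, 0.90, size=n)
    private_insurance = rng.binomial(1, 0.35, size=n)
    n_meds = np.maximum(15, np.round(rng.normal(17.4, 3.5, size=n))).astype(int)
    died = rng.binomial(1, cfg.death_rate, size=n)
    covid = rng.binomial(1, cfg.covid_followup_rate, size=n)

    # --- latent utilisation costs ----------------------------------------
    sigma_c = _cluster_frailty_sigma(cfg.icc_cost, cfg.cost_shape)
    f_cluster = np.repeat(_lognormal_frailty(rng, sigma_c, n_clusters), sizes)
    f_ind = _lognormal_frailty(rng, cfg.cost_frailty_sd, n)

    mean_b = cfg.baseline_cost_mean * f_cluster * f_ind
    mean_f = ((cfg.baseline_cost_mean + cfg.true_delta_cost * arm_int)
              * f_cluster * f_ind)
    mean_f = mean_f * np.where(died == 1, 0.5, 1.0)
    mean_f = np.maximum(mean_f, 1e-9)

    if cfg.cost_distribution == "gamma":
        latent_b = rng.gamma(cfg.cost_shape, mean_b / cfg.cost_shape)
        latent_f = rng.gamma(cfg.cost_shape, mean_f / cfg.cost_shape)
    else:
        cv = 1.0 / np.sqrt(cfg.cost_shape)
        latent_b = np.maximum(0.0, rng.normal(mean_b, cv * mean_b))
        latent_f = np.maximum(0.0, rng.normal(mean_f, cv * mean_f))

    data = {
        "participant_id": np.arange(n),
        "cluster_id": cluster_id,
        "arm": np.where(arm_int == 1, "intervention", "control"),
        "age": age,
        "sex": sex,
        "medical_card": medical_card,
        "private_insurance": private_insurance,
        "n_baseline_medications": n_meds,
        "died": died,
        "followup_after_covid": covid,
        "_latent_cost_baseline": latent_b,
        "_latent_cost_followup": latent_f,
    }

    for item in SERVICE_ITEMS:
        share = DEFAULT_ITEM_SHARES[item]
        unit = DEFAULT_UNIT_COSTS[item]
        data[f"{item}_baseline"] = _randomised_round(rng, latent_b * share / unit)
        data[f"{item}_followup"] = _randomised_round(rng, latent_f * share / unit)

    # --- utilities --------------------------------------------------------
    tau = cfg.utility_sd * np.sqrt(cfg.icc_utility / (1.0 - cfg.icc_utility))
    b_cluster = np.repeat(rng.normal(0.0, tau, size=n_clusters) if tau > 0
                          else np.zeros(n_clusters), sizes)
    target_b = cfg.baseline_utility_mean + b_cluster
    u_baseline = _truncnorm_draw(rng, target_b, cfg.utility_sd,
                                 cfg.utility_min, 1.0)

    rho = cfg.utility_followup_corr
    # deviation of the realised baseline draw from its own truncated mean,
    # so anchoring on it leaves the follow-up mean unchanged in expectation
    loc_b = _truncnorm_location(target_b, cfg.utility_sd, cfg.utility_min, 1.0)
    a_std = (cfg.utility_min - loc_b) / cfg.utility_sd
    b_std = (1.0 - loc_b) / cfg.utility_sd
    z = np.maximum(stats.norm.cdf(b_std) - stats.norm.cdf(a_std), 1e-300)
    mean_b_real = loc_b + cfg.utility_sd * (stats.norm.pdf(a_std)
                                            - stats.norm.pdf(b_std)) / z
    dev = u_baseline - mean_b_real
    target_f = (cfg.baseline_utility_mean + b_cluster
                + cfg.true_delta_utility * arm_int + rho * dev)
    sd_f = cfg.utility_sd * np.sqrt(max(1.0 - rho ** 2, 1e-12))
    u_followup = _truncnorm_draw(rng, target_f, sd_f, cfg.utility_min, 1.0)
    u_followup = np.where(died == 1, 0.0, u_followup)

    data["eq5d_baseline"] = np.round(u_baseline, 4)
    data["eq5d_followup"] = np.round(u_followup, 4)

    participants = pd.DataFrame(data)

    # --- medication change lines (arm-independent by construction) -------
    med_rows = []
    n_stopped = rng.poisson(cfg.n_med_stopped_mean, size=n)
    n_started = rng.poisson(cfg.n_med_started_mean, size=n)
    intervals = np.array([28, 30, 90])
    interval_p = np.array([0.6, 0.3, 0.1])
    for pid in range(n):
        for direction, count in (("stopped", n_stopped[pid]),
                                 ("started", n_started[pid])):
            if count == 0:
                continue
            cost = rng.gamma(cfg.med_ingredient_cost_shape,
                             cfg.med_ingredient_cost_mean
                             / cfg.med_ingredient_cost_shape, size=count)
            iv = rng.choice(intervals, p=interval_p, size=count)
            inc = rng.binomial(1, 0.95, size=count)
            for c, i, k in zip(cost, iv, inc):
                med_rows.append((pid, direction, round(float(c), 2), int(i), int(k)))
    med_changes = pd.DataFrame(
        med_rows,
        columns=["participant_id", "direction", "ingredient_cost_per_interval",
                 "dispensing_interval", "included"],
    )

    return TrialDataset(participants=participants, med_changes=med_changes,
                        complete=participants.copy(), config=cfg)


# ---------------------------------------------------------------------------
# missing-at-random masking
# ---------------------------------------------------------------------------

def _calibrate_intercept(score: np.ndarray, rate: float) -> float:
    """Intercept a such that mean(expit(a + score)) equals the target rate."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    from scipy.special import expit
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + score).mean() < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_missingness(data: TrialDataset, config: SimConfig) -> TrialDataset:
    """Mask follow-up utility and follow-up cost items missing-at-random.

    The masking probability is logistic in standardised age and baseline
    utilisation cost (weight ``mar_covariate_weight``; 0 recovers MCAR),
    with the intercept calibrated per dataset so the marginal rate matches
    the configured rate in expectation. Masking never looks at follow-up
    values, so the mechanism is MAR given (age, baseline cost).
    """
    cfg = config
    if not (0.0 <= cfg.missing_utility_rate <= 1.0
            and 0.0 <= cfg.missing_cost_rate <= 1.0):
        raise ValueError("missing rates must lie in [0, 1]")
    df = data.participants.copy()
    if cfg.missing_utility_rate == 0.0 and cfg.missing_cost_rate == 0.0:
        return TrialDataset(participants=df, med_changes=data.med_changes.copy(),
                            complete=(data.complete if data.complete is not None
                                      else data.participants).copy(),
                            config=cfg)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 911]))
    from scipy.special import expit

    def std(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / (s if s > 0 else 1.0)

    score = cfg.mar_covariate_weight * (
        std(df["age"].to_numpy(float))
        + std(df["_latent_cost_baseline"].to_numpy(float))
    ) / np.sqrt(2.0)

    if cfg.missing_utility_rate > 0:
        a = _calibrate_intercept(score, cfg.missing_utility_rate)
        mask = rng.random(len(df)) < expit(a + score)
        df.loc[mask, "eq5d_followup"] = np.nan

    if cfg.missing_cost_rate > 0:
        a = _calibrate_intercept(score, cfg.missing_cost_rate)
        p = expit(a + score)
        for item in SERVICE_ITEMS:
            col = f"{item}_followup"
            mask = rng.random(len(df)) < p
            df[col] = df[col].astype(float)
            df.loc[mask, col] = np.nan

    return TrialDataset(participants=df, med_changes=data.med_changes.copy(),
                        complete=(data.complete if data.complete is not None
                                  else data.participants).copy(),
                        config=cfg)
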