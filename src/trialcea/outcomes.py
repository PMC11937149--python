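"""EQ-5D-5L utility scoring and QALY construction.

A five-digit EQ-5D-5L state (mobility, self-care, usual activities,
pain/discomfort, anxiety/depression; levels 1–5) is mapped to a utility
index by a country-specific value set: 1 is full health, 0 is dead, and
states valued worse than dead score below 0. The value set is *data*, not
code — any complete state→score table or additive decrement table is
accepted. A synthetic value set with the Irish index range [−0.974, 1]
ships for tests and examples; it is not the published national tariff.

QALYs gained over the follow-up window are the area under the utility
curve, i.e. the trapezoid between the baseline and follow-up index scores.
Handling of participants who die during follow-up is configurable (the
default scores the follow-up assessment 0 and keeps the full-horizon
trapezoid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ValueSet",
    "QalyRecord",
    "synthetic_value_set",
    "score_state",
    "qaly_auc",
    "apply_death_rule",
    "qaly_dataset",
    "DEATH_RULES",
]

DIMENSIONS = ("mobility", "self_care", "usual_activities",
              "pain_discomfort", "anxiety_depression")

DEATH_RULES = ("zero_from_death", "exclude", "midpoint")


@dataclass
class ValueSet:
    """State→index mapping, either explicit (all 3125 states) or closed
    under additive decrements per dimension level. State 11111 scores 1."""

    scores: Optional[Dict[str, float]] = None
    decrements: Optional[Dict[str, tuple]] = None  # dim -> decrements for levels 1..5
    min_score: float = -0.974

    def __post_init__(self) -> None:
        if (self.scores is None) == (self.decrements is None):
            raise ValueError("provide exactly one of scores or decrements")
        if self.min_score < -1:
            raise ValueError("min_score must be >= -1")
        if self.decrements is not None:
            if set(self.decrements) != set(DIMENSIONS):
                raise ValueError(f"decrements must cover {DIMENSIONS}")
            for dim, dec in self.decrements.items():
                if len(dec) != 5 or dec[0] != 0:
                    raise ValueError(f"{dim}: need 5 decrements with level 1 = 0")
        if abs(self.score("11111") - 1.0) > 1e-12:
            raise ValueError("state 11111 must score 1")

    def score(self, state: str) -> float:
        state = str(state)
        if len(state) != 5 or any(d not in "12345" for d in state):
            raise ValueError(f"malformed EQ-5D-5L state {state!r}")
        if self.scores is not None:
            try:
                return self.scores[state]
            except KeyError:
                raise KeyError(f"state {state!r} not in value set") from None
        total = 1.0
        for dim, digit in zip(DIMENSIONS, state):
            total -= self.decrements[dim][int(digit) - 1]
        return total

    @property
    def range(self) -> tuple[float, float]:
        return (self.min_score, 1.0)

    def to_csv(self, path: str | Path) -> None:
        if self.decrements is not None:
            rows = [(dim, lvl + 1, dec)
                    for dim, decs in self.decrements.items()
                    for lvl, dec in enumerate(decs)]
            pd.DataFrame(rows, columns=["dimension", "level", "decrement"]
                         ).to_csv(path, index=False)
        else:
            pd.DataFrame({"state": list(self.scores),
                          "score": list(self.scores.values())}
                         ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ValueSet":
        df = pd.read_csv(path, dtype={0: str})
        cols = [c.lower() for c in df.columns]
        if "decrement" in cols:
            dec: Dict[str, list] = {}
            for _, row in df.iterrows():
                dec.setdefault(row["dimension"], [0.0] * 5)[int(row["level"]) - 1] \
                    = float(row["decrement"])
            decs = {k: tuple(v) for k, v in dec.items()}
            min_score = 1.0 - sum(v[-1] for v in decs.values())
            return cls(decrements=decs, min_score=min_score)
        scores = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
        return cls(scores=scores, min_score=min(scores.values()))


def synthetic_value_set() -> ValueSet:
    """Additive-decrement value set spanning [−0.974, 1].

    The per-dimension maximum decrements sum to 1.974 so the worst state
    55555 scores −0.974, matching the published Irish index range; the
    within-dimension level profile is a plausible convex ladder. Synthetic:
    for testing and examples only.
    """
    max_dec = {"mobility": 0.350, "self_care": 0.320, "usual_activities": 0.280,
               "pain_discomfort": 0.550, "anxiety_depression": 0.474}
    profile = (0.0, 0.12, 0.30, 0.60, 1.0)
    decs = {dim: tuple(round(m * p, 6) for p in profile)
            for dim, m in max_dec.items()}
    return ValueSet(decrements=decs, min_score=-0.974)


def score_state(state: str, vs: ValueSet) -> float:
    """Utility index for a five-digit state under the given value set."""
    return vs.score(state)


def qaly_auc(u_baseline: float, u_followup: float,
             horizon_years: float = 0.5) -> float:
    """Area-under-the-curve QALYs: trapezoid between the two index scores
    over the horizon."""
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    return horizon_years * (u_baseline + u_followup) / 2.0


@dataclass
class QalyRecord:
    participant_id: int
    u_baseline: float
    u_followup: float
    horizon_years: float
    qalys: float
    excluded: bool = False


def apply_death_rule(record: Mapping, rule: str = "zero_from_death",
                     horizon_years: float = 0.5) -> QalyRecord:
    """QALYs for one participant, honouring the decedent rule.

    zero_from_death (default) — decedents score 0 at follow-up and keep the
    full-horizon trapezoid (the death date is unknown); exclude — decedents
    are flagged out of the QALY analysis; midpoint — utility declines
    linearly from baseline to 0 at mid-horizon, 0 thereafter.
    """
    if rule not in DEATH_RULES:
        raise ValueError(f"unknown death rule {rule!r}; choose from {DEATH_RULES}")
    pid = int(record["participant_id"])
    u0 = float(record["eq5d_baseline"])
    died = bool(record["died"])
    if not died:
        u1 = float(record["eq5d_followup"])
        return QalyRecord(pid, u0, u1, horizon_years,
                          qaly_auc(u0, u1, horizon_years))
    if rule == "exclude":
        return QalyRecord(pid, u0, np.nan, horizon_years, np.nan, excluded=True)
    if rule == "midpoint":
        qalys = (horizon_years / 2.0) * u0 / 2.0
        return QalyRecord(pid, u0, 0.0, horizon_years, qalys)
    return QalyRecord(pid, u0, 0.0, horizon_years,
                      qaly_auc(u0, 0.0, horizon_years))


def qaly_dataset(participants: pd.DataFrame, value_set: Optional[ValueSet] = None,
                 rule: str = "zero_from_death",
                 horizon_years: float = 0.5) -> pd.DataFrame:
    """Vectorised QALY construction for a participant table.

    ``eq5d_baseline``/``eq5d_followup`` may hold index scores (floats) or
    five-digit states (strings), in which case ``value_set`` scores them.
    Returns a frame with utility columns, ``qalys`` and ``qaly_excluded``.
    """
    if rule not in DEATH_RULES:
        raise ValueError(f"unknown death rule {rule!r}; choose from {DEATH_RULES}")
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")

    def to_index(col: pd.Series) -> np.ndarray:
        if col.dtype == object:
            if value_set is None:
                raise ValueError("state-coded EQ-5D data needs a value set")
            return np.array([np.nan if pd.isna(s) else value_set.score(s)
                             for s in col], dtype=float)
        return col.to_numpy(float)

    u0 = to_index(participants["eq5d_baseline"])
    u1 = to_index(participants["eq5d_followup"])
    died = participants["died"].to_numpy(bool)

    u1_eff = u1.copy()
    excluded = np.zeros(len(u0), dtype=bool)
    if rule == "exclude":
        excluded = died
        u1_eff = np.where(died, np.nan, u1)
        qalys = horizon_years * (u0 + u1_eff) / 2.0
    elif rule == "midpoint":
        u1_eff = np.where(died, 0.0, u1)
        qalys = np.where(died, (horizon_years / 2.0) * u0 / 2.0,
                         horizon_years * (u0 + u1_eff) / 2.0)
    else:
        u1_eff = np.where(died, 0.0, u1)
        qalys = horizon_years * (u0 + u1_eff) / 2.0

    return pd.DataFrame({
        "participant_id": participants["participant_id"].to_numpy(),
        "u_baseline": u0,
        "u_followup": u1_eff,
        "qalys": qalys,
        "qaly_excluded": excluded,
    })
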