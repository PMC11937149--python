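"""Total six-month healthcare cost construction.

Three components enter the per-participant total, from the perspective of
the health service:

1. intervention delivery cost — fixed plus variable implementation outlays
   allocated equally across intervention-arm participants;
2. marginal medication costs — only medications *stopped* (present at
   baseline, absent at follow-up) and *started* (the reverse) are costed,
   each as ceiling(horizon / dispensing interval) dispensings of
   (ingredient cost + dispensing fee); stopped medications enter with a
   negative sign, so totals can be negative;
3. primary/secondary-care utilisation — item counts priced by a unit-cost
   vector (GP consultation types, practice nurse, outpatient, inpatient
   nights, emergency department).

Any missing component leaves the total missing; resolving item-level
missingness is the imputation module's job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .synthetic import SERVICE_ITEMS, DEFAULT_UNIT_COSTS, TrialDataset

__all__ = [
    "UnitCostTable",
    "InterventionCostSpec",
    "MedChangeLine",
    "CostBreakdown",
    "allocate_intervention_cost",
    "medication_cost",
    "total_cost",
    "cost_dataset",
    "default_unit_costs",
]

#: Default six-month horizon in days for medication costing.
DEFAULT_HORIZON_DAYS = 182


@dataclass
class UnitCostTable:
    """Euro cost per unit of each resource item, plus the per-dispensing
    pharmacy fee, in a stated price year."""

    costs: Dict[str, float]
    dispensing_fee: float = 5.0
    price_year: str = "2022"

    def __post_init__(self) -> None:
        for item, c in self.costs.items():
            if c < 0:
                raise ValueError(f"negative unit cost for {item!r}")
        if self.dispensing_fee < 0:
            raise ValueError("dispensing fee must be >= 0")

    def __getitem__(self, item: str) -> float:
        try:
            return self.costs[item]
        except KeyError:
            raise KeyError(f"no unit cost for resource item {item!r}") from None

    def scaled(self, multiplier: float) -> "UnitCostTable":
        """Multiply all service unit costs (sensitivity scenarios); the
        dispensing fee is left unchanged."""
        if multiplier <= 0:
            raise ValueError("multiplier must be positive")
        return UnitCostTable({k: v * multiplier for k, v in self.costs.items()},
                             dispensing_fee=self.dispensing_fee,
                             price_year=self.price_year)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"item": list(self.costs), "euro_per_unit":
                      list(self.costs.values())}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, dispensing_fee: float = 5.0,
                 price_year: str = "2022") -> "UnitCostTable":
        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))),
                   dispensing_fee=dispensing_fee, price_year=price_year)


def default_unit_costs() -> UnitCostTable:
    """Synthetic unit-cost vector shipped for tests and examples (euro,
    2022-style magnitudes; not the national tariffs)."""
    return UnitCostTable(dict(DEFAULT_UNIT_COSTS))


@dataclass
class InterventionCostSpec:
    """Implementation cost of the intervention: fixed once-off outlays
    (website, educator/administrator time) plus variable operating items,
    spread over the intervention-arm participants."""

    fixed_total: float
    variable_total: float
    n_intervention_participants: int

    def __post_init__(self) -> None:
        if self.fixed_total < 0 or self.variable_total < 0:
            raise ValueError("intervention cost totals must be >= 0")
        if self.n_intervention_participants <= 0:
            raise ValueError("n_intervention_participants must be > 0")

    @property
    def per_participant(self) -> float:
        return (self.fixed_total + self.variable_total) / self.n_intervention_participants

    def scaled(self, multiplier: float) -> "InterventionCostSpec":
        return InterventionCostSpec(self.fixed_total * multiplier,
                                    self.variable_total * multiplier,
                                    self.n_intervention_participants)


def allocate_intervention_cost(spec: InterventionCostSpec) -> float:
    """Unrounded per-participant intervention cost; round to the nearest
    euro for reporting."""
    return spec.per_participant


@dataclass
class MedChangeLine:
    participant_id: int
    direction: str  # "stopped" | "started"
    ingredient_cost_per_interval: float
    dispensing_interval: int
    included: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("stopped", "started"):
            raise ValueError(f"direction must be 'stopped' or 'started', "
                             f"got {self.direction!r}")
        if self.dispensing_interval <= 0:
            raise ValueError(
                f"non-positive dispensing interval on line for participant "
                f"{self.participant_id} ({self.direction}, "
                f"€{self.ingredient_cost_per_interval}/interval)")
        if self.ingredient_cost_per_interval < 0:
            raise ValueError("ingredient cost must be >= 0")


def medication_cost(lines: Iterable[MedChangeLine], horizon_days: int,
                    dispensing_fee: float = 5.0) -> tuple[float, float]:
    """(cost_started, cost_stopped) over the horizon.

    Each line contributes ceiling(horizon / interval) dispensings of
    (ingredient cost per interval + dispensing fee); excluded lines
    (non-covered / non-drug / high-tech classes) contribute nothing.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    started = stopped = 0.0
    for line in lines:
        if not line.included:
            continue
        if line.dispensing_interval <= 0:
            raise ValueError(
                f"non-positive dispensing interval on line for participant "
                f"{line.participant_id}")
        n_disp = math.ceil(horizon_days / line.dispensing_interval)
        cost = n_disp * (line.ingredient_cost_per_interval + dispensing_fee)
        if line.direction == "started":
            started += cost
        else:
            stopped += cost
    return started, stopped


@dataclass
class CostBreakdown:
    """Per-participant cost components; total = intervention + started
    − stopped + Σ service costs (may be negative, or NaN if any component
    is missing)."""

    participant_id: int
    intervention_cost: float
    cost_started: float
    cost_stopped: float
    service_costs: Dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = (self.intervention_cost + self.cost_started
                      - self.cost_stopped + sum(self.service_costs.values()))


def total_cost(record: Mapping, units: UnitCostTable,
               iv_spec: Optional[InterventionCostSpec],
               period: str = "followup",
               med_lines: Iterable[MedChangeLine] = (),
               horizon_days: int = DEFAULT_HORIZON_DAYS,
               items: tuple[str, ...] = SERVICE_ITEMS) -> CostBreakdown:
    """Build one participant's cost breakdown for a period.

    The intervention component applies only to intervention-arm rows at
    follow-up; medication changes are costed only at follow-up. A missing
    item count propagates NaN into the total.
    """
    if period not in ("baseline", "followup"):
        raise ValueError(f"unknown period {period!r}")
    service = {}
    for item in items:
        count = record[f"{item}_{period}"]
        service[item] = float(count) * units[item]  # NaN count -> NaN cost
    if period == "followup":
        started, stopped = medication_cost(med_lines, horizon_days,
                                           units.dispensing_fee)
        iv_cost = (allocate_intervention_cost(iv_spec)
                   if iv_spec is not None and record["arm"] == "intervention"
                   else 0.0)
    else:
        started = stopped = 0.0
        iv_cost = 0.0
    return CostBreakdown(participant_id=int(record["participant_id"]),
                         intervention_cost=iv_cost, cost_started=started,
                         cost_stopped=stopped, service_costs=service)


def _med_costs_frame(med_changes: pd.DataFrame, horizon_days: int,
                     dispensing_fee: float) -> pd.DataFrame:
    """Vectorised per-participant (cost_started, cost_stopped)."""
    if len(med_changes) == 0:
        return pd.DataFrame(columns=["cost_started", "cost_stopped"])
    m = med_changes[med_changes["included"].astype(bool)].copy()
    if (m["dispensing_interval"] <= 0).any():
        bad = m.loc[m["dispensing_interval"] <= 0].iloc[0]
        raise ValueError(f"non-positive dispensing interval on line for "
                         f"participant {bad['participant_id']}")
    n_disp = np.ceil(horizon_days / m["dispensing_interval"].to_numpy(float))
    m["line_cost"] = n_disp * (m["ingredient_cost_per_interval"].to_numpy(float)
                               + dispensing_fee)
    out = (m.pivot_table(index="participant_id", columns="direction",
                         values="line_cost", aggfunc="sum", fill_value=0.0)
           .rename(columns={"started": "cost_started", "stopped": "cost_stopped"}))
    for col in ("cost_started", "cost_stopped"):
        if col not in out:
            out[col] = 0.0
    return out[["cost_started", "cost_stopped"]]


def cost_dataset(data: TrialDataset, units: UnitCostTable,
                 iv_spec: Optional[InterventionCostSpec],
                 horizon_days: int = DEFAULT_HORIZON_DAYS,
                 items: tuple[str, ...] = SERVICE_ITEMS,
                 exclude_components: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-participant cost table for both periods.

    Returns a frame indexed like ``data.participants`` with per-item cost
    columns ``cost_{item}_{period}``, medication components, the
    intervention component, and ``total_cost_baseline`` /
    ``total_cost_followup``. ``exclude_components`` may name service items,
    ``medication_stopped``, ``medication_started`` or ``intervention``
    (``hospitalisation`` is an alias for inpatient nights) to zero a
    component out, as in sensitivity scenarios.
    """
    known = set(items) | {"medication_stopped", "medication_started",
                          "intervention", "hospitalisation"}
    unknown = set(exclude_components) - known
    if unknown:
        raise ValueError(f"unknown cost components: {sorted(unknown)}")
    excl = {("inpatient_nights" if c == "hospitalisation" else c)
            for c in exclude_components}

    df = data.participants
    out = pd.DataFrame({"participant_id": df["participant_id"].to_numpy()})

    for period in ("baseline", "followup"):
        service_total = np.zeros(len(df))
        for item in items:
            unit = units[item]
            counts = df[f"{item}_{period}"].to_numpy(float)
            cost = counts * unit
            if item in excl:
                cost = np.zeros(len(df))
            out[f"cost_{item}_{period}"] = cost
            service_total = service_total + cost
        out[f"service_cost_{period}"] = service_total

    med = _med_costs_frame(data.med_changes, horizon_days, units.dispensing_fee)
    med = med.reindex(df["participant_id"]).fillna(0.0)
    started = med["cost_started"].to_numpy(float)
    stopped = med["cost_stopped"].to_numpy(float)
    if "medication_started" in excl:
        started = np.zeros(len(df))
    if "medication_stopped" in excl:
        stopped = np.zeros(len(df))
    out["cost_started"] = started
    out["cost_stopped"] = stopped

    iv_pp = (allocate_intervention_cost(iv_spec) if iv_spec is not None else 0.0)
    if "intervention" in excl:
        iv_pp = 0.0
    out["intervention_cost"] = np.where(df["arm"].to_numpy() == "intervention",
                                        iv_pp, 0.0)

    out["total_cost_baseline"] = out["service_cost_baseline"]
    out["total_cost_followup"] = (out["service_cost_followup"]
                                  + out["intervention_cost"]
                                  + out["cost_started"] - out["cost_stopped"])
    return out
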