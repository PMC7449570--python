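"""Cost model and optimal-design search.

Total experimental cost of a design that sequences n participants and
array-genotypes m is n * (sequencing cost) + m * (array cost); sequenced
participants incur no array cost.  Designs with equal total cost lie on the
iso-cost line m = a - b*n with a = cost/array_cost and
b = seq_cost/array_cost.

Two equivalent notions of the most cost-effective design are supported over
an exhaustive (n, m, array) grid:

* minimum total cost subject to power >= target, and
* maximum power subject to total cost <= budget.

Costs are held as exact integer cents so feasibility boundaries are not
subject to float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .disease_model import DiseaseModel, SignificanceSpec
from .power_engine import StudyDesign, _powers_over_m
from .quality_data import QualityTable, interpolate_panel_size

__all__ = [
    "CostModel",
    "GridSpec",
    "OptimizationResult",
    "total_cost",
    "min_cost_design",
    "max_power_design",
]

#: Current list prices per sample for the three genotyping arrays (USD).
DEFAULT_ARRAY_COSTS = {"core": 49.0, "omniexpress": 94.0, "omni2.5": 172.0}


@dataclass(frozen=True)
class CostModel:
    """Per-sample sequencing and array-genotyping costs (USD)."""

    seq_cost_per_sample: float = 1000.0
    array_cost_per_sample: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARRAY_COSTS)
    )

    def __post_init__(self) -> None:
        if self.seq_cost_per_sample <= 0:
            raise ValueError("sequencing cost must be > 0")
        for label, c in self.array_cost_per_sample.items():
            if c <= 0:
                raise ValueError(f"array cost for {label!r} must be > 0")

    def seq_cents(self) -> int:
        return int(round(self.seq_cost_per_sample * 100))

    def array_cents(self, array: str) -> int:
        try:
            return int(round(self.array_cost_per_sample[array] * 100))
        except KeyError as exc:
            raise ValueError(f"unknown array label {array!r}") from exc


def total_cost_cents(design: StudyDesign, costs: CostModel) -> int:
    return design.n_seq * costs.seq_cents() + design.m_imp * costs.array_cents(design.array)


def total_cost(design: StudyDesign, costs: CostModel) -> float:
    """Total experimental cost in dollars: n*seq_cost + m*array_cost."""
    return total_cost_cents(design, costs) / 100.0


@dataclass(frozen=True)
class GridSpec:
    """Exhaustive search grid: n over available panel sizes, m in steps.

    ``n_values`` should be panel sizes at which quality tables exist (or,
    with ``interpolate=True``, any sizes inside their range).
    """

    n_values: tuple[int, ...]
    m_max: int
    m_step: int = 50
    m_min: int = 0
    interpolate: bool = True

    def __post_init__(self) -> None:
        if not self.n_values:
            raise ValueError("grid must contain at least one n value")
        if self.m_step < 1 or self.m_max < self.m_min:
            raise ValueError("invalid m grid")

    def m_values(self) -> range:
        return range(self.m_min, self.m_max + 1, self.m_step)


@dataclass
class OptimizationResult:
    """Outcome of an exhaustive design search.

    When no design is feasible, ``best`` is None and ``max_power``/``min_cost``
    report the best values seen, so callers can diagnose how far the
    constraint was from attainable.
    """

    objective: str
    feasible: bool
    best: StudyDesign | None
    best_power: float | None
    best_cost: float | None
    frontier: pd.DataFrame
    constraints: dict
    max_power: float | None = None


def _evaluate_grid(
    model: DiseaseModel,
    tables: Mapping[str, Sequence[QualityTable]],
    costs: CostModel,
    sig: SignificanceSpec,
    grid: GridSpec,
    **power_kwargs,
) -> pd.DataFrame:
    import numpy as np

    rows = []
    for array, array_tables in tables.items():
        for n in grid.n_values:
            table = interpolate_panel_size(list(array_tables), n)
            m_vals = np.array([m for m in grid.m_values() if n + m >= 1])
            if m_vals.size == 0:
                continue
            powers, p_imp = _powers_over_m(table, model, sig, n, m_vals, **power_kwargs)
            for m, pw in zip(m_vals, powers):
                design = StudyDesign(n_seq=int(n), m_imp=int(m), array=array)
                rows.append(
                    {
                        "array": array,
                        "n_seq": int(n),
                        "m_imp": int(m),
                        "cost_cents": total_cost_cents(design, costs),
                        "power": float(pw),
                        "p_imputable": p_imp,
                    }
                )
    if not rows:
        raise ValueError("empty design grid")
    df = pd.DataFrame(rows)
    df["cost"] = df["cost_cents"] / 100.0
    return df


def _result_from_row(objective, row, frontier, constraints, feasible=True, max_power=None):
    best = StudyDesign(
        n_seq=int(row["n_seq"]), m_imp=int(row["m_imp"]), array=row["array"]
    )
    return OptimizationResult(
        objective=objective,
        feasible=feasible,
        best=best,
        best_power=float(row["power"]),
        best_cost=float(row["cost"]),
        frontier=frontier,
        constraints=constraints,
        max_power=max_power,
    )


def min_cost_design(
    power_target: float,
    model: DiseaseModel,
    tables: Mapping[str, Sequence[QualityTable]],
    costs: CostModel | None = None,
    sig: SignificanceSpec | None = None,
    grid: GridSpec | None = None,
    **power_kwargs,
) -> OptimizationResult:
    """Cheapest design on the grid attaining power >= ``power_target``.

    Exhaustive evaluation; ties broken by cost, then n, then m.  When no
    grid point is feasible the result carries ``feasible=False`` and the
    maximum power found.
    """
    if not 0.0 <= power_target < 1.0:
        raise ValueError("power target must be in [0, 1)")
    costs = costs or CostModel()
    sig = sig or SignificanceSpec()
    if grid is None:
        raise ValueError("a GridSpec is required")
    frontier = _evaluate_grid(model, tables, costs, sig, grid, **power_kwargs)
    frontier["feasible"] = frontier["power"] >= power_target
    constraints = {"power_target": power_target}
    feas = frontier[frontier["feasible"]]
    if feas.empty:
        return OptimizationResult(
            objective="min_cost_at_power",
            feasible=False,
            best=None,
            best_power=None,
            best_cost=None,
            frontier=frontier,
            constraints=constraints,
            max_power=float(frontier["power"].max()),
        )
    best = feas.sort_values(["cost_cents", "n_seq", "m_imp"]).iloc[0]
    return _result_from_row("min_cost_at_power", best, frontier, constraints,
                            max_power=float(frontier["power"].max()))


def max_power_design(
    budget: float,
    model: DiseaseModel,
    tables: Mapping[str, Sequence[QualityTable]],
    costs: CostModel | None = None,
    sig: SignificanceSpec | None = None,
    grid: GridSpec | None = None,
    **power_kwargs,
) -> OptimizationResult:
    """Most powerful design on the grid with total cost <= ``budget`` dollars.

    Ties broken by lower cost, then lower n, then lower m.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    costs = costs or CostModel()
    sig = sig or SignificanceSpec()
    if grid is None:
        raise ValueError("a GridSpec is required")
    budget_cents = int(round(budget * 100))
    frontier = _evaluate_grid(model, tables, costs, sig, grid, **power_kwargs)
    frontier["feasible"] = frontier["cost_cents"] <= budget_cents
    constraints = {"budget": budget}
    feas = frontier[frontier["feasible"]]
    if feas.empty:
        return OptimizationResult(
            objective="max_power_at_budget",
            feasible=False,
            best=None,
            best_power=None,
            best_cost=None,
            frontier=frontier,
            constraints=constraints,
            max_power=None,
        )
    best = feas.sort_values(
        ["power", "cost_cents", "n_seq", "m_imp"],
        ascending=[False, True, True, True],
    ).iloc[0]
    return _result_from_row("max_power_at_budget", best, frontier, constraints,
                            max_power=float(feas["power"].max()))
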