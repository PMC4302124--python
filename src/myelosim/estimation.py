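"""Toxicity-parameter estimation from median blood-count time series.

The model is fitted to clinical (or synthetic) median curves by minimizing

    J(k) = integral_{t0}^{t1} | log f_model(t, k) - log f_data(t) | dt

per scenario (natural log; f_data is the linear interpolation of the data
points on the linear scale), summed over all scenarios of a fitting step.
Cell counts are treated as log-normally distributed, hence the log scale.

Minimization uses a (mu+lambda) evolution strategy in log-parameter space
with per-coordinate self-adaptive step sizes, box constraints by projection
and ordering constraints (e.g. "escalated dose must not be less toxic") by
penalty.  Parameters estimated in earlier steps of a stepwise protocol are
frozen; the shipped default protocol mirrors the staged estimation order
from simple to complex chemotherapies and keeps three scenarios out of all
fitting steps for validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemo_toxicity import ToxicityParameterSet, load_toxicity_table
from .model_core import CellKineticParameters
from .regimens import Regimen, scenario_regimen
from .sim_engine import SolverSettings, simulate

__all__ = [
    "ObservedSeries",
    "FitScenario",
    "FitResult",
    "FitStep",
    "EsOptions",
    "cost",
    "evolution_strategy",
    "fit_toxicity",
    "stepwise_protocol",
    "default_protocol",
    "read_observed_csv",
    "write_observed_csv",
]

#: Fields of a toxicity parameter set that may be estimated.
FIT_FIELDS = (
    "first_cycle_factor",
    "k_delay_per_h",
    "k_s",
    "k_cg",
    "k_pgb",
    "k_mgb",
    "k_delay_wbc_per_h",
    "k_ly",
)

#: Default box bounds (linear scale) per estimable field.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "first_cycle_factor": (1.0, 3.0),
    "k_delay_per_h": (1.0e-3, 1.0),
    "k_s": (1.0e-7, 1.0e2),
    "k_cg": (1.0e-7, 1.0e2),
    "k_pgb": (1.0e-7, 1.0e2),
    "k_mgb": (1.0e-7, 1.0e2),
    "k_delay_wbc_per_h": (1.0e-5, 1.0),
    "k_ly": (1.0e-7, 1.0e2),
}


@dataclass(frozen=True)
class ObservedSeries:
    """Median WBC or ANC day/value pairs for one scenario."""

    days: tuple[float, ...]
    values: tuple[float, ...]
    count_type: str = "WBC"          # 'WBC' | 'ANC'
    scenario_id: str = ""
    unit: str = "cells/ul"
    iqr: tuple | None = None         # metadata only

    def __post_init__(self) -> None:
        days = tuple(float(d) for d in self.days)
        values = tuple(float(v) for v in self.values)
        if len(days) != len(values) or len(days) < 2:
            raise ValueError("need >= 2 matching day/value pairs")
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("days must be non-decreasing")
        if any(v <= 0 for v in values):
            raise ValueError("values must be positive (log scale)")
        if self.count_type not in ("WBC", "ANC"):
            raise ValueError(f"unknown count type {self.count_type!r}")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)


def cost(
    model_time_day: np.ndarray, model_values: np.ndarray, data: ObservedSeries
) -> float:
    """Integrated absolute log-deviation between model curve and data.

    Trapezoidal quadrature over the data span on the data-day grid (the
    resolution at which the data curve is defined): the integrand vanishes
    at every node when the model passes through the data points, so a model
    that reproduces the data exactly has zero cost.  Evaluating between
    clinic days would instead compare the model against the chords of the
    interpolated data curve, putting a spurious floor under the cost and
    biasing estimates.
    """
    t = np.asarray(model_time_day, dtype=float)
    v = np.asarray(model_values, dtype=float)
    t0, t1 = data.days[0], data.days[-1]
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(
            f"model curve [{t[0]}, {t[-1]}] does not span data window [{t0}, {t1}]"
        )
    grid = np.unique(np.asarray(data.days, dtype=float))
    m = np.interp(grid, t, v)
    d = np.interp(grid, data.days, data.values)
    if np.any(m <= 0):
        raise ValueError("model curve must be positive on the data window (log scale)")
    return float(np.trapezoid(np.abs(np.log(m) - np.log(d)), grid))


# ---------------------------------------------------------------------------
# (mu + lambda) evolution strategy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EsOptions:
    mu: int = 5
    lam: int = 35
    generations: int = 200
    initial_step: float = 0.5          # log-space standard deviation
    stagnation_restart: int = 40       # generations without improvement
    min_step: float = 1.0e-8


def evolution_strategy(
    func: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int,
    options: EsOptions = EsOptions(),
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[tuple[int, float]]]:
    """Minimize ``func`` on a box via a (mu+lambda) ES with self-adaptation.

    Works directly on the given coordinates (callers pass log-parameters).
    Box constraints are enforced by projection; a restart re-seeds all but
    the best parent after prolonged stagnation.  Deterministic given seed.
    Returns ``(best_x, best_f, trace)`` with one trace entry per generation.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    n = lower.size
    if np.any(upper < lower):
        raise ValueError("invalid bounds: upper < lower")
    rng = np.random.default_rng(seed)
    tau_g = 1.0 / math.sqrt(2.0 * n)
    tau_c = 1.0 / math.sqrt(2.0 * math.sqrt(n))

    def sample_x() -> np.ndarray:
        return rng.uniform(lower, upper)

    def new_parent(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        return x, np.full(n, options.initial_step), func(x)

    parents = []
    if x0 is not None:
        parents.append(new_parent(np.clip(np.asarray(x0, dtype=float), lower, upper)))
    while len(parents) < options.mu:
        parents.append(new_parent(sample_x()))

    best_x, _, best_f = min(parents, key=lambda p: p[2])
    trace: list[tuple[int, float]] = []
    since_improvement = 0
    for gen in range(options.generations):
        offspring = []
        for _ in range(options.lam):
            px, psig, _ = parents[rng.integers(len(parents))]
            sig = psig * np.exp(tau_g * rng.standard_normal() + tau_c * rng.standard_normal(n))
            sig = np.maximum(sig, options.min_step)
            x = np.clip(px + sig * rng.standard_normal(n), lower, upper)
            offspring.append((x, sig, func(x)))
        pool = parents + offspring
        pool.sort(key=lambda p: p[2])
        parents = pool[: options.mu]
        if parents[0][2] < best_f - 1e-15:
            best_x, _, best_f = parents[0]
            since_improvement = 0
        else:
            since_improvement += 1
        if since_improvement >= options.stagnation_restart:
            parents = [parents[0]] + [new_parent(sample_x()) for _ in range(options.mu - 1)]
            since_improvement = 0
        trace.append((gen, best_f))
    return np.asarray(best_x), float(best_f), trace


# ---------------------------------------------------------------------------
# toxicity fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitScenario:
    """One data set with the regimen that generated it."""

    regimen: Regimen
    series: ObservedSeries


@dataclass
class FitResult:
    sets: dict[str, ToxicityParameterSet]
    cost: float
    initial_cost: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0
    frozen: dict[str, ToxicityParameterSet] = field(default_factory=dict)
    free: dict[str, tuple[str, ...]] = field(default_factory=dict)
    constraints_ok: bool = True
    converged: bool = True

    def report_frame(self) -> pd.DataFrame:
        """Fitted parameter sets in the reference-table column layout."""
        rows = []
        for label, s in self.sets.items():
            rows.append(
                {
                    "label": label,
                    "first_cycle_factor": s.first_cycle_factor,
                    "k_delay_per_h": s.k_delay_per_h,
                    "k_s": s.k_s,
                    "k_cg": s.k_cg,
                    "k_pgb": s.k_pgb,
                    "k_mgb": s.k_mgb,
                    "k_delay_wbc_per_h": s.k_delay_wbc_per_h,
                    "k_ly": s.k_ly,
                    "fitted": label in self.free,
                }
            )
        return pd.DataFrame(rows).set_index("label")


def _get_field(pset: ToxicityParameterSet, name: str) -> float:
    value = getattr(pset, name)
    if value is None:
        raise ValueError(f"{pset.label}: field {name} not present (no lymphocyte branch)")
    return float(value)


def _with_fields(pset: ToxicityParameterSet, updates: Mapping[str, float]) -> ToxicityParameterSet:
    return replace(pset, **updates)


def _scenario_cost(
    scenarios: Sequence[FitScenario],
    sets: Mapping[str, ToxicityParameterSet],
    params: CellKineticParameters,
    solver: SolverSettings,
) -> float:
    total = 0.0
    for sc in scenarios:
        horizon = max(sc.series.days[-1] + 1.0, sc.regimen.horizon_days)
        res = simulate(
            sc.regimen, toxicity=dict(sets), params=params,
            horizon_days=horizon, solver=solver,
        )
        curve = res.curve(sc.series.count_type)
        total += cost(res.time_day, curve, sc.series)
    return total


def fit_toxicity(
    scenarios: Sequence[FitScenario],
    free: Mapping[str, Sequence[str]],
    initial: Mapping[str, ToxicityParameterSet],
    frozen: Mapping[str, ToxicityParameterSet] | None = None,
    bounds: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    ordering: Sequence[tuple[str, str]] = (),
    params: CellKineticParameters | None = None,
    solver: SolverSettings | None = None,
    seed: int = 0,
    es_options: EsOptions = EsOptions(),
    penalty_weight: float = 100.0,
) -> FitResult:
    """Estimate the free fields of one or more toxicity parameter sets.

    ``free`` maps labels to the field names to estimate; ``initial``
    supplies full template sets for those labels (fixed fields keep their
    template values).  ``frozen`` sets enter the simulations untouched.
    ``ordering`` entries ``(a, b)`` require every free field of ``a`` shared
    with set ``b`` to satisfy ``a >= b`` (penalized, verified post hoc).
    Deterministic given ``seed``.
    """
    params = params or CellKineticParameters.default()
    solver = solver or SolverSettings()
    frozen = dict(frozen or {})
    free = {label: tuple(fields) for label, fields in free.items()}
    for label, fields in free.items():
        if label not in initial:
            raise ValueError(f"free label {label!r} has no initial template")
        for name in fields:
            if name not in FIT_FIELDS:
                raise ValueError(f"unknown estimable field {name!r}")

    # encoding: one log coordinate per (label, field)
    coords: list[tuple[str, str]] = [
        (label, name) for label in sorted(free) for name in free[label]
    ]

    def decode(x: np.ndarray) -> dict[str, ToxicityParameterSet]:
        sets = dict(frozen)
        by_label: dict[str, dict[str, float]] = {}
        for (label, name), xi in zip(coords, x):
            by_label.setdefault(label, {})[name] = math.exp(xi)
        for label in free:
            sets[label] = _with_fields(initial[label], by_label.get(label, {}))
        return sets

    def reference_value(label: str, name: str) -> float:
        source = frozen.get(label) or initial.get(label)
        if source is None:
            raise ValueError(f"ordering constraint references unknown set {label!r}")
        return _get_field(source, name)

    # feasibility screen for ordering constraints against bounds
    bounds = dict(bounds or {})
    lo = np.empty(len(coords))
    hi = np.empty(len(coords))
    for i, (label, name) in enumerate(coords):
        lb, ub = bounds.get((label, name), DEFAULT_BOUNDS[name])
        lo[i], hi[i] = math.log(lb), math.log(ub)
    for upper_label, lower_label in ordering:
        for i, (label, name) in enumerate(coords):
            if label != upper_label:
                continue
            if (lower_label, name) in dict.fromkeys(coords):
                continue  # both free: mutual feasibility always possible
            floor = reference_value(lower_label, name)
            if math.exp(hi[i]) < floor:
                raise ValueError(
                    f"infeasible ordering {upper_label} >= {lower_label} for {name}: "
                    f"bound {math.exp(hi[i])} < {floor}"
                )

    if not coords:
        base_cost = _scenario_cost(scenarios, frozen, params, solver)
        return FitResult(
            sets=dict(frozen), cost=base_cost, initial_cost=base_cost,
            seed=seed, frozen=dict(frozen), free={},
        )

    def penalty(sets: Mapping[str, ToxicityParameterSet]) -> float:
        p = 0.0
        for upper_label, lower_label in ordering:
            upper = sets.get(upper_label) or initial.get(upper_label)
            lower = sets.get(lower_label) or initial.get(lower_label)
            for name in free.get(upper_label, ()):  # only constrain fitted fields
                try:
                    u = _get_field(upper, name)
                    l = _get_field(lower, name)
                except ValueError:
                    continue
                if u < l:
                    p += (math.log(l) - math.log(u)) ** 2
        return p

    def objective(x: np.ndarray) -> float:
        sets = decode(x)
        return _scenario_cost(scenarios, sets, params, solver) + penalty_weight * penalty(sets)

    x0 = np.array(
        [
            np.clip(math.log(_get_field(initial[label], name)), lo[i], hi[i])
            for i, (label, name) in enumerate(coords)
        ]
    )
    initial_cost = objective(x0)
    best_x, best_f, trace = evolution_strategy(
        objective, lo, hi, seed=seed, options=es_options, x0=x0
    )
    best_sets = decode(best_x)
    constraints_ok = penalty(best_sets) == 0.0
    final_cost = _scenario_cost(scenarios, best_sets, params, solver)
    return FitResult(
        sets=best_sets,
        cost=final_cost,
        initial_cost=initial_cost,
        trace=trace,
        seed=seed,
        frozen=dict(frozen),
        free=free,
        constraints_ok=constraints_ok,
        converged=best_f <= initial_cost,
    )


# ---------------------------------------------------------------------------
# stepwise protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitStep:
    """One stage of a stepwise estimation protocol."""

    name: str
    scenario_ids: tuple[int, ...]
    free: Mapping[str, tuple[str, ...]]
    ordering: tuple[tuple[str, str], ...] = ()


#: Scenarios reserved for validation; no step may use them.
VALIDATION_SCENARIOS = (12, 22, 32)

_CELL_FIELDS = ("k_s", "k_cg", "k_pgb", "k_mgb", "k_ly")
_ALL_FIELDS = FIT_FIELDS


def default_protocol() -> tuple[FitStep, ...]:
    """The shipped staged protocol: simple chemotherapies first.

    CHOP is estimated separately per risk group (elderly assumed more
    toxic); first-cycle factors and delay rates are shared across dose
    levels and risk groups, so follow-up fits free only the cell-stage and
    lymphocyte coefficients.  Later combinations freeze all earlier results
    and carry dose-ordering constraints.
    """
    return (
        FitStep("chop_elderly", (13, 15, 21, 30, 31), {"CHOPo": _ALL_FIELDS}),
        FitStep("chop_young", (14, 20, 33), {"CHOPy": _CELL_FIELDS},
                ordering=(("CHOPo", "CHOPy"),)),
        FitStep("choep_young", (16, 23), {"ETy": _ALL_FIELDS}),
        FitStep("choep_elderly", (17, 24), {"ETo": _CELL_FIELDS},
                ordering=(("ETo", "ETy"),)),
        FitStep("beacopp_basis", (18, 26),
                {"CD": _CELL_FIELDS, "VB": _ALL_FIELDS, "PROC": _ALL_FIELDS},
                ordering=(("CHOPy", "CD"),)),
        FitStep("beacopp_escalated", (27,),
                {"CDesk": _CELL_FIELDS, "ETesk": _CELL_FIELDS},
                ordering=(("CDesk", "CD"), ("ETesk", "ETy"))),
        FitStep("high_choep", (3, 25), {"CDh": _CELL_FIELDS, "ETh": _CELL_FIELDS},
                ordering=(("CDh", "CHOPy"), ("ETh", "ETy"))),
        FitStep("ta", (1, 4, 5, 6, 7, 8), {"TA": _ALL_FIELDS}),
        FitStep("cp", (2, 9, 10, 11), {"CP": _ALL_FIELDS}),
        FitStep("ect_etc", (19, 28),
                {"E90": _ALL_FIELDS, "E150": _CELL_FIELDS,
                 "P175": _ALL_FIELDS, "P225": _CELL_FIELDS,
                 "C600": _ALL_FIELDS, "C2500": _CELL_FIELDS},
                ordering=(("E150", "E90"), ("P225", "P175"), ("C2500", "C600"))),
        FitStep("eshap", (29,),
                {"ET40": _CELL_FIELDS, "Cyta": _ALL_FIELDS, "Cisp": _ALL_FIELDS}),
    )


def stepwise_protocol(
    steps: Sequence[FitStep],
    data: Mapping[int, ObservedSeries],
    initial: Mapping[str, ToxicityParameterSet] | None = None,
    frozen: Mapping[str, ToxicityParameterSet] | None = None,
    params: CellKineticParameters | None = None,
    solver: SolverSettings | None = None,
    seed: int = 0,
    es_options: EsOptions = EsOptions(),
    regimen_factory: Callable[[int], Regimen] = scenario_regimen,
) -> dict[str, FitResult]:
    """Execute a staged protocol, freezing each step's estimates.

    ``data`` maps scenario ids to observed series; every step's scenarios
    must be present and must not be validation scenarios.  ``initial``
    defaults to the shipped reference table (templates for fixed fields).
    """
    initial = dict(initial or load_toxicity_table())
    frozen_sets: dict[str, ToxicityParameterSet] = dict(frozen or {})
    results: dict[str, FitResult] = {}
    for step in steps:
        bad = sorted(set(step.scenario_ids) & set(VALIDATION_SCENARIOS))
        if bad:
            raise ValueError(f"step {step.name} uses validation scenarios {bad}")
        missing = [i for i in step.scenario_ids if i not in data]
        if missing:
            raise ValueError(f"step {step.name}: no data for scenarios {missing}")
        for upper, lower in step.ordering:
            if lower not in frozen_sets and lower not in step.free and lower not in initial:
                raise ValueError(
                    f"step {step.name}: ordering references unfitted set {lower!r}"
                )
        scenarios = [
            FitScenario(regimen=regimen_factory(i), series=data[i])
            for i in step.scenario_ids
        ]
        result = fit_toxicity(
            scenarios,
            free=step.free,
            initial=initial,
            frozen=frozen_sets,
            ordering=step.ordering,
            params=params,
            solver=solver,
            seed=seed,
            es_options=es_options,
        )
        for label in step.free:
            frozen_sets[label] = result.sets[label]
        results[step.name] = result
    return results


# ---------------------------------------------------------------------------
# observed-series files
# ---------------------------------------------------------------------------

def read_observed_csv(path) -> list[ObservedSeries]:
    """Read day/value series from CSV (day, value, unit, scenario_id, count_type)."""
    frame = pd.read_csv(path)
    required = {"day", "value", "scenario_id", "count_type"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"observed-series file missing columns {sorted(missing)}")
    series = []
    for (sid, ctype), grp in frame.groupby(["scenario_id", "count_type"], sort=True):
        grp = grp.sort_values("day")
        series.append(
            ObservedSeries(
                days=tuple(grp["day"]),
                values=tuple(grp["value"]),
                count_type=str(ctype),
                scenario_id=str(sid),
                unit=str(grp["unit"].iloc[0]) if "unit" in grp else "cells/ul",
            )
        )
    return series


def write_observed_csv(series: Iterable[ObservedSeries], path) -> None:
    rows = []
    for s in series:
        for day, value in zip(s.days, s.values):
            rows.append(
                {
                    "day": day,
                    "value": value,
                    "unit": s.unit,
                    "scenario_id": s.scenario_id,
                    "count_type": s.count_type,
                }
            )
    pd.DataFrame(rows, columns=["day", "value", "unit", "scenario_id", "count_type"]).to_csv(
        path, index=False
    )
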