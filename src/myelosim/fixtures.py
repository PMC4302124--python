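"""Synthetic clinic-like median series and named qualitative scenarios.

Clinical granulotoxicity data are medians of blood counts sampled at clinic
visits; cell counts are approximately log-normally distributed.  The
generator emulates this: it simulates the model for a known parameter set,
samples the requested count at visit days (three visits per week by
default) and applies multiplicative log-normal noise with a detection
floor.  Every fixture is a pure function of its configuration and seed, so
estimation and validation are testable without any clinical download.

The qualitative suite bundles the three classic single-application
experiments for the elderly-CHOP parameter set — toxicity restricted to
stem cells, restricted to the mitotic precursors (PGB), and on all stages —
ready to simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemo_toxicity import ToxicityParameterSet, load_toxicity_table
from .estimation import ObservedSeries
from .model_core import CellKineticParameters
from .regimens import CycleAgent, Regimen
from .sim_engine import SimulationResult, SolverSettings, simulate

__all__ = [
    "NoiseModel",
    "default_sampling_days",
    "generate_observed",
    "StageKillScenario",
    "stage_kill_suite",
]


def default_sampling_days(horizon_days: float) -> tuple[float, ...]:
    """Clinic-visit pattern: three visits per week (days 1, 3, 5 of each week)."""
    days = []
    week = 0
    while True:
        for offset in (1.0, 3.0, 5.0):
            day = 7.0 * week + offset
            if day > horizon_days:
                return tuple(days)
            days.append(day)
        week += 1


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal sampling noise at clinic-visit days."""

    sigma: float = 0.2                 # log-scale standard deviation
    sampling_days: tuple[float, ...] | None = None
    floor_per_ul: float = 50.0         # detection floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.floor_per_ul <= 0:
            raise ValueError("detection floor must be positive")


def generate_observed(
    regimen: Regimen,
    toxicity: dict[str, ToxicityParameterSet] | None = None,
    params: CellKineticParameters | None = None,
    noise: NoiseModel = NoiseModel(),
    count_type: str = "WBC",
    horizon_days: float | None = None,
    solver: SolverSettings | None = None,
    result: SimulationResult | None = None,
) -> ObservedSeries:
    """Simulate and sample a clinic-like median series.

    ``sigma = 0`` returns the model curve exactly at the sampling days.  A
    precomputed ``result`` may be passed to draw many noise replicates from
    one simulation.
    """
    horizon = float(horizon_days if horizon_days is not None else regimen.horizon_days)
    if result is None:
        result = simulate(
            regimen, toxicity=toxicity, params=params,
            horizon_days=horizon, solver=solver,
        )
    days = noise.sampling_days or default_sampling_days(horizon)
    if max(days) > result.time_day[-1] + 1e-9 or min(days) < result.time_day[0] - 1e-9:
        raise ValueError("sampling days outside the simulated horizon")
    curve = np.interp(days, result.time_day, result.curve(count_type))
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        curve = curve * np.exp(rng.normal(0.0, noise.sigma, size=len(days)))
    curve = np.maximum(curve, noise.floor_per_ul)
    return ObservedSeries(
        days=tuple(days),
        values=tuple(curve),
        count_type=count_type,
        scenario_id=f"synthetic-{regimen.name}",
    )


@dataclass(frozen=True)
class StageKillScenario:
    """A single-application qualitative experiment ready to simulate."""

    name: str
    regimen: Regimen
    toxicity: dict[str, ToxicityParameterSet] = field(default_factory=dict)

    def run(self, params: CellKineticParameters | None = None,
            horizon_days: float = 100.0,
            solver: SolverSettings | None = None) -> SimulationResult:
        return simulate(
            self.regimen, toxicity=self.toxicity, params=params,
            horizon_days=horizon_days, solver=solver,
        )


def _single_chop_regimen(horizon_days: float = 100.0) -> Regimen:
    return Regimen(
        name="single-CHOP-elderly",
        cycle_days=int(horizon_days),
        n_cycles=1,
        agents=(
            CycleAgent(drug="CHOP-combination", days=(1,), toxicity_label="CHOPo"),
        ),
        risk_group="elderly",
    )


def stage_kill_suite() -> dict[str, StageKillScenario]:
    """Three single-application CHOP (elderly) experiments.

    ``stem_cell_only`` zeroes every coefficient except the stem-cell one,
    ``pgb_only`` keeps only the mitotic-precursor coefficient, and
    ``all_stages`` is the unmodified parameter set.
    """
    base = load_toxicity_table()["CHOPo"]
    regimen = _single_chop_regimen()
    return {
        "stem_cell_only": StageKillScenario(
            "stem_cell_only", regimen, {"CHOPo": base.restricted(["S"])}
        ),
        "pgb_only": StageKillScenario(
            "pgb_only", regimen, {"CHOPo": base.restricted(["PGB"])}
        ),
        "all_stages": StageKillScenario("all_stages", regimen, {"CHOPo": base}),
    }
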