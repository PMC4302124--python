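"""Coupled ODE system and integrator for treatment simulations.

The full model is a cascade: the chemotherapy delay chains are autonomous
(driven only by the piecewise-constant injection pulses), while the cell
compartments and the G-CSF pharmacokinetics feed back on each other.  The
engine exploits this triangular structure and integrates in two phases:

1. the per-drug delay chains (4 marrow + 4 lymphocyte stages per drug) over
   the infusion-edge segments, with dense output, yielding the toxicity
   forcing ``Psi_total^X(t)`` and ``Psi_LY(t)``;
2. the nine-dimensional cell/PK system, with the toxicity forcing evaluated
   from phase 1, restarted at every event time (infusion edges, G-CSF
   boluses, prednisone coverage edges, first-cycle switch) so the right-hand
   side stays piecewise smooth.

Because phase 1 does not depend on the G-CSF schedule, alternative G-CSF
variants of one chemotherapy backbone share bit-identical toxicity traces.
All integration is adaptive LSODA (relative tolerance 1e-6, absolute 1e-9
by default); no analytic shortcut is taken for the chains.
"""

from __future__ import annotations

import bisect
import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model_core
from .chemo_toxicity import (
    DrugApplication,
    ToxicityParameterSet,
    load_toxicity_table,
    prednisone_windows,
)
from .model_core import CellKineticParameters, COMPARTMENTS
from .regimens import (
    DEFAULT_BODY_MASS_KG,
    GcsfInjection,
    Regimen,
    drug_applications,
    prednisone_applications,
)

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "SimulationError",
    "simulate",
    "simulate_gcsf_variants",
]


class SimulationError(RuntimeError):
    """Solver failure with diagnostic context."""


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1.0e-6
    atol: float = 1.0e-9
    method: str = "LSODA"
    grid_step_day: float = 0.1

    def scaled(self, factor: float) -> "SolverSettings":
        return replace(self, rtol=self.rtol * factor, atol=self.atol * factor)


# ---------------------------------------------------------------------------
# phase 1: delay chains
# ---------------------------------------------------------------------------

@dataclass
class _Agent:
    label: str
    params: ToxicityParameterSet
    application: DrugApplication

    @property
    def t2_h(self) -> float:
        return self.application.second_application_h

    def fc_factor(self, t_h: float) -> float:
        return self.params.first_cycle_factor if t_h < self.t2_h else 1.0


class ChainSolution:
    """Dense numerical solution of all delay chains over the horizon."""

    def __init__(self, agents: Sequence[_Agent], horizon_h: float, solver: SolverSettings):
        self.agents = list(agents)
        self.horizon_h = float(horizon_h)
        edges = {0.0, self.horizon_h}
        for agent in self.agents:
            for t_i in agent.application.times_h:
                if t_i < self.horizon_h:
                    edges.add(t_i)
                    edges.add(min(t_i + agent.application.infusion_h, self.horizon_h))
        self.breakpoints = sorted(edges)
        self._solutions = []
        y = np.zeros(8 * len(self.agents))
        for t0, t1 in zip(self.breakpoints[:-1], self.breakpoints[1:]):
            pulses = [
                sum(
                    1.0 / a.application.infusion_h
                    for t_i in a.application.times_h
                    if t_i <= 0.5 * (t0 + t1) < t_i + a.application.infusion_h
                )
                for a in self.agents
            ]
            sol = solve_ivp(
                self._rhs,
                (t0, t1),
                y,
                args=(np.asarray(pulses),),
                method=solver.method,
                rtol=solver.rtol,
                atol=solver.atol,
                dense_output=True,
            )
            if not sol.success:
                raise SimulationError(f"delay-chain integration failed at t={t0 / 24:.2f} d")
            self._solutions.append(sol.sol)
            y = sol.y[:, -1]

    def _rhs(self, t: float, y: np.ndarray, pulses: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        for j, agent in enumerate(self.agents):
            k = agent.params.k_delay_per_h
            kw = agent.params.k_delay_wbc_per_h
            m = y[8 * j : 8 * j + 4]
            w = y[8 * j + 4 : 8 * j + 8]
            out = k * m
            dy[8 * j] = pulses[j] - out[0]
            dy[8 * j + 1 : 8 * j + 4] = out[:3] - out[1:]
            if kw is None:
                dy[8 * j + 4 : 8 * j + 8] = 0.0
            else:
                wout = kw * w
                dy[8 * j + 4] = pulses[j] - wout[0]
                dy[8 * j + 5 : 8 * j + 8] = wout[:3] - wout[1:]
        return dy

    def states(self, t_h: float) -> np.ndarray:
        t = min(max(t_h, 0.0), self.horizon_h)
        idx = bisect.bisect_right(self.breakpoints, t) - 1
        idx = min(max(idx, 0), len(self._solutions) - 1)
        return self._solutions[idx](t)

    def loss_rates(self, t_h: float) -> tuple[np.ndarray, float]:
        """(per-compartment loss rates S,CG,PGB,MGB,GRA in 1/h, Psi_LY)."""
        y = self.states(t_h)
        loss = np.zeros(5)
        psi_ly = 0.0
        for j, agent in enumerate(self.agents):
            p = agent.params
            fc = agent.fc_factor(t_h)
            out4 = p.k_delay_per_h * max(y[8 * j + 3], 0.0)
            loss[0] += fc * p.k_s * out4
            loss[1] += fc * p.k_cg * out4
            loss[2] += fc * p.k_pgb * out4
            loss[3] += fc * p.k_mgb * out4
            if p.k_ly is not None:
                psi_ly += fc * p.k_ly * p.k_delay_wbc_per_h * max(y[8 * j + 7], 0.0)
        return loss, psi_ly

    def psi_out(self, t_grid_h: np.ndarray) -> dict[str, np.ndarray]:
        """Marrow-chain output rate Psi_out^(4) per drug on a time grid."""
        traces = {a.label: np.empty_like(t_grid_h, dtype=float) for a in self.agents}
        for i, t in enumerate(t_grid_h):
            y = self.states(t)
            for j, a in enumerate(self.agents):
                traces[a.label][i] = a.params.k_delay_per_h * max(y[8 * j + 3], 0.0)
        return traces


# ---------------------------------------------------------------------------
# phase 2: cells + PK
# ---------------------------------------------------------------------------

class _FastEffects:
    """Precomputed Hill-curve constants for the integration hot loop."""

    def __init__(self, params: CellKineticParameters):
        c_star = params.steady_state_gcsf_pg_ml
        self.rows = []
        for name in model_core.REGULATED_QUANTITIES:
            e = params.effects[name]
            self.rows.append(
                (
                    1.0 if e.direction == "up" else -1.0,
                    e.minimum,
                    e.maximum,
                    e.half_fil(c_star),
                    e.hill_fil,
                    e.half_peg_pg_ml,
                    e.hill_peg,
                )
            )

    def values(self, c_fil: float, c_peg: float) -> tuple[float, float, float, float]:
        out = []
        cf = max(c_fil, 0.0)
        cp = max(c_peg, 0.0)
        for sign, lo, hi, bf, hf, bp, hp in self.rows:
            s = (cf / bf) ** hf
            if cp > 0.0:
                s += (cp / bp) ** hp
            h = s / (1.0 + s)
            out.append(lo + (hi - lo) * h if sign > 0 else hi - (hi - lo) * h)
        return tuple(out)


@dataclass
class SimulationResult:
    """Dense trajectories of one treatment simulation.

    Normalized compartments have steady state 1; absolute counts are scaled
    by the configured steady-state ANC and the constant lymphocyte baseline.
    """

    time_day: np.ndarray
    cells: np.ndarray                     # (5, N) normalized S..GRA
    fil_conc_pg_ml: np.ndarray
    peg_conc_pg_ml: np.ndarray
    psi_ly: np.ndarray
    psi_out: dict[str, np.ndarray]
    params: CellKineticParameters
    provenance: dict = field(default_factory=dict)

    @property
    def anc_per_ul(self) -> np.ndarray:
        return self.cells[4] * self.params.steady_state_anc_per_ul

    @property
    def wbc_per_ul(self) -> np.ndarray:
        c_ly = self.params.lymphocyte_baseline_per_ul
        return self.anc_per_ul + c_ly * np.exp(-self.psi_ly)

    @property
    def wbc_baseline_per_ul(self) -> float:
        return self.params.steady_state_anc_per_ul + self.params.lymphocyte_baseline_per_ul

    def curve(self, name: str) -> np.ndarray:
        """Named trajectory: a compartment, ANC/WBC (absolute or _norm), GCSF."""
        key = name.upper()
        if key in COMPARTMENTS:
            return self.cells[COMPARTMENTS.index(key)]
        if key == "ANC":
            return self.anc_per_ul
        if key == "WBC":
            return self.wbc_per_ul
        if key == "ANC_NORM":
            return self.cells[4]
        if key == "WBC_NORM":
            return self.wbc_per_ul / self.wbc_baseline_per_ul
        if key == "GCSF":
            return self.fil_conc_pg_ml + self.peg_conc_pg_ml
        raise KeyError(f"unknown curve {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (time_day, variable, value, unit)."""
        blocks = []
        named = {
            "S": (self.cells[0], "normalized"),
            "CG": (self.cells[1], "normalized"),
            "PGB": (self.cells[2], "normalized"),
            "MGB": (self.cells[3], "normalized"),
            "GRA": (self.cells[4], "normalized"),
            "ANC": (self.anc_per_ul, "cells/ul"),
            "WBC": (self.wbc_per_ul, "cells/ul"),
            "GCSF_fil": (self.fil_conc_pg_ml, "pg/ml"),
            "GCSF_peg": (self.peg_conc_pg_ml, "pg/ml"),
        }
        for var, (vals, unit) in named.items():
            blocks.append(
                pd.DataFrame(
                    {"time_day": self.time_day, "variable": var, "value": vals, "unit": unit}
                )
            )
        return pd.concat(blocks, ignore_index=True)

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            for key, value in sorted(self.provenance.items()):
                fh.write(f"# {key}: {value}\n")
            frame.to_csv(fh, index=False)


_HASH_CACHE: dict[int, str] = {}


def _params_hash(params: CellKineticParameters) -> str:
    key = id(params)
    if key not in _HASH_CACHE:
        import yaml as _yaml

        _HASH_CACHE[key] = hashlib.md5(
            _yaml.safe_dump(params.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
    return _HASH_CACHE[key]


def _resolve_toxicity(
    regimen: Regimen, toxicity: dict[str, ToxicityParameterSet] | None
) -> list[_Agent]:
    table = dict(load_toxicity_table())
    if toxicity:
        table.update(toxicity)
    agents = []
    for label, application in drug_applications(regimen).items():
        if label not in table:
            raise KeyError(
                f"no toxicity parameter set for label {label!r}; "
                "pass one via the toxicity mapping"
            )
        agents.append(_Agent(label=label, params=table[label], application=application))
    return agents


def simulate(
    regimen: Regimen,
    toxicity: dict[str, ToxicityParameterSet] | None = None,
    params: CellKineticParameters | None = None,
    horizon_days: float | None = None,
    solver: SolverSettings | None = None,
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
    _chains: ChainSolution | None = None,
) -> SimulationResult:
    """Integrate the coupled model over the study horizon.

    Deterministic given inputs and settings.  The output grid is dense
    (``solver.grid_step_day``) with every event time included exactly.
    """
    params = params or CellKineticParameters.default()
    solver = solver or SolverSettings()
    horizon_days = float(horizon_days if horizon_days is not None else regimen.horizon_days)
    horizon_h = 24.0 * horizon_days

    agents = _resolve_toxicity(regimen, toxicity)
    chains = _chains
    if chains is None:
        chains = ChainSolution(agents, horizon_h, solver)

    # prednisone coverage and clearance multiplier
    pred_mult = params.prednisone_clearance_multiplier
    windows: list[tuple[float, float]] = []
    for app in prednisone_applications(regimen):
        windows.extend(prednisone_windows(app, washout_h=0.0))
    # merge overlapping coverage windows
    merged: list[tuple[float, float]] = []
    for start, end in sorted(windows):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    windows = merged

    # G-CSF boluses
    boluses: list[tuple[float, str, float]] = []
    for inj in regimen.gcsf:
        for cycle in range(1, regimen.n_cycles + 1):
            if inj.cycles is not None and cycle not in inj.cycles:
                continue
            for day in inj.days:
                t_h = 24.0 * ((cycle - 1) * regimen.cycle_days + (day - 1)) + 8.0
                if t_h < horizon_h:
                    boluses.append((t_h, inj.derivative, inj.dose_ug(body_mass_kg)))
    boluses.sort()

    # integration breakpoints
    edges = set(chains.breakpoints)
    edges.update(t for t, _, _ in boluses)
    for start, end in windows:
        edges.add(start)
        edges.add(min(end, horizon_h))
    for agent in agents:
        if agent.t2_h < horizon_h:
            edges.add(agent.t2_h)
    edges.add(0.0)
    edges.add(horizon_h)
    breakpoints = sorted(t for t in edges if 0.0 <= t <= horizon_h)

    effects = _FastEffects(params)
    pk_f = params.gcsf_pk["fil"]
    pk_p = params.gcsf_pk["peg"]
    to_conc_f = 1.0e6 / pk_f.volume_ml
    to_conc_p = 1.0e6 / pk_p.volume_ml
    stem = params.stem
    beta = (stem.renewal_max - 0.5) / (0.5 - stem.renewal_min)
    t_cg = params.transit_h["CG"]
    t_pgb_base = params.transit_h["PGB"]
    t_mgb_base = params.transit_h["MGB"]
    t_gra = params.transit_h["GRA"]
    amp_base = params.amplification["PGB"]
    d_mgb_base = params.mgb_apoptosis_per_h
    mgb_out_base = 1.0 / t_mgb_base + d_mgb_base
    prod0 = params.endogenous_production_pg_ml_h
    theta = params.endogenous_demand_gain

    def rhs(t: float, y: np.ndarray, gra_mult: float) -> np.ndarray:
        s, cg, pgb, mgb, gra = np.maximum(y[:5], 0.0)
        dep_f, c_f, dep_p, c_p = y[5], max(y[6], 0.0), y[7], max(y[8], 0.0)
        tox, _ = chains.loss_rates(t)

        amp, t_pgb, t_mgb, d_mgb = effects.values(c_f, c_p)
        a = stem.renewal_min + (stem.renewal_max - stem.renewal_min) / (
            1.0 + beta * s**stem.renewal_hill
        )
        commit = 2.0 * s * (1.0 - a)
        dy = np.empty(9)
        dy[0] = stem.proliferation_per_h * s * (2.0 * a - 1.0) - tox[0] * s
        dy[1] = (commit - cg) / t_cg - tox[1] * cg
        dy[2] = (amp / amp_base) * cg / t_pgb_base - pgb / t_pgb - tox[2] * pgb
        pgb_efflux_rel = pgb * t_pgb_base / t_pgb
        dy[3] = mgb_out_base * pgb_efflux_rel - mgb * (1.0 / t_mgb + d_mgb) - tox[3] * mgb
        mat_rel = mgb * t_mgb_base / t_mgb
        dy[4] = mat_rel / t_gra - gra * gra_mult / t_gra - tox[4] * gra

        dy[5] = -pk_f.ka_per_h * dep_f
        dy[6] = (
            pk_f.ka_per_h * dep_f * to_conc_f
            + prod0 * (1.0 + theta) / (1.0 + theta * gra)
            - c_f * pk_f.elimination_rate(c_f, gra)
        )
        dy[7] = -pk_p.ka_per_h * dep_p
        dy[8] = pk_p.ka_per_h * dep_p * to_conc_p - c_p * pk_p.elimination_rate(c_p, gra)
        return dy

    y = np.zeros(9)
    y[:5] = 1.0
    y[6] = params.steady_state_gcsf_pg_ml

    grid = np.unique(
        np.concatenate(
            [
                np.arange(0.0, horizon_h + 1e-9, solver.grid_step_day * 24.0),
                np.asarray(breakpoints),
                [horizon_h],
            ]
        )
    )
    grid = grid[(grid >= 0.0) & (grid <= horizon_h)]

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    bolus_idx = 0
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        while bolus_idx < len(boluses) and abs(boluses[bolus_idx][0] - t0) < 1e-9:
            _, deriv, dose_ug = boluses[bolus_idx]
            if deriv == "fil":
                y[5] += pk_f.bioavailability * dose_ug
            else:
                y[7] += pk_p.bioavailability * dose_ug
            bolus_idx += 1
        mid = 0.5 * (t0 + t1)
        gra_mult = pred_mult if any(a <= mid < b for a, b in windows) else 1.0
        seg_grid = grid[(grid >= t0) & (grid <= t1)]
        t_eval = np.unique(np.concatenate([[t0], seg_grid, [t1]]))
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            args=(gra_mult,),
            method=solver.method,
            rtol=solver.rtol,
            atol=solver.atol,
            t_eval=t_eval,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed at t={t0 / 24.0:.2f} d; state={y}; message={sol.message}"
            )
        times.append(sol.t)
        states.append(sol.y)
        y = sol.y[:, -1].copy()

    t_all = np.concatenate(times)
    y_all = np.concatenate(states, axis=1)
    t_out, keep = np.unique(t_all, return_index=True)
    y_out = y_all[:, keep]

    psi_ly = np.array([chains.loss_rates(t)[1] for t in t_out])
    result = SimulationResult(
        time_day=t_out / 24.0,
        cells=np.maximum(y_out[:5], 0.0),
        fil_conc_pg_ml=np.maximum(y_out[6], 0.0),
        peg_conc_pg_ml=np.maximum(y_out[8], 0.0),
        psi_ly=psi_ly,
        psi_out=chains.psi_out(t_out),
        params=params,
        provenance={
            "regimen": regimen.name,
            "params_hash": _params_hash(params),
            "solver": f"{solver.method} rtol={solver.rtol} atol={solver.atol}",
            "horizon_days": horizon_days,
            "body_mass_kg": body_mass_kg,
        },
    )
    return result


def simulate_gcsf_variants(
    regimen: Regimen,
    variants: Iterable[Sequence[GcsfInjection]],
    toxicity: dict[str, ToxicityParameterSet] | None = None,
    params: CellKineticParameters | None = None,
    horizon_days: float | None = None,
    solver: SolverSettings | None = None,
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
) -> list[SimulationResult]:
    """Simulate G-CSF schedule variants over one chemotherapy backbone.

    The delay-chain forcing is computed once and shared, so the chemotherapy
    toxicity traces are bit-identical across variants.
    """
    params = params or CellKineticParameters.default()
    solver = solver or SolverSettings()
    horizon = float(horizon_days if horizon_days is not None else regimen.horizon_days)
    agents = _resolve_toxicity(regimen.without_gcsf(), toxicity)
    chains = ChainSolution(agents, 24.0 * horizon, solver)
    results = []
    for variant in variants:
        results.append(
            simulate(
                regimen.with_gcsf(tuple(variant)),
                toxicity=toxicity,
                params=params,
                horizon_days=horizon,
                solver=solver,
                body_mass_kg=body_mass_kg,
                _chains=chains,
            )
        )
    return results
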