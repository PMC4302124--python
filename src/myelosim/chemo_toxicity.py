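"""Phenomenological chemotherapy toxicity model.

Each drug (or inseparable drug combination) damages the bone marrow through
a common pipeline:

1. an injection pulse ``CHEMO(t)``: rectangular, amplitude ``1/t_inf`` during
   each infusion, so every injection carries unit area;
2. a chain of four concatenated first-order transitions (an Erlang-4 filter
   with rate ``k_delay``) that delays the damage maximum by ``3/k`` hours
   while conserving area;
3. cell-stage-specific toxicity coefficients ``K_X`` that convert the chain
   output into first-order loss rates for S, CG, PGB and MGB, with the first
   application of a drug amplified by a factor ``f_fc >= 1`` (first-cycle
   effect);
4. pointwise addition over drugs (no interaction between agents).

Lymphocytes are not modelled dynamically; their depletion enters the white
count as ``WBC = ANC + C_LY * exp(-Psi_LY)`` with a constant baseline
``C_LY = 3000/ul``.  ``Psi_LY`` is built from a second, slower delay chain
per drug (rate ``k_delay_wbc``) scaled by the drug's ``k_ly`` coefficient.
The chain *state* (dimensionless, since the pulse input has units 1/h) is
used in the exponent; the marrow loss rates use the chain *output* (1/h).

Prednisone-like drugs carry no cytotoxicity; they transiently prolong the
neutrophil blood half-life (a clearance multiplier < 1 during coverage).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToxicityParameterSet",
    "DrugApplication",
    "chemo_pulse",
    "delay_chain_rhs",
    "erlang4_impulse_response",
    "toxicity_function",
    "combine_toxicities",
    "wbc_from_anc",
    "prednisone_effect",
    "load_toxicity_table",
    "toxicity_table_frame",
]

MARROW_STAGES = ("S", "CG", "PGB", "MGB")

_TABLE_COLUMNS = [
    "label",
    "description",
    "context",
    "first_cycle_factor",
    "k_delay_per_h",
    "k_s",
    "k_cg",
    "k_pgb",
    "k_mgb",
    "k_delay_wbc_per_h",
    "k_ly",
]


@dataclass(frozen=True)
class ToxicityParameterSet:
    """The eight toxicity parameters characterizing one drug/combination.

    ``k_delay_wbc_per_h`` and ``k_ly`` may be ``None`` for parameter sets
    estimated from neutrophil data only (no lymphocyte toxicity modelled).
    """

    label: str
    first_cycle_factor: float
    k_delay_per_h: float
    k_s: float
    k_cg: float
    k_pgb: float
    k_mgb: float
    k_delay_wbc_per_h: float | None = None
    k_ly: float | None = None
    description: str = ""
    context: str = ""

    def __post_init__(self) -> None:
        if self.first_cycle_factor < 1.0:
            raise ValueError(
                f"{self.label}: first-cycle factor must be >= 1, got {self.first_cycle_factor}"
            )
        if self.k_delay_per_h <= 0:
            raise ValueError(f"{self.label}: delay rate must be positive")
        for name in ("k_s", "k_cg", "k_pgb", "k_mgb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.label}: {name} must be non-negative")
        if (self.k_ly is None) != (self.k_delay_wbc_per_h is None):
            raise ValueError(f"{self.label}: k_ly and k_delay_wbc_per_h must come together")
        if self.k_ly is not None:
            if self.k_ly < 0 or self.k_delay_wbc_per_h <= 0:
                raise ValueError(f"{self.label}: invalid lymphocyte toxicity parameters")

    @property
    def has_lymphocyte_toxicity(self) -> bool:
        return self.k_ly is not None

    def coefficient(self, compartment: str) -> float:
        try:
            return {
                "S": self.k_s,
                "CG": self.k_cg,
                "PGB": self.k_pgb,
                "MGB": self.k_mgb,
            }[compartment]
        except KeyError:
            raise ValueError(f"unknown marrow compartment {compartment!r}") from None

    def scaled(self, factor: float) -> "ToxicityParameterSet":
        """All cell-stage coefficients multiplied by ``factor``."""
        return replace(
            self,
            k_s=self.k_s * factor,
            k_cg=self.k_cg * factor,
            k_pgb=self.k_pgb * factor,
            k_mgb=self.k_mgb * factor,
            k_ly=None if self.k_ly is None else self.k_ly * factor,
        )

    def restricted(self, stages: Iterable[str]) -> "ToxicityParameterSet":
        """Keep the coefficients of ``stages``; zero every other stage."""
        keep = set(stages)
        unknown = keep - set(MARROW_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        return replace(
            self,
            k_s=self.k_s if "S" in keep else 0.0,
            k_cg=self.k_cg if "CG" in keep else 0.0,
            k_pgb=self.k_pgb if "PGB" in keep else 0.0,
            k_mgb=self.k_mgb if "MGB" in keep else 0.0,
        )


@dataclass(frozen=True)
class DrugApplication:
    """Applications of one drug in absolute study time.

    ``times_day`` are infusion start times (days); ``infusion_h`` is the
    infusion duration.  ``cytotoxic=False`` marks prednisone-like drugs.
    """

    drug: str
    times_day: tuple[float, ...]
    infusion_h: float = 1.0
    dose: float | None = None
    dose_unit: str = "mg/m2"
    cytotoxic: bool = True

    def __post_init__(self) -> None:
        if self.infusion_h <= 0:
            raise ValueError("infusion duration must be positive")
        times = tuple(float(t) for t in self.times_day)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("application times must be strictly increasing")
        object.__setattr__(self, "times_day", times)

    @property
    def times_h(self) -> tuple[float, ...]:
        return tuple(24.0 * t for t in self.times_day)

    @property
    def second_application_h(self) -> float:
        """Start of the drug's second application (inf for single-shot drugs).

        The first-cycle amplification applies before this time.
        """
        if len(self.times_day) < 2:
            return math.inf
        return self.times_h[1]


def chemo_pulse(application: DrugApplication, t_h: float) -> float:
    """Injection pulse rate (1/h) at time ``t_h`` (hours).

    Rectangular: ``1/t_inf`` inside any ``[t_i, t_i + t_inf)`` window, zero
    elsewhere, so each injection integrates to exactly one.
    """
    for t_i in application.times_h:
        if t_i <= t_h < t_i + application.infusion_h:
            return 1.0 / application.infusion_h
    return 0.0


def delay_chain_rhs(
    chain_state: Sequence[float], input_rate: float, k_delay: float
) -> tuple[np.ndarray, float]:
    """Derivatives of the four-stage delay chain and its output rate.

    Stage 1 is fed by the pulse rate itself; each stage feeds the next with
    ``k_delay * state``.  The chain is linear and area-conserving, so the
    output of stage 4 integrates to the number of injections.
    """
    if k_delay <= 0:
        raise ValueError(f"delay rate must be positive, got {k_delay}")
    psi = np.asarray(chain_state, dtype=float)
    if psi.shape != (4,):
        raise ValueError("chain state must have four stages")
    out = k_delay * psi
    deriv = np.empty(4)
    deriv[0] = input_rate - out[0]
    deriv[1:] = out[:3] - out[1:]
    return deriv, float(out[3])


def erlang4_impulse_response(t_h: np.ndarray | float, k_delay: float) -> np.ndarray | float:
    """Closed-form impulse response of the chain: Erlang-4 density.

    ``k (k t)^3 exp(-k t) / 3!`` — the analytic oracle for the integrated
    chain; its peak sits at ``t = 3/k``.
    """
    t = np.asarray(t_h, dtype=float)
    out = np.where(t >= 0, k_delay * (k_delay * t) ** 3 * np.exp(-k_delay * t) / 6.0, 0.0)
    return out if out.ndim else float(out)


def toxicity_function(
    params: ToxicityParameterSet,
    compartment: str,
    chain_output: float,
    t_h: float,
    t_second_application_h: float = math.inf,
) -> float:
    """Cell-loss rate for one drug and marrow stage (1/h).

    ``K_X(t) * chain_output`` with the first-cycle amplification applied
    while ``t`` precedes the drug's second application (drugs applied once
    keep the amplification throughout).
    """
    if chain_output < 0:
        raise ValueError("chain output must be non-negative")
    k = params.coefficient(compartment)
    if t_h < t_second_application_h:
        k *= params.first_cycle_factor
    return k * chain_output


def combine_toxicities(per_drug: Iterable[float]) -> float:
    """Total loss rate: pointwise sum over drugs (no interactions)."""
    total = 0.0
    for value in per_drug:
        if value < 0:
            raise ValueError("toxicity contributions must be non-negative")
        total += value
    return total


def wbc_from_anc(anc_per_ul: float, psi_ly: float, c_ly_per_ul: float = 3000.0) -> float:
    """White count from neutrophils and the lymphocyte depletion exponent.

    ``WBC = ANC + C_LY * exp(-Psi_LY)``; ``Psi_LY = 0`` reproduces the
    normal lymphocyte concentration, large ``Psi_LY`` removes it entirely.
    """
    if anc_per_ul < 0 or psi_ly < 0:
        raise ValueError("ANC and Psi_LY must be non-negative")
    return anc_per_ul + c_ly_per_ul * math.exp(-psi_ly)


def prednisone_effect(
    application: DrugApplication,
    t_h: float,
    multiplier: float = 0.7,
    washout_h: float = 24.0,
) -> float:
    """Granulocyte-clearance multiplier under prednisone-like coverage.

    Returns ``multiplier`` (<= 1) while any application day (plus washout)
    covers ``t``, and 1 otherwise.  Raises for cytotoxic drugs: this effect
    exists only for the non-cytotoxic corticosteroid components.
    """
    if application.cytotoxic:
        raise ValueError(f"{application.drug} is cytotoxic; prednisone effect undefined")
    if not (0 < multiplier <= 1):
        raise ValueError("multiplier must be in (0, 1]")
    for t_i in application.times_h:
        if t_i <= t_h < t_i + application.infusion_h + washout_h:
            return multiplier
    return 1.0


def prednisone_windows(
    application: DrugApplication, washout_h: float = 24.0
) -> list[tuple[float, float]]:
    """Merged absolute-time (hours) coverage windows of a prednisone course."""
    if application.cytotoxic:
        raise ValueError(f"{application.drug} is cytotoxic; prednisone effect undefined")
    raw = [
        (t_i, t_i + application.infusion_h + washout_h) for t_i in application.times_h
    ]
    merged: list[tuple[float, float]] = []
    for start, end in sorted(raw):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def toxicity_table_frame(path=None) -> pd.DataFrame:
    """The shipped toxicity-parameter reference table as a DataFrame."""
    if path is None:
        text = resources.files("myelosim.data").joinpath("toxicity_table.csv").read_text()
        frame = pd.read_csv(io.StringIO(text))
    else:
        frame = pd.read_csv(path)
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"toxicity table missing columns: {sorted(missing)}")
    return frame


def load_toxicity_table(path=None) -> dict[str, ToxicityParameterSet]:
    """Load the reference table (or a user table) keyed by drug label."""
    frame = toxicity_table_frame(path)
    table: dict[str, ToxicityParameterSet] = {}
    for row in frame.itertuples(index=False):
        has_wbc = pd.notna(row.k_ly) and pd.notna(row.k_delay_wbc_per_h)
        table[row.label] = ToxicityParameterSet(
            label=row.label,
            first_cycle_factor=float(row.first_cycle_factor),
            k_delay_per_h=float(row.k_delay_per_h),
            k_s=float(row.k_s),
            k_cg=float(row.k_cg),
            k_pgb=float(row.k_pgb),
            k_mgb=float(row.k_mgb),
            k_delay_wbc_per_h=float(row.k_delay_wbc_per_h) if has_wbc else None,
            k_ly=float(row.k_ly) if has_wbc else None,
            description=str(row.description),
            context=str(row.context),
        )
    return table


def save_toxicity_table(table: dict[str, ToxicityParameterSet], path) -> None:
    """Write a parameter table in the packaged CSV layout (round-trippable)."""
    rows = []
    for s in table.values():
        rows.append(
            {
                "label": s.label,
                "description": s.description,
                "context": s.context,
                "first_cycle_factor": s.first_cycle_factor,
                "k_delay_per_h": s.k_delay_per_h,
                "k_s": s.k_s,
                "k_cg": s.k_cg,
                "k_pgb": s.k_pgb,
                "k_mgb": s.k_mgb,
                "k_delay_wbc_per_h": s.k_delay_wbc_per_h,
                "k_ly": s.k_ly,
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False)
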