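"""Granulopoiesis compartment model with G-CSF feedback.

The model follows human granulopoiesis through five cell compartments —
haematopoietic stem cells (S), committed granulopoietic progenitors (CG),
mitotic precursors (PGB), post-mitotic maturing precursors (MGB) and
circulating granulocytes (GRA) — each described by a balance equation of
influx, amplification and efflux:

    dC/dt = C_in(t) * A(t) - C(t) / T(t)

Compartment contents are normalized so that the unperturbed steady state is
exactly 1.  G-CSF closes the feedback loop: its serum concentration raises
the PGB amplification and PGB transit time and lowers the MGB transit time
and the MGB apoptosis rate (Hill-type effect curves anchored at the
steady-state concentration), while endogenous G-CSF production rises when
the circulating pool is depleted.  Two pharmaceutical derivatives are
modelled: Filgrastim, pooled with endogenous G-CSF, and Pegfilgrastim, a
separate long-lived species whose elimination is almost exclusively
granulocyte-mediated.

Chemotherapy enters only through per-compartment first-order loss rates that
:mod:`myelosim.chemo_toxicity` supplies; this module is chemotherapy-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "EffectCurve",
    "StemParams",
    "GcsfSpeciesPk",
    "CellKineticParameters",
    "ModelState",
    "COMPARTMENTS",
    "REGULATED_QUANTITIES",
    "steady_state",
    "gcsf_effect",
    "stem_cell_regulation",
    "cell_kinetic_rhs",
    "gcsf_pk_rhs",
]

COMPARTMENTS = ("S", "CG", "PGB", "MGB", "GRA")

_DEFAULT_CACHE = None

#: Quantities whose value responds to the G-CSF serum concentration.
REGULATED_QUANTITIES = (
    "pgb_amplification",
    "pgb_transit_h",
    "mgb_transit_h",
    "mgb_apoptosis_per_h",
)


class ConfigurationError(ValueError):
    """Raised for parameter sets that admit no valid steady state."""


@dataclass(frozen=True)
class EffectCurve:
    """Hill-type G-CSF dose-response for one regulated quantity.

    ``direction='up'`` means the quantity increases with G-CSF from
    ``minimum`` (no G-CSF) towards ``maximum`` (saturation); ``'down'``
    mirrors this.  The Filgrastim/endogenous half-effect is not free: it is
    derived so that the curve passes exactly through ``baseline`` at the
    steady-state serum concentration, which anchors the normalization of the
    whole cell-kinetic system.  Pegfilgrastim contributes through its own
    half-effect and Hill exponent (different pharmacodynamics); its baseline
    concentration is zero, so the anchor is untouched.
    """

    direction: str
    minimum: float
    baseline: float
    maximum: float
    hill_fil: float
    hill_peg: float
    half_peg_pg_ml: float

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be up/down, got {self.direction!r}")
        if not (self.minimum < self.baseline < self.maximum):
            raise ConfigurationError(
                f"need min < baseline < max, got {self.minimum}/{self.baseline}/{self.maximum}"
            )
        if self.hill_fil <= 0 or self.hill_peg <= 0:
            raise ConfigurationError("Hill exponents must be positive")
        if self.half_peg_pg_ml <= 0:
            raise ConfigurationError("half_peg_pg_ml must be positive")

    def _baseline_saturation(self) -> float:
        """Saturation level s/(1+s) that reproduces the baseline value."""
        if self.direction == "up":
            r = (self.baseline - self.minimum) / (self.maximum - self.minimum)
        else:
            r = (self.maximum - self.baseline) / (self.maximum - self.minimum)
        return r

    def half_fil(self, gcsf_ss_pg_ml: float) -> float:
        """Filgrastim half-effect concentration implied by the anchor."""
        r = self._baseline_saturation()
        s_star = r / (1.0 - r)
        return gcsf_ss_pg_ml / s_star ** (1.0 / self.hill_fil)

    def value(self, c_fil: float, c_peg: float, gcsf_ss_pg_ml: float) -> float:
        """Quantity value at Filgrastim-pool and Pegfilgrastim concentrations."""
        if c_fil < 0 or c_peg < 0:
            raise ValueError("G-CSF concentrations must be non-negative")
        b_f = self.half_fil(gcsf_ss_pg_ml)
        s = (c_fil / b_f) ** self.hill_fil
        if c_peg > 0:
            s += (c_peg / self.half_peg_pg_ml) ** self.hill_peg
        h = s / (1.0 + s)
        if self.direction == "up":
            return self.minimum + (self.maximum - self.minimum) * h
        return self.maximum - (self.maximum - self.minimum) * h


@dataclass(frozen=True)
class StemParams:
    """Stem-cell proliferation and self-renewal regulation.

    Divisions occur at rate ``proliferation_per_h``; a fraction ``a(S)`` of
    daughters self-renews, the rest commits to granulopoiesis.  ``a`` is a
    decreasing logistic in the normalized stem-cell content, anchored so that
    ``a(1) = 1/2`` (zero net growth at homeostasis) and approaching
    ``renewal_max`` as S falls (self-maintenance gains priority).
    """

    proliferation_per_h: float = 0.0004
    renewal_min: float = 0.10
    renewal_max: float = 0.90
    renewal_hill: float = 16.0

    def __post_init__(self) -> None:
        if self.proliferation_per_h <= 0:
            raise ConfigurationError("proliferation rate must be positive")
        if not (0.0 <= self.renewal_min < 0.5 < self.renewal_max <= 1.0):
            raise ConfigurationError("need renewal_min < 1/2 < renewal_max in [0, 1]")
        if self.renewal_hill <= 0:
            raise ConfigurationError("renewal_hill must be positive")


@dataclass(frozen=True)
class GcsfSpeciesPk:
    """Pharmacokinetics of one G-CSF species (subcutaneous depot model)."""

    ka_per_h: float
    bioavailability: float
    volume_ml: float
    k_lin_per_h: float
    k_gra_per_h: float
    km_pg_ml: float

    def __post_init__(self) -> None:
        if min(self.ka_per_h, self.volume_ml, self.km_pg_ml) <= 0:
            raise ConfigurationError("ka, volume and Km must be positive")
        if not (0 < self.bioavailability <= 1):
            raise ConfigurationError("bioavailability must be in (0, 1]")
        if self.k_lin_per_h < 0 or self.k_gra_per_h < 0:
            raise ConfigurationError("clearance rates must be non-negative")

    def elimination_rate(self, conc_pg_ml: float, gra_norm: float) -> float:
        """First-order elimination rate (1/h) at the given state.

        The granulocyte-mediated route scales with the normalized circulating
        pool and saturates at high ligand concentration.
        """
        g = max(gra_norm, 0.0)
        return self.k_lin_per_h + self.k_gra_per_h * g / (1.0 + conc_pg_ml / self.km_pg_ml)


@dataclass(frozen=True)
class CellKineticParameters:
    """Full parameterization of the chemotherapy-free model."""

    steady_state_anc_per_ul: float = 5000.0
    lymphocyte_baseline_per_ul: float = 3000.0
    steady_state_gcsf_pg_ml: float = 25.0
    stem: StemParams = field(default_factory=StemParams)
    transit_h: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 36.0, "PGB": 60.0, "MGB": 120.0, "GRA": 7.0}
    )
    amplification: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 32.0, "PGB": 16.0}
    )
    mgb_apoptosis_per_h: float = 0.004
    effects: Mapping[str, EffectCurve] = field(default_factory=dict)
    gcsf_pk: Mapping[str, GcsfSpeciesPk] = field(default_factory=dict)
    endogenous_demand_gain: float = 1.0
    prednisone_clearance_multiplier: float = 0.7
    schema_version: int = 1

    def __post_init__(self) -> None:
        for name in ("CG", "PGB", "MGB", "GRA"):
            if self.transit_h.get(name, 0.0) <= 0:
                raise ConfigurationError(f"transit time for {name} must be positive")
        for name, amp in self.amplification.items():
            if amp < 1.0:
                raise ConfigurationError(f"amplification in {name} must be >= 1, got {amp}")
        if self.steady_state_anc_per_ul <= 0 or self.steady_state_gcsf_pg_ml <= 0:
            raise ConfigurationError("steady-state ANC and G-CSF must be positive")
        if self.lymphocyte_baseline_per_ul < 0:
            raise ConfigurationError("lymphocyte baseline must be non-negative")
        if not (0 < self.prednisone_clearance_multiplier <= 1):
            raise ConfigurationError("prednisone multiplier must be in (0, 1]")

    # -- derived anchors -------------------------------------------------

    @property
    def endogenous_production_pg_ml_h(self) -> float:
        """Baseline production rate balancing elimination at steady state."""
        pk = self.gcsf_pk["fil"]
        c = self.steady_state_gcsf_pg_ml
        return c * pk.elimination_rate(c, 1.0)

    def endogenous_production(self, gra_norm: float) -> float:
        """Demand-regulated endogenous G-CSF production (pg/ml/h)."""
        theta = self.endogenous_demand_gain
        g = max(gra_norm, 0.0)
        return self.endogenous_production_pg_ml_h * (1.0 + theta) / (1.0 + theta * g)

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "CellKineticParameters":
        effects = {
            name: EffectCurve(
                direction=e["direction"],
                minimum=float(e["min"]),
                baseline=float(e["baseline"]),
                maximum=float(e["max"]),
                hill_fil=float(e["hill_fil"]),
                hill_peg=float(e["hill_peg"]),
                half_peg_pg_ml=float(e["half_peg_pg_ml"]),
            )
            for name, e in cfg["effects"].items()
        }
        unknown = set(effects) - set(REGULATED_QUANTITIES)
        if unknown:
            raise ConfigurationError(f"unknown regulated quantities: {sorted(unknown)}")
        pk = {
            name: GcsfSpeciesPk(**{k: float(v) for k, v in spec.items()})
            for name, spec in cfg["gcsf_pk"].items()
        }
        return cls(
            steady_state_anc_per_ul=float(cfg["steady_state_anc_per_ul"]),
            lymphocyte_baseline_per_ul=float(cfg["lymphocyte_baseline_per_ul"]),
            steady_state_gcsf_pg_ml=float(cfg["steady_state_gcsf_pg_ml"]),
            stem=StemParams(**{k: float(v) for k, v in cfg["stem"].items()}),
            transit_h={k: float(v) for k, v in cfg["transit_h"].items()},
            amplification={k: float(v) for k, v in cfg["amplification"].items()},
            mgb_apoptosis_per_h=float(cfg["mgb_apoptosis_per_h"]),
            effects=effects,
            gcsf_pk=pk,
            endogenous_demand_gain=float(cfg["endogenous_gcsf"]["demand_gain"]),
            prednisone_clearance_multiplier=float(cfg["prednisone"]["clearance_multiplier"]),
            schema_version=int(cfg.get("schema_version", 1)),
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "steady_state_anc_per_ul": self.steady_state_anc_per_ul,
            "lymphocyte_baseline_per_ul": self.lymphocyte_baseline_per_ul,
            "steady_state_gcsf_pg_ml": self.steady_state_gcsf_pg_ml,
            "stem": {
                "proliferation_per_h": self.stem.proliferation_per_h,
                "renewal_min": self.stem.renewal_min,
                "renewal_max": self.stem.renewal_max,
                "renewal_hill": self.stem.renewal_hill,
            },
            "transit_h": dict(self.transit_h),
            "amplification": dict(self.amplification),
            "mgb_apoptosis_per_h": self.mgb_apoptosis_per_h,
            "effects": {
                name: {
                    "direction": e.direction,
                    "min": e.minimum,
                    "baseline": e.baseline,
                    "max": e.maximum,
                    "hill_fil": e.hill_fil,
                    "hill_peg": e.hill_peg,
                    "half_peg_pg_ml": e.half_peg_pg_ml,
                }
                for name, e in self.effects.items()
            },
            "gcsf_pk": {
                name: {
                    "ka_per_h": pk.ka_per_h,
                    "bioavailability": pk.bioavailability,
                    "volume_ml": pk.volume_ml,
                    "k_lin_per_h": pk.k_lin_per_h,
                    "k_gra_per_h": pk.k_gra_per_h,
                    "km_pg_ml": pk.km_pg_ml,
                }
                for name, pk in self.gcsf_pk.items()
            },
            "endogenous_gcsf": {"demand_gain": self.endogenous_demand_gain},
            "prednisone": {"clearance_multiplier": self.prednisone_clearance_multiplier},
        }

    @classmethod
    def default(cls) -> "CellKineticParameters":
        global _DEFAULT_CACHE
        if _DEFAULT_CACHE is None:
            text = resources.files("myelosim.data").joinpath("default_params.yaml").read_text()
            _DEFAULT_CACHE = cls.from_dict(yaml.safe_load(text))
        return _DEFAULT_CACHE

    @classmethod
    def from_yaml(cls, path) -> "CellKineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "CellKineticParameters":
        return replace(self, **kwargs)


@dataclass
class ModelState:
    """Snapshot of the full dynamic state.

    Cell contents are normalized (steady state = 1).  ``chains`` maps a drug
    label to an ``(8,)`` array: four marrow delay-chain stages followed by
    four lymphocyte delay-chain stages, all zero when unperturbed.
    """

    cells: np.ndarray                       # (5,) S, CG, PGB, MGB, GRA
    fil_depot_ug: float = 0.0
    fil_conc_pg_ml: float = 0.0             # Filgrastim + endogenous pool
    peg_depot_ug: float = 0.0
    peg_conc_pg_ml: float = 0.0
    chains: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (5,):
            raise ValueError("cells must have shape (5,)")

    def compartment(self, name: str) -> float:
        return float(self.cells[COMPARTMENTS.index(name)])


def steady_state(params: CellKineticParameters) -> ModelState:
    """Unperturbed fixed point: all normalized compartments exactly 1.

    The normalization of the balance equations (influx scaled so that it
    equals efflux at baseline) makes this exact by construction; the G-CSF
    pool sits at the configured endogenous concentration.
    """
    return ModelState(
        cells=np.ones(5),
        fil_conc_pg_ml=params.steady_state_gcsf_pg_ml,
    )


def stem_cell_regulation(params: CellKineticParameters, s: float) -> float:
    """Self-renewal fraction a(S): decreasing, a(1) = 1/2 exactly."""
    if s < 0:
        raise ValueError(f"stem-cell content must be non-negative, got {s}")
    st = params.stem
    lo, hi, nu = st.renewal_min, st.renewal_max, st.renewal_hill
    beta = (hi - 0.5) / (0.5 - lo)  # anchors a(1) = 1/2
    return lo + (hi - lo) / (1.0 + beta * s**nu)


def gcsf_effect(
    params: CellKineticParameters,
    concentration_pg_ml: float,
    quantity: str,
    derivative: str = "fil",
) -> float:
    """Value of a regulated quantity at a given G-CSF serum concentration.

    For ``derivative='fil'`` the concentration is the pooled
    Filgrastim/endogenous level (its steady-state value returns the baseline
    quantity exactly).  For ``'peg'`` the concentration is Pegfilgrastim on
    top of the endogenous baseline pool, so zero again returns the baseline.
    """
    if quantity not in REGULATED_QUANTITIES:
        raise ValueError(f"unknown regulated quantity {quantity!r}")
    if derivative not in ("fil", "peg"):
        raise ValueError(f"unknown G-CSF derivative {derivative!r}")
    if concentration_pg_ml < 0:
        raise ValueError("concentration must be non-negative")
    curve = params.effects[quantity]
    c_star = params.steady_state_gcsf_pg_ml
    if derivative == "fil":
        return curve.value(concentration_pg_ml, 0.0, c_star)
    return curve.value(c_star, concentration_pg_ml, c_star)


def regulated_values(
    params: CellKineticParameters, c_fil: float, c_peg: float
) -> dict[str, float]:
    """All four regulated quantities at the current serum concentrations."""
    c_star = params.steady_state_gcsf_pg_ml
    return {
        name: params.effects[name].value(max(c_fil, 0.0), max(c_peg, 0.0), c_star)
        for name in REGULATED_QUANTITIES
    }


def cell_kinetic_rhs(
    params: CellKineticParameters,
    cells: np.ndarray,
    c_fil: float,
    c_peg: float,
    toxicity: np.ndarray | None = None,
    gra_clearance_multiplier: float = 1.0,
) -> np.ndarray:
    """Right-hand side of the five normalized cell balance equations.

    ``toxicity`` holds the summed chemotherapy loss rates (1/h) per
    compartment in S, CG, PGB, MGB, GRA order (the last entry is normally 0:
    the toxicity table carries no direct granulocyte kill).
    ``gra_clearance_multiplier`` (<= 1) models the prednisone-prolonged
    neutrophil half-life.
    """
    cells = np.asarray(cells, dtype=float)
    if np.any(np.isnan(cells)):
        raise FloatingPointError(f"NaN in cell state: {cells}")
    if toxicity is None:
        toxicity = np.zeros(5)
    s, cg, pgb, mgb, gra = np.maximum(cells, 0.0)

    reg = regulated_values(params, c_fil, c_peg)
    t_cg = params.transit_h["CG"]
    t_pgb_base = params.transit_h["PGB"]
    t_mgb_base = params.transit_h["MGB"]
    t_gra = params.transit_h["GRA"]
    amp_pgb_base = params.amplification["PGB"]
    d_mgb_base = params.mgb_apoptosis_per_h

    a = stem_cell_regulation(params, s)
    # relative commitment flux out of S (1 at steady state since a(1) = 1/2)
    commit = 2.0 * s * (1.0 - a)

    t_pgb = reg["pgb_transit_h"]
    t_mgb = reg["mgb_transit_h"]
    d_mgb = reg["mgb_apoptosis_per_h"]
    amp_rel = reg["pgb_amplification"] / amp_pgb_base

    d_s = params.stem.proliferation_per_h * s * (2.0 * a - 1.0)
    d_cg = commit / t_cg - cg / t_cg
    d_pgb = amp_rel * cg / t_pgb_base - pgb / t_pgb
    pgb_efflux_rel = pgb * t_pgb_base / t_pgb       # 1 at steady state
    d_mgb_dt = (1.0 / t_mgb_base + d_mgb_base) * pgb_efflux_rel - mgb * (
        1.0 / t_mgb + d_mgb
    )
    mat_rel = mgb * t_mgb_base / t_mgb              # maturation flux, 1 at ss
    d_gra = mat_rel / t_gra - gra * gra_clearance_multiplier / t_gra

    deriv = np.array([d_s, d_cg, d_pgb, d_mgb_dt, d_gra])
    return deriv - np.asarray(toxicity, dtype=float) * np.maximum(cells, 0.0)


def gcsf_pk_rhs(
    params: CellKineticParameters,
    fil_depot_ug: float,
    fil_conc_pg_ml: float,
    peg_depot_ug: float,
    peg_conc_pg_ml: float,
    gra_norm: float,
) -> tuple[float, float, float, float]:
    """Derivatives of the G-CSF depot amounts and serum concentrations.

    Subcutaneous boluses are added to the depots at event times by the
    simulation engine, keeping this right-hand side piecewise smooth.
    Endogenous production feeds the Filgrastim pool and increases when the
    circulating granulocyte pool is below normal (demand regulation).
    """
    pk_f = params.gcsf_pk["fil"]
    pk_p = params.gcsf_pk["peg"]
    to_conc_f = 1.0e6 / pk_f.volume_ml  # ug -> pg/ml
    to_conc_p = 1.0e6 / pk_p.volume_ml

    d_dep_f = -pk_f.ka_per_h * fil_depot_ug
    d_conc_f = (
        pk_f.ka_per_h * fil_depot_ug * to_conc_f
        + params.endogenous_production(gra_norm)
        - fil_conc_pg_ml * pk_f.elimination_rate(fil_conc_pg_ml, gra_norm)
    )
    d_dep_p = -pk_p.ka_per_h * peg_depot_ug
    d_conc_p = (
        pk_p.ka_per_h * peg_depot_ug * to_conc_p
        - peg_conc_pg_ml * pk_p.elimination_rate(peg_conc_pg_ml, gra_norm)
    )
    return d_dep_f, d_conc_f, d_dep_p, d_conc_p
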