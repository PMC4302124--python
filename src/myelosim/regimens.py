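"""Machine-readable treatment-plan library and schedule expansion.

A :class:`Regimen` is a chemotherapy backbone (cyclic drug applications,
each mapped to a toxicity-parameter label) plus an optional G-CSF support
schedule.  The packaged library encodes ten protocol families (CHOP, CHOEP,
high-CHOEP, BEACOPP, BEACOPP escalated, TA, CP, ETC, EC-T, ESHAP) and 33
clinical scenarios combining them with Filgrastim/Pegfilgrastim schedules
and risk groups.

Conventions: within-cycle days are 1-based; all injections and infusion
starts happen at a fixed clock time (08:00 by default); per-kg G-CSF doses
are converted with a configurable reference body mass (70 kg default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Iterable

import yaml

from .chemo_toxicity import DrugApplication

__all__ = [
    "GcsfInjection",
    "CycleAgent",
    "Regimen",
    "ScheduleEvent",
    "expand_schedule",
    "drug_applications",
    "prednisone_applications",
    "load_protocols",
    "load_scenarios",
    "get_regimen",
    "scenario_regimen",
    "load_regimen",
    "save_regimen",
]

DEFAULT_BODY_MASS_KG = 70.0
DEFAULT_BODY_SURFACE_M2 = 1.8
CLOCK_TIME_H = 8.0  # injections at 08:00


class RegimenValidationError(ValueError):
    """Schema or consistency violation in a regimen definition."""


@dataclass(frozen=True)
class GcsfInjection:
    """G-CSF support: one derivative injected on given within-cycle days."""

    derivative: str            # 'fil' | 'peg'
    dose: float
    dose_unit: str = "ug"      # 'ug' (absolute) | 'ug_per_kg'
    days: tuple[int, ...] = ()
    cycles: tuple[int, ...] | None = None  # None = every cycle

    def __post_init__(self) -> None:
        if self.derivative not in ("fil", "peg"):
            raise RegimenValidationError(f"unknown G-CSF derivative {self.derivative!r}")
        if self.dose <= 0:
            raise RegimenValidationError("G-CSF dose must be positive")
        if self.dose_unit not in ("ug", "ug_per_kg"):
            raise RegimenValidationError(f"unknown dose unit {self.dose_unit!r}")
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))

    def dose_ug(self, body_mass_kg: float = DEFAULT_BODY_MASS_KG) -> float:
        if self.dose_unit == "ug":
            return self.dose
        return self.dose * body_mass_kg


@dataclass(frozen=True)
class CycleAgent:
    """One drug (or combination) of the cyclic backbone."""

    drug: str
    days: tuple[int, ...]
    toxicity_label: str | None = None
    infusion_h: float = 1.0
    doses: str = ""
    cytotoxic: bool = True
    cycles: tuple[int, ...] | None = None
    external_knowledge: bool = False

    def __post_init__(self) -> None:
        if self.infusion_h <= 0:
            raise RegimenValidationError(f"{self.drug}: infusion duration must be positive")
        if self.cytotoxic and not self.toxicity_label:
            raise RegimenValidationError(
                f"{self.drug}: cytotoxic agents must map to a toxicity label"
            )
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        if self.cycles is not None:
            object.__setattr__(self, "cycles", tuple(int(c) for c in self.cycles))


@dataclass(frozen=True)
class Regimen:
    """A full treatment plan over ``n_cycles`` cycles of ``cycle_days`` days."""

    name: str
    cycle_days: int
    n_cycles: int
    agents: tuple[CycleAgent, ...]
    gcsf: tuple[GcsfInjection, ...] = ()
    risk_group: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cycle_days <= 0 or self.n_cycles <= 0:
            raise RegimenValidationError("cycle length and cycle count must be positive")
        for agent in self.agents:
            for day in agent.days:
                if not 1 <= day <= self.cycle_days:
                    raise RegimenValidationError(
                        f"{self.name}/{agent.drug}: day {day} outside cycle of "
                        f"{self.cycle_days} days"
                    )
            if agent.cycles is not None:
                bad = [c for c in agent.cycles if not 1 <= c <= self.n_cycles]
                if bad:
                    raise RegimenValidationError(
                        f"{self.name}/{agent.drug}: cycles {bad} outside 1..{self.n_cycles}"
                    )
        for inj in self.gcsf:
            for day in inj.days:
                if not 1 <= day <= self.cycle_days:
                    raise RegimenValidationError(
                        f"{self.name}/G-CSF: day {day} outside cycle of {self.cycle_days} days"
                    )

    @property
    def horizon_days(self) -> float:
        return float(self.cycle_days * self.n_cycles)

    def with_gcsf(self, gcsf: Iterable[GcsfInjection]) -> "Regimen":
        return replace(self, gcsf=tuple(gcsf))

    def without_gcsf(self) -> "Regimen":
        return replace(self, gcsf=())

    def toxicity_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for agent in self.agents:
            if agent.cytotoxic and agent.toxicity_label not in seen:
                seen.append(agent.toxicity_label)
        return tuple(seen)


@dataclass(frozen=True, order=True)
class ScheduleEvent:
    """Absolute-time event: kind is infusion_start/infusion_end/gcsf."""

    time_h: float
    kind: str
    label: str
    payload: tuple = ()


def _agent_times_day(regimen: Regimen, agent: CycleAgent) -> list[float]:
    times = []
    for cycle in range(1, regimen.n_cycles + 1):
        if agent.cycles is not None and cycle not in agent.cycles:
            continue
        offset = (cycle - 1) * regimen.cycle_days
        for day in agent.days:
            times.append(offset + (day - 1) + CLOCK_TIME_H / 24.0)
    return sorted(times)


def expand_schedule(
    regimen: Regimen, body_mass_kg: float = DEFAULT_BODY_MASS_KG
) -> list[ScheduleEvent]:
    """Deterministic sorted list of absolute-time (hours) treatment events."""
    events: list[ScheduleEvent] = []
    for agent in regimen.agents:
        for t_day in _agent_times_day(regimen, agent):
            start = 24.0 * t_day
            events.append(ScheduleEvent(start, "infusion_start", agent.drug))
            events.append(ScheduleEvent(start + agent.infusion_h, "infusion_end", agent.drug))
    for inj in regimen.gcsf:
        for cycle in range(1, regimen.n_cycles + 1):
            if inj.cycles is not None and cycle not in inj.cycles:
                continue
            offset = (cycle - 1) * regimen.cycle_days
            for day in inj.days:
                t_h = 24.0 * (offset + (day - 1)) + CLOCK_TIME_H
                events.append(
                    ScheduleEvent(t_h, "gcsf", inj.derivative, (inj.dose_ug(body_mass_kg),))
                )
    return sorted(events)


def drug_applications(regimen: Regimen) -> dict[str, DrugApplication]:
    """Absolute-time pulse trains of the cytotoxic agents, keyed by toxicity label.

    Agents sharing a toxicity label (none in the shipped library) are merged
    into one pulse train, since they share one delay chain and one
    coefficient set.
    """
    merged: dict[str, DrugApplication] = {}
    for agent in regimen.agents:
        if not agent.cytotoxic:
            continue
        times = tuple(_agent_times_day(regimen, agent))
        label = agent.toxicity_label
        if label in merged:
            prev = merged[label]
            times = tuple(sorted(set(prev.times_day) | set(times)))
            merged[label] = replace(prev, times_day=times)
        else:
            merged[label] = DrugApplication(
                drug=agent.drug,
                times_day=times,
                infusion_h=agent.infusion_h,
                cytotoxic=True,
            )
    return merged


def prednisone_applications(regimen: Regimen) -> list[DrugApplication]:
    """Absolute-time applications of the non-cytotoxic (prednisone-like) agents."""
    apps = []
    for agent in regimen.agents:
        if agent.cytotoxic:
            continue
        apps.append(
            DrugApplication(
                drug=agent.drug,
                times_day=tuple(_agent_times_day(regimen, agent)),
                infusion_h=24.0,  # one coverage day per application
                cytotoxic=False,
            )
        )
    return apps


# ---------------------------------------------------------------------------
# packaged library
# ---------------------------------------------------------------------------

def _read_packaged_yaml(name: str) -> dict:
    text = resources.files("myelosim.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def load_protocols() -> dict[str, dict]:
    """Raw protocol-family definitions keyed by protocol name."""
    return _read_packaged_yaml("protocols.yaml")["protocols"]


def load_scenarios() -> dict[int, dict]:
    """The 33 clinical scenarios keyed by scenario id."""
    doc = _read_packaged_yaml("scenarios.yaml")
    return {int(s["id"]): s for s in doc["scenarios"]}


def _resolve_label(raw: Any, risk_group: str | None, protocol: str) -> str:
    if isinstance(raw, str):
        return raw
    if isinstance(raw, dict):
        if risk_group is None:
            raise RegimenValidationError(
                f"{protocol}: toxicity label depends on risk group "
                f"({sorted(raw)}); pass risk_group"
            )
        try:
            return raw[risk_group]
        except KeyError:
            raise RegimenValidationError(
                f"{protocol}: no toxicity label for risk group {risk_group!r}"
            ) from None
    raise RegimenValidationError(f"{protocol}: malformed toxicity label {raw!r}")


def _agents_from_spec(spec: dict, risk_group: str | None, protocol: str) -> tuple[CycleAgent, ...]:
    agents = []
    for entry in spec["agents"]:
        cytotoxic = bool(entry.get("cytotoxic", True))
        label = None
        if cytotoxic:
            label = _resolve_label(entry["toxicity_label"], risk_group, protocol)
        agents.append(
            CycleAgent(
                drug=entry["drug"],
                days=tuple(entry["days"]),
                toxicity_label=label,
                infusion_h=float(entry.get("infusion_h", 1.0)),
                doses=str(entry.get("doses", "")),
                cytotoxic=cytotoxic,
                cycles=tuple(entry["cycles"]) if entry.get("cycles") else None,
                external_knowledge=bool(entry.get("external_knowledge", False)),
            )
        )
    return tuple(agents)


def get_regimen(
    protocol: str,
    risk_group: str | None = None,
    cycle_days: int | None = None,
    n_cycles: int | None = None,
    gcsf: Iterable[GcsfInjection] = (),
) -> Regimen:
    """Instantiate a protocol family from the packaged library."""
    protocols = load_protocols()
    if protocol not in protocols:
        raise RegimenValidationError(
            f"unknown protocol {protocol!r}; available: {sorted(protocols)}"
        )
    spec = protocols[protocol]
    cd = int(cycle_days or spec["default_cycle_days"])
    nc = int(n_cycles or spec["default_n_cycles"])
    name = f"{protocol}-{cd}" if cycle_days else protocol
    return Regimen(
        name=name,
        cycle_days=cd,
        n_cycles=nc,
        agents=_agents_from_spec(spec, risk_group, protocol),
        gcsf=tuple(gcsf),
        risk_group=risk_group,
        metadata={"protocol": protocol},
    )


def scenario_regimen(
    scenario_id: int,
    n_cycles: int | None = None,
) -> Regimen:
    """Regimen for one of the 33 shipped clinical scenarios."""
    scenarios = load_scenarios()
    if scenario_id not in scenarios:
        raise RegimenValidationError(f"unknown scenario id {scenario_id}")
    sc = scenarios[scenario_id]
    gcsf: list[GcsfInjection] = []
    if sc.get("gcsf"):
        g = sc["gcsf"]
        gcsf.append(
            GcsfInjection(
                derivative=g["derivative"],
                dose=float(g["dose"]),
                dose_unit=g["dose_unit"],
                days=tuple(g["days"]),
            )
        )
    regimen = get_regimen(
        sc["protocol"],
        risk_group=sc.get("risk_group"),
        cycle_days=sc.get("cycle_days"),
        n_cycles=n_cycles,
        gcsf=gcsf,
    )
    meta = dict(regimen.metadata)
    meta.update(
        scenario_id=scenario_id,
        disease=sc.get("disease"),
        validation=bool(sc.get("validation", False)),
    )
    return replace(regimen, name=f"scenario-{scenario_id:02d}-{regimen.name}", metadata=meta)


# ---------------------------------------------------------------------------
# user-defined regimen files
# ---------------------------------------------------------------------------

def save_regimen(regimen: Regimen, path) -> None:
    doc = {
        "schema_version": 1,
        "name": regimen.name,
        "cycle_days": regimen.cycle_days,
        "n_cycles": regimen.n_cycles,
        "risk_group": regimen.risk_group,
        "metadata": regimen.metadata,
        "agents": [
            {
                "drug": a.drug,
                "days": list(a.days),
                "toxicity_label": a.toxicity_label,
                "infusion_h": a.infusion_h,
                "doses": a.doses,
                "cytotoxic": a.cytotoxic,
                "cycles": list(a.cycles) if a.cycles else None,
                "external_knowledge": a.external_knowledge,
            }
            for a in regimen.agents
        ],
        "gcsf": [
            {
                "derivative": g.derivative,
                "dose": g.dose,
                "dose_unit": g.dose_unit,
                "days": list(g.days),
                "cycles": list(g.cycles) if g.cycles else None,
            }
            for g in regimen.gcsf
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_regimen(path, known_labels: Iterable[str] | None = None) -> Regimen:
    """Load a user regimen file (the lossless inverse of :func:`save_regimen`).

    If ``known_labels`` is given, cytotoxic agents must reference one of
    them; a file may extend the vocabulary by shipping inline toxicity sets
    under ``inline_toxicity`` (handled by the caller via
    :func:`myelosim.chemo_toxicity.load_toxicity_table`).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("name", "cycle_days", "n_cycles", "agents"):
        if key not in doc:
            raise RegimenValidationError(f"regimen file missing field {key!r} at top level")
    agents = []
    for i, entry in enumerate(doc["agents"]):
        if "drug" not in entry or "days" not in entry:
            raise RegimenValidationError(f"agents[{i}]: need at least drug and days")
        agents.append(
            CycleAgent(
                drug=entry["drug"],
                days=tuple(entry["days"]),
                toxicity_label=entry.get("toxicity_label"),
                infusion_h=float(entry.get("infusion_h", 1.0)),
                doses=str(entry.get("doses", "")),
                cytotoxic=bool(entry.get("cytotoxic", True)),
                cycles=tuple(entry["cycles"]) if entry.get("cycles") else None,
                external_knowledge=bool(entry.get("external_knowledge", False)),
            )
        )
    gcsf = tuple(
        GcsfInjection(
            derivative=g["derivative"],
            dose=float(g["dose"]),
            dose_unit=g.get("dose_unit", "ug"),
            days=tuple(g["days"]),
            cycles=tuple(g["cycles"]) if g.get("cycles") else None,
        )
        for g in doc.get("gcsf") or ()
    )
    regimen = Regimen(
        name=doc["name"],
        cycle_days=int(doc["cycle_days"]),
        n_cycles=int(doc["n_cycles"]),
        agents=tuple(agents),
        gcsf=gcsf,
        risk_group=doc.get("risk_group"),
        metadata=doc.get("metadata") or {},
    )
    if known_labels is not None:
        inline = set((doc.get("inline_toxicity") or {}).keys())
        allowed = set(known_labels) | inline
        unknown = [l for l in regimen.toxicity_labels() if l not in allowed]
        if unknown:
            raise RegimenValidationError(
                f"{regimen.name}: unknown toxicity labels {unknown} "
                "(supply inline_toxicity or use shipped labels)"
            )
    return regimen
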