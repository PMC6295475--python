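"""Soda-lake medium description and conversion to dimensionless activities.

The 1 M Na+ carbonate/bicarbonate brine is far from ideal-dilute behaviour, so
concentrations are mapped to activities with fixed electrolyte correction
factors: f = 0.5 for monovalent ions, f = 0.04 for divalent ions, 1 for
neutral aqueous species.  Dissolved H2 is additionally salted out; this is
expressed as a 0.2 multiplier on the H2 gas activity and exposes the two
reporting frames used throughout the package:

* ``pure_water``     - H2 solubility as in pure water (dG^1),
* ``soda_corrected`` - H2 activity times the salting-out factor (dG^1*).

CH4 and CO2 never receive the salting factor.  Water activity is fixed at 1
and H+ activity is 10**(-pH), pH being an activity measurement already.
"""

from __future__ import annotations

import dataclasses
import tomllib
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ActivityDomainError, ConfigError, UsageError
from .thermo_core import ChemicalSpecies, GibbsTable, P_STANDARD_PA

H2_FRAMES = ("pure_water", "soda_corrected")


@dataclass
class MediumConditions:
    """In-situ physico-chemical state of an incubation.

    Parameters
    ----------
    temperature:
        K.  Default 303.15 (30 degC incubations).
    pH:
        Activity-based pH; default 9.5.
    na_total:
        Total sodium, mol/L (nominal 1 M soda medium); informational.
    carbonate_alkalinity_total:
        Total dissolved inorganic carbon, mol/L, to be speciated over
        CO2(aq)/HCO3-/CO3-2.  When ``None``, bicarbonate/carbonate must be
        given explicitly in *solutes*.
    solutes:
        Species name -> concentration, mol/L.
    gases:
        Species name -> partial pressure, Pa.
    f_monovalent, f_divalent:
        Electrolyte activity factors for mono-/divalent ions.
    h2_salting_factor:
        Salting-out multiplier on the H2 activity in the soda-corrected frame.
    h2_frame:
        ``"pure_water"`` or ``"soda_corrected"``.
    pk1, pk2:
        Carbonic-acid dissociation pK values (25 degC freshwater defaults);
        used as conditional constants with the activity factors folded into
        the quotient.
    henry_co2:
        CO2 solubility, mol L^-1 atm^-1, for the equilibrium CO2 pressure.
    """

    temperature: float = 303.15
    pH: float = 9.5
    na_total: float = 1.0
    carbonate_alkalinity_total: float | None = None
    solutes: dict[str, float] = field(default_factory=dict)
    gases: dict[str, float] = field(default_factory=dict)
    f_monovalent: float = 0.5
    f_divalent: float = 0.04
    h2_salting_factor: float = 0.2
    h2_frame: str = "pure_water"
    pk1: float = 6.35
    pk2: float = 10.33
    henry_co2: float = 0.0339

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ConfigError(f"temperature must be > 0 K, got {self.temperature}")
        if not (0 < self.f_divalent <= self.f_monovalent <= 1):
            raise ConfigError(
                "activity factors must satisfy 0 < f_divalent <= f_monovalent <= 1, "
                f"got {self.f_divalent}/{self.f_monovalent}"
            )
        if not (0 < self.h2_salting_factor <= 1):
            raise ConfigError(
                f"h2_salting_factor must be in (0, 1], got {self.h2_salting_factor}"
            )
        if self.h2_frame not in H2_FRAMES:
            raise ConfigError(f"h2_frame must be one of {H2_FRAMES}, got {self.h2_frame!r}")
        if self.carbonate_alkalinity_total is not None and not (
            self.carbonate_alkalinity_total > 0
        ):
            raise ConfigError("carbonate_alkalinity_total must be > 0 when given")
        for name, conc in self.solutes.items():
            if conc < 0:
                raise ConfigError(f"concentration of {name} must be >= 0, got {conc}")
        for name, p in self.gases.items():
            if p < 0:
                raise ConfigError(f"partial pressure of {name} must be >= 0, got {p}")

    def replace(self, **changes) -> "MediumConditions":
        """Return a copy with the given fields replaced (dicts are copied)."""
        out = dataclasses.replace(self, **changes)
        if "solutes" not in changes:
            out.solutes = dict(self.solutes)
        if "gases" not in changes:
            out.gases = dict(self.gases)
        return out

    # -- plain-text (TOML) serialization ------------------------------------

    _MEDIUM_KEYS = {
        "temperature_K": "temperature",
        "pH": "pH",
        "na_total_M": "na_total",
        "carbonate_alkalinity_total_M": "carbonate_alkalinity_total",
        "h2_frame": "h2_frame",
    }
    _CORRECTION_KEYS = {
        "f_monovalent": "f_monovalent",
        "f_divalent": "f_divalent",
        "h2_salting_factor": "h2_salting_factor",
        "pK1": "pk1",
        "pK2": "pk2",
        "henry_co2_M_per_atm": "henry_co2",
    }

    @classmethod
    def from_toml_data(cls, data: Mapping) -> "MediumConditions":
        known_sections = {"medium", "solutes_mM", "gases_Pa", "corrections"}
        kwargs: dict = {}
        for section in data:
            if section not in known_sections | {"scenario", "reactions", "simulate"}:
                raise ConfigError(f"unknown config section [{section}]")
        for key, value in data.get("medium", {}).items():
            if key not in cls._MEDIUM_KEYS:
                raise ConfigError(f"unknown key {key!r} in [medium]")
            kwargs[cls._MEDIUM_KEYS[key]] = value
        for key, value in data.get("corrections", {}).items():
            if key not in cls._CORRECTION_KEYS:
                raise ConfigError(f"unknown key {key!r} in [corrections]")
            kwargs[cls._CORRECTION_KEYS[key]] = value
        kwargs["solutes"] = {
            name: float(mm) / 1000.0 for name, mm in data.get("solutes_mM", {}).items()
        }
        kwargs["gases"] = {
            name: float(p) for name, p in data.get("gases_Pa", {}).items()
        }
        return cls(**kwargs)

    @classmethod
    def from_toml(cls, source) -> "MediumConditions":
        """Read conditions from a TOML file path or binary file object."""
        if hasattr(source, "read"):
            data = tomllib.load(source)
        else:
            with open(source, "rb") as fh:
                data = tomllib.load(fh)
        return cls.from_toml_data(data)

    def to_toml(self) -> str:
        lines = ["[medium]"]
        lines.append(f"temperature_K = {self.temperature!r}")
        lines.append(f"pH = {self.pH!r}")
        lines.append(f"na_total_M = {self.na_total!r}")
        if self.carbonate_alkalinity_total is not None:
            lines.append(
                f"carbonate_alkalinity_total_M = {self.carbonate_alkalinity_total!r}"
            )
        lines.append(f'h2_frame = "{self.h2_frame}"')
        if self.solutes:
            lines.append("")
            lines.append("[solutes_mM]")
            for name, conc in self.solutes.items():
                lines.append(f'"{name}" = {conc * 1000.0!r}')
        if self.gases:
            lines.append("")
            lines.append("[gases_Pa]")
            for name, p in self.gases.items():
                lines.append(f'"{name}" = {float(p)!r}')
        lines.append("")
        lines.append("[corrections]")
        lines.append(f"f_monovalent = {self.f_monovalent!r}")
        lines.append(f"f_divalent = {self.f_divalent!r}")
        lines.append(f"h2_salting_factor = {self.h2_salting_factor!r}")
        lines.append(f"pK1 = {self.pk1!r}")
        lines.append(f"pK2 = {self.pk2!r}")
        lines.append(f"henry_co2_M_per_atm = {self.henry_co2!r}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_toml(), encoding="utf-8")


class ActivitySet(Mapping):
    """Dimensionless activities keyed by species name.

    Water activity is fixed at 1 and H+ at 10**(-pH) by construction in
    :func:`build_activity_set`.  Missing lookups raise
    :class:`~syntherm.errors.UnknownSpeciesError` via the Mapping protocol
    consumers in :mod:`syntherm.thermo_core`.
    """

    def __init__(self, activities: Mapping[str, float], frame_note: str = ""):
        self._activities = dict(activities)
        self.frame_note = frame_note

    def __getitem__(self, name: str) -> float:
        return self._activities[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._activities)

    def __len__(self) -> int:
        return len(self._activities)

    def __repr__(self) -> str:
        return f"ActivitySet({self._activities!r}, frame_note={self.frame_note!r})"


def ion_activity_factor(species: ChemicalSpecies, conditions: MediumConditions) -> float:
    """Electrolyte activity factor for a dissolved species.

    Monovalent ions get ``f_monovalent``, divalent ions ``f_divalent``,
    neutral aqueous species and water 1.0.  Gases are rejected; they go
    through :func:`gas_activity`.
    """
    if species.phase == "gas":
        raise UsageError(
            f"{species.name} is a gas; use gas_activity, not an ion factor"
        )
    if species.phase == "water":
        return 1.0
    cls = species.ion_class
    if cls == "monovalent":
        return conditions.f_monovalent
    if cls == "divalent":
        return conditions.f_divalent
    return 1.0


def gas_activity(
    species: ChemicalSpecies, partial_pressure: float, conditions: MediumConditions
) -> float:
    """Dimensionless activity of a gas at *partial_pressure* (Pa).

    ``a = p / 101325`` (1 atm standard state); H2 is additionally multiplied
    by the salting-out factor in the ``soda_corrected`` frame.  CH4 and CO2
    never receive the salting factor.
    """
    if species.phase != "gas":
        raise UsageError(f"{species.name} is not a gas-phase species")
    if not partial_pressure > 0:
        raise ActivityDomainError(
            f"partial pressure of {species.name} must be > 0 Pa, "
            f"got {partial_pressure!r}"
        )
    a = partial_pressure / P_STANDARD_PA
    if species.name == "H2" and conditions.h2_frame == "soda_corrected":
        a *= conditions.h2_salting_factor
    return a


@dataclass(frozen=True)
class CarbonateSpeciation:
    """Partition of total dissolved inorganic carbon, mol/L, plus the
    gas-liquid equilibrium CO2 partial pressure, Pa."""

    co2_aq: float
    hco3: float
    co3: float
    p_co2_equilibrium: float

    @property
    def total(self) -> float:
        return self.co2_aq + (self.hco3 + self.co3)


def carbonate_speciation(conditions: MediumConditions) -> CarbonateSpeciation:
    """Speciate total inorganic carbon over CO2(aq), HCO3- and CO3-2.

    Dissociation equilibria are evaluated in activity space with the fixed
    electrolyte factors folded in, i.e. concentration ratios are

        [HCO3-]/[CO2aq]  = K1 / (a_H * f_mono)
        [CO3-2]/[HCO3-]  = K2 * f_mono / (a_H * f_di)

    with a_H = 10**(-pH).  The three concentrations sum to the total exactly
    (CO2(aq) is computed as the residual).  The equilibrium CO2 partial
    pressure follows from the Henry constant.
    """
    total = conditions.carbonate_alkalinity_total
    if total is None or not total > 0:
        raise ConfigError("carbonate_alkalinity_total must be set and > 0")
    a_h = 10.0 ** (-conditions.pH)
    k1 = 10.0 ** (-conditions.pk1)
    k2 = 10.0 ** (-conditions.pk2)
    r1 = k1 / (a_h * conditions.f_monovalent)
    r2 = k2 * conditions.f_monovalent / (a_h * conditions.f_divalent)
    denom = 1.0 + r1 * (1.0 + r2)
    hco3 = total * r1 / denom
    co3 = total * r1 * r2 / denom
    co2_aq = total - (hco3 + co3)
    p_co2 = co2_aq / conditions.henry_co2 * P_STANDARD_PA
    return CarbonateSpeciation(co2_aq=co2_aq, hco3=hco3, co3=co3, p_co2_equilibrium=p_co2)


def build_activity_set(conditions: MediumConditions, table: GibbsTable) -> ActivitySet:
    """Convert a :class:`MediumConditions` into the activities entering ln Q.

    Solute activities are concentration times the ion factor; bicarbonate and
    carbonate come from :func:`carbonate_speciation` when a total alkalinity
    is declared, otherwise from explicit solute entries; gases go through
    :func:`gas_activity`.  Water is 1 and H+ is 10**(-pH) always.  Species
    with zero concentration or pressure are omitted (they would make ln Q
    undefined; downstream lookups then fail loudly naming the species).
    """
    activities: dict[str, float] = {"H2O": 1.0, "H+": 10.0 ** (-conditions.pH)}

    if conditions.carbonate_alkalinity_total is not None:
        spec = carbonate_speciation(conditions)
        activities["HCO3-"] = spec.hco3 * conditions.f_monovalent
        activities["CO3-2"] = spec.co3 * conditions.f_divalent
        if "CO2" in table and "CO2" not in conditions.gases:
            # gas-liquid equilibrium assumed for CO2
            activities["CO2"] = spec.p_co2_equilibrium / P_STANDARD_PA

    for name, conc in conditions.solutes.items():
        sp = table[name]
        if conditions.carbonate_alkalinity_total is not None and name in (
            "HCO3-",
            "CO3-2",
        ):
            continue
        if conc > 0:
            activities[name] = conc * ion_activity_factor(sp, conditions)

    for name, p in conditions.gases.items():
        sp = table[name]
        if p > 0:
            activities[name] = gas_activity(sp, p, conditions)

    return ActivitySet(activities, frame_note=conditions.h2_frame)
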