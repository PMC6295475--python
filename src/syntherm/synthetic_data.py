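"""Synthetic batch-incubation series and the reference scenario fixtures.

The generator emulates the structure of soda-lake SAO batch incubations:
linear (zero-order) substrate decline at a configured rate, products rising
per reaction stoichiometry, H2 at a rise-then-plateau quasi-steady partial
pressure of a few to tens of Pa, a formate trace pinned to its H2/bicarbonate
equilibrium value and censored at the assay detection limit, and seeded
multiplicative (constant-CV) triplicate noise.

:func:`reference_scenarios` ships the four enrichment-culture scenarios
(methanogenic and sulfate-reducing, each with and without its inhibitor)
with documented reconstructed in-situ values, together with the published
Gibbs-energy entries they are benchmarked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .incubation_io import Measurement, TimeSeries, apply_detection_limit
from .medium_chemistry import MediumConditions
from .reactions import (
    ACETATE_OXIDATION,
    FORMATE_METHANOGENESIS,
    HYDROGENOTROPHIC_METHANOGENESIS,
    HYDROGENOTROPHIC_SULFATE_REDUCTION,
    MSAO_TOTAL,
    SSAO_TOTAL,
)
from .syntrophy_analysis import Scenario, equilibrium_formate
from .thermo_core import Reaction

#: Gas constant, J mol^-1 K^-1, for mmol/L -> Pa headspace conversion.
_R_J = 8.314462618

#: Analytes reported from reaction stoichiometry and their recording unit.
_PRODUCT_UNITS = {"CH4": "mmol_per_L", "HS-": "mM"}


def _reference_conditions(**overrides) -> MediumConditions:
    """Common reconstructed in-situ medium of the enrichment incubations."""
    base = dict(
        temperature=303.15,
        pH=9.5,
        na_total=1.0,
        solutes={"HCO3-": 0.6},
        gases={},
        f_monovalent=0.5,
        f_divalent=0.04,
        h2_salting_factor=0.2,
        h2_frame="soda_corrected",
    )
    solutes = dict(base["solutes"], **overrides.pop("solutes", {}))
    gases = dict(base["gases"], **overrides.pop("gases", {}))
    base.update(overrides)
    base["solutes"] = solutes
    base["gases"] = gases
    return MediumConditions(**base)


def reference_scenarios() -> dict[str, Scenario]:
    """The four benchmark scenarios with reconstructed in-situ values.

    Common to all: 303.15 K, pH 9.5, activity factors 0.5/0.04, H2
    salting-out factor 0.2, bicarbonate 0.6 M.  The inhibited variants (BES
    blocks methanogenesis, molybdate blocks sulfate reduction) have no
    consumer reaction and a higher accumulated H2 pressure.
    """
    msao = _reference_conditions(
        solutes={"acetate": 0.045},
        gases={"H2": 11.5, "CH4": 20265.0},
    )
    msao_bes = _reference_conditions(
        solutes={"acetate": 0.045},
        gases={"H2": 47.9},
    )
    ssao = _reference_conditions(
        solutes={"acetate": 0.025, "SO4-2": 0.020, "HS-": 0.005},
        gases={"H2": 4.7},
    )
    ssao_mo = _reference_conditions(
        solutes={"acetate": 0.025, "SO4-2": 0.020, "HS-": 0.005},
        gases={"H2": 13.7},
    )
    return {
        "M-SAO": Scenario(
            label="M-SAO",
            producer_reaction=ACETATE_OXIDATION,
            consumer_reaction=HYDROGENOTROPHIC_METHANOGENESIS,
            total_reaction=MSAO_TOTAL,
            conditions=msao,
        ),
        "M-SAO+BES": Scenario(
            label="M-SAO+BES",
            producer_reaction=ACETATE_OXIDATION,
            conditions=msao_bes,
        ),
        "S-SAO": Scenario(
            label="S-SAO",
            producer_reaction=ACETATE_OXIDATION,
            consumer_reaction=HYDROGENOTROPHIC_SULFATE_REDUCTION,
            total_reaction=SSAO_TOTAL,
            conditions=ssao,
        ),
        "S-SAO+MoO4": Scenario(
            label="S-SAO+MoO4",
            producer_reaction=ACETATE_OXIDATION,
            conditions=ssao_mo,
        ),
    }


#: Published actual Gibbs energies (dG^1, dG^1*) in kJ/mol for the benchmark
#: scenarios, keyed by (scenario label, role); used for regression comparison.
REFERENCE_DELTA_G: dict[tuple[str, str], tuple[float, float]] = {
    ("M-SAO", "producer"): (+2.2, -13.7),
    ("M-SAO", "consumer"): (-31.2, -15.3),
    ("M-SAO", "total"): (-29.0, -29.0),
    ("M-SAO+BES", "producer"): (+16.3, +0.4),
    ("S-SAO", "producer"): (-6.2, -22.3),
    ("S-SAO", "consumer"): (-33.3, -17.3),
    ("S-SAO", "total"): (-39.5, -39.6),
    ("S-SAO+MoO4", "producer"): (+4.4, -11.6),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic batch incubation.

    Defaults describe the methanogenic enrichment: 30 mM acetate consumed at
    0.04 mM/h by the overall methanogenic reaction, H2 settling at the
    measured 11.5 Pa quasi-steady plateau, triplicates with 10% CV noise,
    30 mL liquid / 20 mL headspace vials sampled every 50 h out to 800 h,
    formate censored at the 0.05 mM assay limit.
    """

    label: str = "M-SAO"
    reaction: Reaction = field(default_factory=lambda: MSAO_TOTAL)
    substrate: str = "acetate"
    substrate_initial: float = 30.0  # mM
    rate: float = 0.04  # mM/h
    h2_quasi_steady: float = 11.5  # Pa
    h2_inhibited_ceiling: float = 47.9  # Pa
    consumer_present: bool = True
    substrate_cap: float | None = None  # mM consumed under inhibition
    h2_rise_tau: float = 50.0  # h
    noise_sd: float = 0.10  # relative (CV), per measurement
    replicates: int = 3
    sampling_times: tuple = tuple(float(t) for t in range(0, 801, 50))
    seed: int = 0
    detection_limits: dict[str, float] = field(
        default_factory=lambda: {"formate": 0.05}
    )
    liquid_volume_mL: float = 30.0
    headspace_volume_mL: float = 20.0
    conditions: MediumConditions | None = None
    include_formate_trace: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0 or self.substrate_initial < 0:
            raise ConfigError("rate and substrate_initial must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.reaction.coefficient(self.substrate) >= 0:
            raise ConfigError(
                f"substrate {self.substrate!r} must be consumed by "
                f"{self.reaction.name!r}"
            )
        if list(self.sampling_times) != sorted(set(self.sampling_times)):
            raise ConfigError("sampling_times must be strictly increasing")

    def medium(self) -> MediumConditions:
        if self.conditions is not None:
            return self.conditions
        return _reference_conditions(solutes={"acetate": self.substrate_initial / 1000.0})


def msao_config(**overrides) -> SimulationConfig:
    """Methanogenic enrichment defaults (0.04 mM/h, H2 plateau 11.5 Pa)."""
    return SimulationConfig(**overrides)


def ssao_config(**overrides) -> SimulationConfig:
    """Sulfate-reducing enrichment: 0.01 mM/h, H2 plateau 4.7 Pa, sulfide rise."""
    params = dict(
        label="S-SAO",
        reaction=SSAO_TOTAL,
        substrate_initial=25.0,
        rate=0.01,
        h2_quasi_steady=4.7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def bes_config(**overrides) -> SimulationConfig:
    """Methanogenesis-inhibited culture: no H2 sink, H2 climbs to 47.9 Pa,
    acetate consumption stalls at 1.6 mM."""
    params = dict(
        label="M-SAO+BES",
        reaction=ACETATE_OXIDATION,
        consumer_present=False,
        substrate_cap=1.6,
        h2_inhibited_ceiling=47.9,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def molybdate_config(**overrides) -> SimulationConfig:
    """Sulfate-reduction-inhibited culture: H2 climbs to 13.7 Pa."""
    params = dict(
        label="S-SAO+MoO4",
        reaction=ACETATE_OXIDATION,
        substrate_initial=25.0,
        rate=0.01,
        consumer_present=False,
        substrate_cap=1.6,
        h2_inhibited_ceiling=13.7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def formate_feeding_config(**overrides) -> SimulationConfig:
    """7 mM formate converted to methane at 4:1 with a transient H2 peak."""
    params = dict(
        label="M-SAO+formate",
        reaction=FORMATE_METHANOGENESIS,
        substrate="formate",
        substrate_initial=7.0,
        rate=0.2,
        h2_quasi_steady=40.6,
        include_formate_trace=False,
        detection_limits={},
    )
    params.update(overrides)
    return SimulationConfig(**params)


def generate_incubation(config: SimulationConfig) -> TimeSeries:
    """Simulate one batch incubation as a censored, replicated time series.

    Deterministic for a fixed config and seed: replicate noise streams are
    spawned from a single seed sequence.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    nu_s = abs(float(config.reaction.coefficient(config.substrate)))
    plateau = (
        config.h2_quasi_steady if config.consumer_present else config.h2_inhibited_ceiling
    )
    conds = config.medium()
    measurements: list[Measurement] = []

    def noisy(rng, value: float) -> float:
        if config.noise_sd == 0:
            return float(value)
        return max(0.0, float(value) * (1.0 + config.noise_sd * float(rng.standard_normal())))

    for rep_index, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        rep = f"r{rep_index + 1}"
        for t in config.sampling_times:
            consumed = min(config.rate * t, config.substrate_initial)
            if config.substrate_cap is not None:
                consumed = min(consumed, config.substrate_cap)
            substrate = config.substrate_initial - consumed
            extent = consumed / nu_s  # mmol reaction turnover per liter medium
            measurements.append(
                Measurement(t, rep, config.substrate, noisy(rng, substrate), "mM")
            )
            for species, coeff in config.reaction.stoichiometry.items():
                if coeff > 0 and species in _PRODUCT_UNITS:
                    amount = float(coeff) * extent
                    measurements.append(
                        Measurement(
                            t, rep, species, noisy(rng, amount), _PRODUCT_UNITS[species]
                        )
                    )
            h2 = float(plateau * -np.expm1(-t / config.h2_rise_tau))
            measurements.append(Measurement(t, rep, "H2", noisy(rng, h2), "Pa"))
            if config.include_formate_trace:
                if h2 > 0:
                    c = conds.replace()
                    c.gases["H2"] = h2
                    formate_mM = equilibrium_formate(c) / 1000.0
                else:
                    formate_mM = 0.0
                measurements.append(
                    Measurement(t, rep, "formate", noisy(rng, formate_mM), "mM")
                )

    series = TimeSeries(
        measurements,
        scenario=config.label,
        liquid_volume_mL=config.liquid_volume_mL,
        headspace_volume_mL=config.headspace_volume_mL,
        temperature=conds.temperature,
    )
    for analyte, limit in config.detection_limits.items():
        if analyte in series.analytes:
            series = apply_detection_limit(series, analyte, limit)
    return series
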