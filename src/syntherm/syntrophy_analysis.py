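"""Scenario-level bioenergetics of the acetate-oxidizing syntrophy.

A :class:`Scenario` couples a H2-producing acetate oxidation to an optional
H2-consuming partner reaction (methanogenesis or sulfate reduction) under one
set of medium conditions.  Evaluation reports each reaction's actual Gibbs
energy in both H2 frames (dG^1: pure-water solubility; dG^1*: soda-brine
salting-out), the formate concentration expected if the formate/H2 couple is
at equilibrium, critical H2 pressures, the syntrophic feasibility window and
the partitioning of the overall energy gain between the partners.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass

import pandas as pd

from .errors import (
    ActivityDomainError,
    ConfigError,
    UndefinedPartitionError,
    UsageError,
)
from .medium_chemistry import MediumConditions, build_activity_set
from .reactions import FORMATE_OXIDATION, get_reaction
from .thermo_core import (
    GibbsTable,
    R,
    Reaction,
    actual_delta_g,
    ln_reaction_quotient,
    standard_delta_g,
)

ROLES = ("producer", "consumer", "total")


@dataclass
class Scenario:
    """One incubation condition: reactions plus the medium they run in."""

    label: str
    producer_reaction: Reaction
    conditions: MediumConditions
    consumer_reaction: Reaction | None = None
    total_reaction: Reaction | None = None

    def __post_init__(self) -> None:
        if (
            self.consumer_reaction is not None
            and self.total_reaction is not None
        ):
            combined = self.producer_reaction + self.consumer_reaction
            if combined.stoichiometry != self.total_reaction.stoichiometry:
                raise ConfigError(
                    f"scenario {self.label!r}: producer + consumer does not equal "
                    f"the declared total reaction "
                    f"(got {combined.equation()}, expected "
                    f"{self.total_reaction.equation()})"
                )

    def reactions(self) -> list[tuple[str, Reaction]]:
        pairs = [("producer", self.producer_reaction)]
        if self.consumer_reaction is not None:
            pairs.append(("consumer", self.consumer_reaction))
        if self.total_reaction is not None:
            pairs.append(("total", self.total_reaction))
        return pairs


@dataclass(frozen=True)
class ReactionEnergy:
    """Actual Gibbs energies of one reaction in the two H2 frames, kJ/mol."""

    name: str
    role: str
    equation: str
    dg1: float
    dg1_star: float


@dataclass
class ScenarioResult:
    """Machine-readable per-scenario energy table."""

    label: str
    records: list[ReactionEnergy]
    h2_pa: float | None
    equilibrium_formate_uM: float | None

    def record(self, role: str) -> ReactionEnergy:
        for rec in self.records:
            if rec.role == role:
                return rec
        raise UsageError(f"scenario {self.label!r} has no {role!r} reaction")

    def delta_g(self, role: str, frame: str) -> float:
        rec = self.record(role)
        if frame == "pure_water":
            return rec.dg1
        if frame == "soda_corrected":
            return rec.dg1_star
        raise UsageError(f"unknown frame {frame!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.label,
                "reaction": rec.name,
                "role": rec.role,
                "equation": rec.equation,
                "h2_pa": self.h2_pa,
                "dG1_kJ_mol": rec.dg1,
                "dG1star_kJ_mol": rec.dg1_star,
            }
            for rec in self.records
        ]
        return pd.DataFrame(rows)


def evaluate_scenario(scenario: Scenario, table: GibbsTable | None = None) -> ScenarioResult:
    """Compute dG^1 and dG^1* for every reaction of *scenario*.

    The pure-water frame feeds dG^1 and the soda-corrected frame dG^1*; for
    reactions without H2 the two coincide.  When the conditions declare a H2
    partial pressure, the equilibrium formate concentration (in the
    conditions' own H2 frame) is attached.
    """
    table = table or GibbsTable.default()
    conds = scenario.conditions
    acts = {
        frame: build_activity_set(conds.replace(h2_frame=frame), table)
        for frame in ("pure_water", "soda_corrected")
    }
    records = []
    for role, reaction in scenario.reactions():
        dg1 = actual_delta_g(reaction, table, acts["pure_water"], conds.temperature)
        dg1s = actual_delta_g(reaction, table, acts["soda_corrected"], conds.temperature)
        records.append(
            ReactionEnergy(
                name=reaction.name,
                role=role,
                equation=reaction.equation(),
                dg1=dg1,
                dg1_star=dg1s,
            )
        )
    h2_pa = conds.gases.get("H2")
    formate = None
    if h2_pa and h2_pa > 0:
        formate = equilibrium_formate(conds, table)
    return ScenarioResult(
        label=scenario.label,
        records=records,
        h2_pa=h2_pa,
        equilibrium_formate_uM=formate,
    )


def equilibrium_formate(conditions: MediumConditions, table: GibbsTable | None = None) -> float:
    """Formate concentration (micromol/L) at dG = 0 for formate oxidation.

    Solves ``formate + H2O -> HCO3- + H2`` for the formate activity with all
    other activities fixed (H2 taken in the conditions' own frame), then
    converts the activity back to a concentration with the monovalent factor,
    because the estimate is compared against a detection limit expressed in
    concentration units.  Closed form: the unknown appears in a single log
    term.
    """
    table = table or GibbsTable.default()
    acts = build_activity_set(conditions, table)
    reaction = FORMATE_OXIDATION
    for required in ("H2", "HCO3-"):
        if required not in acts:
            raise ActivityDomainError(
                f"equilibrium formate needs a positive {required} "
                "partial pressure/concentration in the conditions"
            )
    dg0 = standard_delta_g(reaction, table)
    rt = R * conditions.temperature
    # dG = dG0 + RT*(lnQ_rest - ln a_formate) = 0, formate coefficient is -1
    others = Reaction("others", {s: c for s, c in reaction.stoichiometry.items() if s != "formate"})
    ln_a_formate = dg0 / rt + ln_reaction_quotient(others, acts)
    activity = math.exp(ln_a_formate)
    return activity / conditions.f_monovalent * 1e6


def critical_h2(
    reaction: Reaction,
    conditions: MediumConditions,
    table: GibbsTable | None = None,
    threshold: float = 0.0,
) -> float:
    """H2 partial pressure (Pa) at which *reaction* reaches dG = *threshold*.

    All activities except H2 are held fixed; since dG is log-linear in the H2
    pressure the answer is closed-form,

        p* = p_ref * exp((threshold - dG(p_ref)) / (nu_H2 * R * T)).

    The H2 frame is taken from *conditions*.
    """
    table = table or GibbsTable.default()
    nu = reaction.coefficient("H2")
    if nu == 0:
        raise UsageError(
            f"reaction {reaction.name!r} does not involve H2; no critical pressure"
        )
    p_ref = conditions.gases.get("H2") or 1.0
    conds = conditions.replace()
    conds.gases["H2"] = p_ref
    acts = build_activity_set(conds, table)
    dg_ref = actual_delta_g(reaction, table, acts, conds.temperature)
    rt = R * conds.temperature
    return p_ref * math.exp((threshold - dg_ref) / (float(nu) * rt))


@dataclass(frozen=True)
class H2Window:
    """H2 pressure interval in which both syntrophic partners are exergonic."""

    p_min: float
    p_max: float
    nonempty: bool

    def __contains__(self, pressure: float) -> bool:
        return self.nonempty and self.p_min < pressure < self.p_max


def h2_window(
    scenario: Scenario,
    table: GibbsTable | None = None,
    threshold: float = 0.0,
) -> H2Window:
    """Feasibility window {p : dG_producer(p) < thr and dG_consumer(p) < thr}.

    The producer makes H2 (positive coefficient), so its dG rises with the H2
    pressure and its critical pressure is the window ceiling; the consumer
    uses H2, so its critical pressure is the floor.
    """
    if scenario.consumer_reaction is None:
        raise UsageError(
            f"scenario {scenario.label!r} has no consumer reaction; "
            "a feasibility window needs both partners"
        )
    table = table or GibbsTable.default()
    bounds = {}
    for rxn in (scenario.producer_reaction, scenario.consumer_reaction):
        nu = rxn.coefficient("H2")
        if nu == 0:
            raise UsageError(f"reaction {rxn.name!r} does not involve H2")
        p_star = critical_h2(rxn, scenario.conditions, table, threshold)
        bounds["ceiling" if nu > 0 else "floor"] = p_star
    if "ceiling" not in bounds or "floor" not in bounds:
        raise UsageError(
            "the producer must form H2 and the consumer must consume it"
        )
    p_min, p_max = bounds["floor"], bounds["ceiling"]
    return H2Window(p_min=p_min, p_max=p_max, nonempty=p_min < p_max)


def energy_partition(result: ScenarioResult, frame: str) -> dict[str, float]:
    """Fraction of the total energy gain captured by each partner.

    Defined only when the total reaction is exergonic in the chosen frame;
    shares sum to 1 exactly.
    """
    producer = result.delta_g("producer", frame)
    consumer = result.delta_g("consumer", frame)
    total = result.delta_g("total", frame)
    if not total < 0:
        raise UndefinedPartitionError(
            f"total dG is {total:+.2f} kJ/mol in the {frame} frame; "
            "energy shares are undefined for a non-exergonic total"
        )
    producer_share = producer / total
    return {"producer_share": producer_share, "consumer_share": 1.0 - producer_share}


# -- scenario config files ---------------------------------------------------


def _resolve_reaction(spec, defines: dict[str, Reaction]) -> Reaction:
    if isinstance(spec, str):
        if spec in defines:
            return defines[spec]
        return get_reaction(spec)
    raise ConfigError(f"reaction reference must be a name string, got {spec!r}")


def load_scenario(source, table: GibbsTable | None = None) -> Scenario:
    """Read a scenario from a TOML file.

    The file carries the medium sections of
    :meth:`~syntherm.medium_chemistry.MediumConditions.from_toml` plus::

        [scenario]
        label = "M-SAO"

        [reactions]
        producer = "acetate_oxidation"       # built-in name or defined below
        consumer = "hydrogenotrophic_methanogenesis"   # optional
        total = "msao_total"                 # optional

        [reactions.define.my_reaction]       # optional inline stoichiometries
        "acetate" = -1.0
        "HCO3-" = 2.0

    """
    if hasattr(source, "read"):
        data = tomllib.load(source)
    else:
        with open(source, "rb") as fh:
            data = tomllib.load(fh)
    conditions = MediumConditions.from_toml_data(data)
    label = data.get("scenario", {}).get("label", "scenario")
    rxns = dict(data.get("reactions", {}))
    defines = {
        name: Reaction(name, stoich)
        for name, stoich in rxns.pop("define", {}).items()
    }
    if "producer" not in rxns:
        raise ConfigError("scenario file must name a producer reaction")
    producer = _resolve_reaction(rxns.pop("producer"), defines)
    consumer = total = None
    if "consumer" in rxns:
        consumer = _resolve_reaction(rxns.pop("consumer"), defines)
    if "total" in rxns:
        total = _resolve_reaction(rxns.pop("total"), defines)
    if rxns:
        raise ConfigError(f"unknown keys in [reactions]: {sorted(rxns)}")
    return Scenario(
        label=label,
        producer_reaction=producer,
        consumer_reaction=consumer,
        total_reaction=total,
        conditions=conditions,
    )


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Stack scenario results into one delimited-text-ready table."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
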