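"""Built-in catabolic reactions of the haloalkaline acetate-oxidizing syntrophy.

All reactions are written for pH ~9.5 soda-lake conditions: inorganic carbon
as bicarbonate, sulfide as HS-, carboxylic acids fully deprotonated.
"""

from __future__ import annotations

from .errors import ConfigError
from .thermo_core import Reaction

#: Syntrophic acetate oxidation to bicarbonate and hydrogen (the producer).
ACETATE_OXIDATION = Reaction(
    "acetate_oxidation",
    {"acetate": -1, "H2O": -4, "HCO3-": 2, "H2": 4, "H+": 1},
)

#: Hydrogenotrophic methanogenesis (the M-SAO consumer).
HYDROGENOTROPHIC_METHANOGENESIS = Reaction(
    "hydrogenotrophic_methanogenesis",
    {"H2": -4, "HCO3-": -1, "H+": -1, "CH4": 1, "H2O": 3},
)

#: Hydrogenotrophic sulfate reduction (the S-SAO consumer).
HYDROGENOTROPHIC_SULFATE_REDUCTION = Reaction(
    "hydrogenotrophic_sulfate_reduction",
    {"H2": -4, "SO4-2": -1, "H+": -1, "HS-": 1, "H2O": 4},
)

#: Formate oxidation to bicarbonate and hydrogen; its dG = 0 equilibrium sets
#: the formate level expected if formate and H2 are interchangeable carriers.
FORMATE_OXIDATION = Reaction(
    "formate_oxidation",
    {"formate": -1, "H2O": -1, "HCO3-": 1, "H2": 1},
)

#: Methanogenesis from formate (4:1 formate:methane).
FORMATE_METHANOGENESIS = Reaction(
    "formate_methanogenesis",
    {"formate": -4, "H+": -1, "H2O": -1, "CH4": 1, "HCO3-": 3},
)

#: Overall methanogenic acetate conversion (producer + consumer, H2 cancelled).
MSAO_TOTAL = Reaction(
    "msao_total",
    {"acetate": -1, "H2O": -1, "HCO3-": 1, "CH4": 1},
)

#: Overall sulfate-reducing acetate conversion.
SSAO_TOTAL = Reaction(
    "ssao_total",
    {"acetate": -1, "SO4-2": -1, "HCO3-": 2, "HS-": 1},
)

REACTIONS: dict[str, Reaction] = {
    r.name: r
    for r in (
        ACETATE_OXIDATION,
        HYDROGENOTROPHIC_METHANOGENESIS,
        HYDROGENOTROPHIC_SULFATE_REDUCTION,
        FORMATE_OXIDATION,
        FORMATE_METHANOGENESIS,
        MSAO_TOTAL,
        SSAO_TOTAL,
    )
}


def get_reaction(name: str) -> Reaction:
    """Look up a built-in reaction by name."""
    try:
        return REACTIONS[name]
    except KeyError:
        known = ", ".join(sorted(REACTIONS))
        raise ConfigError(f"unknown reaction {name!r}; built-ins: {known}") from None
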