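"""Species registry, reaction stoichiometry, and Gibbs energy arithmetic.

The central quantity is the actual Gibbs free energy change of a catabolic
reaction under in-situ conditions,

    dG = dG0 + R*T*ln(Q),

where dG0 is assembled from tabulated standard Gibbs free energies of
formation (298.15 K, pH 0 reference, 1 atm gas standard state) and Q is the
reaction quotient over dimensionless activities.  Stoichiometric coefficients
are stored as exact rationals so that element- and charge-balance checks are
exact, never a floating-point tolerance.
"""

from __future__ import annotations

import csv
import io
import math
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path

from .errors import (
    ActivityDomainError,
    ParseError,
    UnbalancedReactionError,
    UnknownSpeciesError,
)

#: Molar gas constant, kJ mol^-1 K^-1.
R = 8.314462618e-3

#: Reference temperature of the formation-energy table, K.
T_REF = 298.15

#: Standard-state pressure for gases, Pa (1 atm; classical dGf0 tables use atm).
P_STANDARD_PA = 101_325.0

PHASES = ("gas", "aqueous", "water")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an empirical formula like ``"C2H3O2"`` into an element-count map."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return counts


@dataclass(frozen=True)
class ChemicalSpecies:
    """A chemical species with its standard Gibbs free energy of formation.

    Parameters
    ----------
    name:
        Identifier used in reactions, tables and condition files.
    formula:
        Element -> count map (non-negative integers).
    charge:
        Elementary charge of the species.
    phase:
        ``"gas"``, ``"aqueous"`` or ``"water"``.
    dgf0:
        Standard Gibbs free energy of formation at 298.15 K, kJ/mol.
    """

    name: str
    formula: Mapping[str, int]
    charge: int
    phase: str
    dgf0: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", parse_formula(self.formula))
        for element, count in self.formula.items():
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(
                    f"formula count for {element} in {self.name} must be a "
                    f"non-negative integer, got {count!r}"
                )

    @property
    def ion_class(self) -> str:
        """``neutral``, ``monovalent`` or ``divalent`` from ``|charge|``."""
        magnitude = abs(self.charge)
        if magnitude == 0:
            return "neutral"
        if magnitude == 1:
            return "monovalent"
        if magnitude == 2:
            return "divalent"
        raise ValueError(f"no ion class defined for |charge| = {magnitude}")


def _as_fraction(value) -> Fraction:
    if isinstance(value, float):
        # route through repr so 0.5 -> 1/2, not a 53-bit binary artifact
        return Fraction(str(value))
    return Fraction(value)


@dataclass(frozen=True)
class Reaction:
    """A chemical reaction as a signed, exact-rational stoichiometry map.

    Products carry positive coefficients, reactants negative ones.
    """

    name: str
    stoichiometry: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        coeffs = {
            species: _as_fraction(c)
            for species, c in self.stoichiometry.items()
            if _as_fraction(c) != 0
        }
        object.__setattr__(self, "stoichiometry", coeffs)

    def coefficient(self, species: str) -> Fraction:
        return self.stoichiometry.get(species, Fraction(0))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.stoichiometry)

    def reversed(self, name: str | None = None) -> "Reaction":
        return Reaction(
            name or f"reverse({self.name})",
            {s: -c for s, c in self.stoichiometry.items()},
        )

    def __add__(self, other: "Reaction") -> "Reaction":
        combined = dict(self.stoichiometry)
        for species, c in other.stoichiometry.items():
            combined[species] = combined.get(species, Fraction(0)) + c
        return Reaction(f"{self.name} + {other.name}", combined)

    def scaled(self, factor, name: str | None = None) -> "Reaction":
        f = _as_fraction(factor)
        return Reaction(
            name or f"{factor}*({self.name})",
            {s: f * c for s, c in self.stoichiometry.items()},
        )

    def equation(self) -> str:
        """Human-readable ``reactants -> products`` string."""

        def side(items):
            parts = []
            for species, c in items:
                c = abs(c)
                prefix = "" if c == 1 else f"{c} "
                parts.append(f"{prefix}{species}")
            return " + ".join(parts) if parts else "(nothing)"

        reactants = [(s, c) for s, c in self.stoichiometry.items() if c < 0]
        products = [(s, c) for s, c in self.stoichiometry.items() if c > 0]
        return f"{side(reactants)} -> {side(products)}"


class GibbsTable(Mapping):
    """Name-indexed registry of :class:`ChemicalSpecies` with formation energies.

    Lookup of a missing name raises :class:`UnknownSpeciesError`; it is never
    silently treated as zero.
    """

    def __init__(self, entries: Mapping[str, ChemicalSpecies] | list, provenance: str = ""):
        if not isinstance(entries, Mapping):
            entries = {sp.name: sp for sp in entries}
        self._entries: dict[str, ChemicalSpecies] = dict(entries)
        self.provenance = provenance

    def __getitem__(self, name: str) -> ChemicalSpecies:
        try:
            return self._entries[name]
        except KeyError:
            raise UnknownSpeciesError(name) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_file(cls, source, provenance: str | None = None) -> "GibbsTable":
        """Load a table from delimited text.

        Expected columns: ``name, formula, charge, phase, dgf0_kJ_per_mol``;
        tab- or comma-delimited; ``#`` starts a comment line; UTF-8.
        """
        if hasattr(source, "read"):
            text = source.read()
            origin = provenance or "stream"
        else:
            text = Path(source).read_text(encoding="utf-8")
            origin = provenance or str(source)
        rows: list[tuple[int, list[str]]] = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, raw))
        if not rows:
            raise ParseError("no header row found")
        delim = "\t" if "\t" in rows[0][1] else ","
        header_line = next(csv.reader([rows[0][1]], delimiter=delim))
        header = [h.strip() for h in header_line]
        expected = ["name", "formula", "charge", "phase", "dgf0_kJ_per_mol"]
        if header != expected:
            raise ParseError(
                f"expected columns {expected}, got {header}", line=rows[0][0]
            )
        entries = {}
        for lineno, raw in rows[1:]:
            fields = [f.strip() for f in next(csv.reader([raw], delimiter=delim))]
            if len(fields) != len(expected):
                raise ParseError(
                    f"expected {len(expected)} fields, got {len(fields)}", line=lineno
                )
            try:
                sp = ChemicalSpecies(
                    name=fields[0],
                    formula=parse_formula(fields[1]),
                    charge=int(fields[2]),
                    phase=fields[3],
                    dgf0=float(fields[4]),
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            entries[sp.name] = sp
        return cls(entries, provenance=origin)

    _default: "GibbsTable | None" = None

    @classmethod
    def default(cls) -> "GibbsTable":
        """The shipped formation-energy table (Thauer et al. 1977 values)."""
        if cls._default is None:
            text = (
                resources.files("syntherm.data")
                .joinpath("formation_energies.tsv")
                .read_text(encoding="utf-8")
            )
            cls._default = cls.from_file(
                io.StringIO(text),
                provenance="Thauer, Jungermann & Decker (1977) Bacteriol. Rev. 41:100-180",
            )
        return cls._default


@dataclass(frozen=True)
class BalanceReport:
    """Element and charge residuals of a reaction (products minus reactants)."""

    element_residuals: Mapping[str, Fraction]
    charge_residual: Fraction
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        ok = self.charge_residual == 0 and all(
            r == 0 for r in self.element_residuals.values()
        )
        object.__setattr__(self, "passed", ok)


def validate_reaction_balance(reaction: Reaction, table: GibbsTable) -> BalanceReport:
    """Check element and charge conservation of *reaction* against *table*.

    Residuals are exact rationals; the report passes iff every residual is
    exactly zero.  Unknown species raise :class:`UnknownSpeciesError`.
    """
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    for name, coeff in reaction.stoichiometry.items():
        sp = table[name]
        for element, count in sp.formula.items():
            elements[element] = elements.get(element, Fraction(0)) + coeff * count
        charge += coeff * sp.charge
    return BalanceReport(element_residuals=elements, charge_residual=charge)


def standard_delta_g(reaction: Reaction, table: GibbsTable) -> float:
    """Standard Gibbs energy change dG0 = sum(coeff * dGf0), kJ/mol.

    Refuses unbalanced reactions: a dG0 of a non-conserving equation is
    meaningless and usually signals a typo in the stoichiometry.
    """
    report = validate_reaction_balance(reaction, table)
    if not report.passed:
        bad = {e: str(r) for e, r in report.element_residuals.items() if r != 0}
        raise UnbalancedReactionError(
            f"reaction {reaction.name!r} is unbalanced: element residuals {bad}, "
            f"charge residual {report.charge_residual}"
        )
    return float(sum(coeff * table[name].dgf0 for name, coeff in reaction.stoichiometry.items()))


def ln_reaction_quotient(reaction: Reaction, activities: Mapping[str, float]) -> float:
    """ln Q = sum(coeff * ln a) over every species with a nonzero coefficient."""
    total = 0.0
    for name, coeff in reaction.stoichiometry.items():
        try:
            a = activities[name]
        except KeyError:
            raise UnknownSpeciesError(name, context="activity set") from None
        if not (a > 0):
            raise ActivityDomainError(
                f"activity of {name!r} must be strictly positive, got {a!r}"
            )
        total += float(coeff) * math.log(a)
    return total


def actual_delta_g(
    reaction: Reaction,
    table: GibbsTable,
    activities: Mapping[str, float],
    temperature: float,
) -> float:
    """Actual Gibbs energy change dG = dG0 + R*T*ln(Q), kJ/mol.

    dG0 is used as tabulated at 298.15 K (no enthalpy correction); the RT
    factor uses the supplied *temperature*.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    dg0 = standard_delta_g(reaction, table)
    return dg0 + R * temperature * ln_reaction_quotient(reaction, activities)
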