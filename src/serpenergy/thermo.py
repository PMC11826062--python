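"""Thermodynamic constants for aqueous carbon, hydrogen and methane species.

Standard-state formation properties (25 degC, 1 bar) follow the
CODATA/SUPCRT-lineage compilations of Shock & Helgeson and Amend & Shock.
Reaction equilibrium constants are assembled from these by Hess's law, so
any linear combination of reactions is thermodynamically consistent by
construction, and are shifted to in-situ temperature with the van't Hoff
relation (adequate over the 19-36 degC range of serpentinized surface
fluids; the second-order heat-capacity terms are below display precision
there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Reference temperature for formation properties, K.
T_REF_K = 298.15

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SpeciesProps:
    """Standard-state properties of one aqueous species.

    ``dg_f`` and ``dh_f`` are Gibbs energy and enthalpy of formation at
    25 degC in kJ/mol; ``charge`` is the formal charge used by the
    activity model.
    """

    charge: int
    dg_f: float
    dh_f: float
    source: str = ""


# fmt: off
_DEFAULT_SPECIES: dict[str, SpeciesProps] = {
    "H2O":      SpeciesProps(0,  -237.18, -285.83, "CODATA 1989"),
    "H+":       SpeciesProps(1,     0.00,    0.00, "convention"),
    "OH-":      SpeciesProps(-1, -157.30, -230.02, "CODATA 1989"),
    "CO2":      SpeciesProps(0,  -385.98, -413.80, "Shock & Helgeson 1988"),
    "HCO3-":    SpeciesProps(-1, -586.94, -689.93, "Shock & Helgeson 1988"),
    "CO3-2":    SpeciesProps(-2, -527.98, -675.23, "Shock & Helgeson 1988"),
    "HCOOH":    SpeciesProps(0,  -372.30, -425.43, "Shock 1995"),
    "HCOO-":    SpeciesProps(-1, -350.90, -425.55, "Shock & Helgeson 1990"),
    "CH3COOH":  SpeciesProps(0,  -396.48, -485.76, "Shock 1995"),
    "CH3COO-":  SpeciesProps(-1, -369.31, -486.01, "Shock & Helgeson 1990"),
    "H2":       SpeciesProps(0,    17.72,   -4.20, "Shock & Helgeson 1988 (aq)"),
    "CH4":      SpeciesProps(0,   -34.35,  -87.81, "Shock & Helgeson 1988 (aq)"),
}
# fmt: on

# Acid/base dissociation reactions used by the speciation stage, written as
# stoichiometry maps (products positive, reactants negative).
_ACID_REACTIONS: dict[str, dict[str, float]] = {
    "ka1": {"CO2": -1, "H2O": -1, "HCO3-": 1, "H+": 1},
    "ka2": {"HCO3-": -1, "CO3-2": 1, "H+": 1},
    "ka_formic": {"HCOOH": -1, "HCOO-": 1, "H+": 1},
    "ka_acetic": {"CH3COOH": -1, "CH3COO-": 1, "H+": 1},
    "kw": {"H2O": -1, "OH-": 1, "H+": 1},
}


class MissingSpeciesError(KeyError):
    """A reaction references a species with no formation properties."""


@dataclass
class ThermoDB:
    """Formation-property database with derived equilibrium constants."""

    species: dict[str, SpeciesProps] = field(
        default_factory=lambda: dict(_DEFAULT_SPECIES)
    )
    gas_constant: float = R_GAS

    def props(self, name: str) -> SpeciesProps:
        try:
            return self.species[name]
        except KeyError:
            raise MissingSpeciesError(
                f"no formation properties for species {name!r}"
            ) from None

    def delta_g(self, stoichiometry: Mapping[str, float]) -> float:
        """Standard Gibbs energy of reaction at 25 degC, kJ/mol."""
        return sum(v * self.props(s).dg_f for s, v in stoichiometry.items())

    def delta_h(self, stoichiometry: Mapping[str, float]) -> float:
        """Standard enthalpy of reaction at 25 degC, kJ/mol."""
        return sum(v * self.props(s).dh_f for s, v in stoichiometry.items())

    def ln_k(self, stoichiometry: Mapping[str, float], temperature_c: float) -> float:
        """ln K of a reaction at ``temperature_c`` via van't Hoff.

        The 25 degC anchor comes from delta_rG = -RT ln K; the enthalpy of
        reaction (assumed T-independent) supplies the temperature slope.
        """
        t_k = temperature_c + 273.15
        ln_k25 = -self.delta_g(stoichiometry) * 1000.0 / (self.gas_constant * T_REF_K)
        dh = self.delta_h(stoichiometry) * 1000.0
        return ln_k25 - (dh / self.gas_constant) * (1.0 / t_k - 1.0 / T_REF_K)

    # -- derived acid constants -------------------------------------------

    def acid_constant(self, name: str, temperature_c: float = 25.0) -> float:
        """Dissociation constant K for one of ka1/ka2/ka_formic/ka_acetic/kw."""
        return math.exp(self.ln_k(_ACID_REACTIONS[name], temperature_c))

    def pka(self, name: str, temperature_c: float = 25.0) -> float:
        return -self.ln_k(_ACID_REACTIONS[name], temperature_c) / LN10

    # -- activity model support -------------------------------------------

    def davies_a(self, temperature_c: float) -> float:
        """Debye-Huckel A parameter (molal, log10 basis) vs temperature.

        Quadratic fit to the 0-60 degC values tabulated for water at
        saturation pressure; A(25) = 0.509.
        """
        t = temperature_c
        return 0.4913 + 6.083e-4 * t + 4.715e-6 * t * t

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "ThermoDB":
        """Load a species table from a YAML mapping name -> {charge, dg_f, dh_f, source}."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        species = {
            name: SpeciesProps(
                charge=int(rec["charge"]),
                dg_f=float(rec["dg_f"]),
                dh_f=float(rec["dh_f"]),
                source=str(rec.get("source", "")),
            )
            for name, rec in raw.get("species", raw).items()
        }
        return cls(species=species)

    def to_yaml(self, path) -> None:
        payload = {
            "species": {
                name: {
                    "charge": p.charge,
                    "dg_f": p.dg_f,
                    "dh_f": p.dh_f,
                    "source": p.source,
                }
                for name, p in self.species.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def default_thermo() -> ThermoDB:
    """The built-in compilation-backed database."""
    return ThermoDB()
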