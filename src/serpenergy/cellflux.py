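"""Diffusion-limited substrate delivery to a cell-sized sphere.

The steady-state diffusive flux to a perfectly absorbing sphere of radius R
is J = 4 pi D R (C_inf - C_R). C_inf is the bulk concentration of the
substrate (activities are taken as numerically equal to molarity in these
dilute fluids); C_R, the concentration at the cell surface, is bounded
below by the substrate concentration that would be in *equilibrium* with
the rest of the fluid for the metabolism consuming it — a cell cannot draw
its substrate below thermodynamic equilibrium. The resulting J is therefore
a physical upper limit ("potential flux") on substrate delivery, reported
in attomoles per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .energetics import (
    ACETOCLASTIC,
    FORMATOTROPHIC,
    HYDROGENOTROPHIC,
    Reaction,
    log_k,
)
from .samples import FluidSample, RunConfig
from .speciation import SpeciatedFluid, speciate
from .thermo import ThermoDB, default_thermo

SECONDS_PER_DAY = 86400.0
MOL_PER_L_TO_MOL_PER_M3 = 1e3
MOL_TO_AMOL = 1e18


@dataclass
class DiffusionTable:
    """Species diffusion coefficients in water at 25 degC, 1 bar (m^2/s)."""

    d: dict[str, float] = field(
        default_factory=lambda: {
            "CO2": 1.92e-9,
            "HCOOH": 1.52e-9,
            "CH3COOH": 1.19e-9,
            "HCO3-": 1.18e-9,
            "HCOO-": 1.45e-9,
            "CH3COO-": 1.09e-9,
        }
    )
    sources: dict[str, str] = field(
        default_factory=lambda: {
            "CO2": "Cadogan et al. 2014",
            "HCOOH": "Vitagliano & Lyons 1956",
            "CH3COOH": "Vitagliano & Lyons 1956",
            "HCO3-": "PhreeqC database",
            "HCOO-": "Vanysek 2000 (limiting ionic conductance)",
            "CH3COO-": "Vanysek 2000 (limiting ionic conductance)",
        }
    )

    def __post_init__(self) -> None:
        for sp, d in self.d.items():
            if d <= 0:
                raise ValueError(f"diffusion coefficient for {sp} must be > 0")

    def get(self, species: str) -> float:
        try:
            return self.d[species]
        except KeyError:
            raise KeyError(f"no diffusion coefficient for species {species!r}") from None


@dataclass
class FluxResult:
    """Potential diffusive flux of one species to one model cell."""

    site_id: str
    species: str
    d: float  # m^2/s
    radius: float  # m
    c_inf: Optional[float] = None  # mol/L
    c_r: Optional[float] = None  # mol/L
    j: Optional[float] = None  # amol/day
    clamped: bool = False  # True when C_inf < C_R forced J to 0


def equilibrium_substrate_activity(
    reaction: Reaction,
    fluid: SpeciatedFluid,
    substrate: str,
    temperature_c: Optional[float] = None,
    db: Optional[ThermoDB] = None,
) -> Optional[float]:
    """Substrate activity at which the reaction would be at equilibrium.

    Holding every other activity fixed, solve a_s^(v_s) * Q_rest = K for
    a_s (v_s is the substrate's negative stoichiometric coefficient):
    ln a_eq = (ln K - ln Q_rest) / v_s. Returns None if any other required
    activity is null or zero.
    """
    v_s = reaction.stoichiometry.get(substrate)
    if v_s is None or v_s >= 0:
        raise ValueError(f"{substrate!r} is not a reactant of {reaction.reaction_id}")
    db = db or default_thermo()
    t_c = fluid.sample.temperature if temperature_c is None else temperature_c
    ln_q_rest = 0.0
    for species, v in reaction.stoichiometry.items():
        if species == substrate:
            continue
        a = fluid.activity(species)
        if a is None or a <= 0.0:
            return None
        ln_q_rest += v * math.log(a)
    ln_kr = log_k(reaction, t_c, db)
    return math.exp((ln_kr - ln_q_rest) / v_s)


def potential_flux(
    d: float, radius: float, c_inf: float, c_r: float
) -> tuple[float, bool]:
    """J = 4 pi D R (C_inf - C_R) in amol/day; clamps negative gradients.

    Returns (flux, clamped). Concentrations are mol/L.
    """
    if d < 0 or radius < 0 or c_inf < 0 or c_r < 0:
        raise ValueError("potential_flux inputs must be non-negative")
    gradient = c_inf - c_r
    clamped = gradient < 0
    gradient = max(gradient, 0.0)
    j_si = 4.0 * math.pi * d * radius * gradient * MOL_PER_L_TO_MOL_PER_M3  # mol/s
    return j_si * SECONDS_PER_DAY * MOL_TO_AMOL, clamped


#: flux species -> (metabolism, anion substrate of that metabolism,
#:                  acid-constant name linking acid and anion; None = is the anion)
_FLUX_SPECIES = {
    "CO2": (HYDROGENOTROPHIC, "HCO3-", "ka1"),
    "HCOOH": (FORMATOTROPHIC, "HCOO-", "ka_formic"),
    "CH3COOH": (ACETOCLASTIC, "CH3COO-", "ka_acetic"),
    "HCO3-": (HYDROGENOTROPHIC, "HCO3-", None),
    "HCOO-": (FORMATOTROPHIC, "HCOO-", None),
    "CH3COO-": (ACETOCLASTIC, "CH3COO-", None),
}

#: column order of published potential-flux tables
FLUX_SPECIES_ORDER = ("CO2", "HCOOH", "CH3COOH", "HCO3-", "HCOO-", "CH3COO-")


def flux_table(
    samples: Sequence[FluidSample],
    db: Optional[ThermoDB] = None,
    config: Optional[RunConfig] = None,
    diffusion: Optional[DiffusionTable] = None,
) -> list[FluxResult]:
    """Potential fluxes of the six substrate species for every sample.

    For each anion the boundary concentration C_R is the equilibrium
    activity for its metabolism; the paired neutral acid is then placed at
    acid-base equilibrium with that anion at the sample pH. Activities are
    converted to concentrations with gamma = 1. Missing inputs (no CH4
    activity, unmeasured pools) leave blank cells.
    """
    db = db or default_thermo()
    config = config or RunConfig()
    diffusion = diffusion or DiffusionTable()
    radius = config.cell_radius
    out: list[FluxResult] = []
    for sample in samples:
        fluid = speciate(sample, db, config)
        a_h = 10.0 ** (-sample.ph)
        # one equilibrium anion activity per metabolism, reused by the acid
        a_eq_anion: dict[str, Optional[float]] = {}
        for reaction, anion in [
            (HYDROGENOTROPHIC, "HCO3-"),
            (FORMATOTROPHIC, "HCOO-"),
            (ACETOCLASTIC, "CH3COO-"),
        ]:
            a_eq_anion[anion] = equilibrium_substrate_activity(
                reaction, fluid, anion, db=db
            )
        for species in FLUX_SPECIES_ORDER:
            _, anion, ka_name = _FLUX_SPECIES[species]
            d = diffusion.get(species)
            result = FluxResult(
                site_id=sample.site_id, species=species, d=d, radius=radius
            )
            c_inf = fluid.activity(species)
            a_eq = a_eq_anion[anion]
            if c_inf is not None and a_eq is not None:
                if ka_name is None:
                    c_r = a_eq
                else:
                    ka = db.acid_constant(ka_name, sample.temperature)
                    c_r = a_eq * a_h / ka  # acid in equilibrium with the anion
                result.c_inf = c_inf
                result.c_r = c_r
                result.j, result.clamped = potential_flux(d, radius, c_inf, c_r)
            out.append(result)
    return out
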