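"""Aqueous speciation of measured totals into individual species activities.

Measured pools (DIC, total formate, total acetate) are distributed over
their acid/base partners by mass action at the sample pH, with Davies-model
activity coefficients. H2(aq) and CH4(aq) are carried as neutral species at
their measured molalities. The carbon pools are treated as mutually
independent: no redox interconversion happens during speciation (DIC never
becomes formate, etc.), mirroring standard practice of suppressing redox
couples when speciating a disequilibrium fluid.

Closed-form ionization fractions are used throughout; for a diprotic or
monoprotic system at fixed pH the distribution is exact, so pool mass
balance holds to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .samples import FluidSample, RunConfig, ValidationError
from .thermo import ThermoDB, default_thermo

#: the species tracked for every fluid
SPECIES_SET = (
    "CO2",
    "HCO3-",
    "CO3-2",
    "HCOOH",
    "HCOO-",
    "CH3COOH",
    "CH3COO-",
    "H2",
    "CH4",
    "H+",
    "OH-",
    "H2O",
)

#: formal charges used by the activity model
CHARGES = {
    "CO2": 0,
    "HCO3-": -1,
    "CO3-2": -2,
    "HCOOH": 0,
    "HCOO-": -1,
    "CH3COOH": 0,
    "CH3COO-": -1,
    "H2": 0,
    "CH4": 0,
    "H+": 1,
    "OH-": -1,
    "H2O": 0,
}

DAVIES_I_MAX = 0.5  # mol/kg; validity ceiling of the Davies equation


@dataclass(frozen=True)
class SpeciesState:
    """Molality, activity coefficient, and activity of one species."""

    m: Optional[float]
    gamma: Optional[float]
    activity: Optional[float]


_NULL_STATE = SpeciesState(None, None, None)


@dataclass
class SpeciatedFluid:
    """A fluid sample resolved into species activities."""

    sample: FluidSample
    ionic_strength: float
    species: dict[str, SpeciesState]

    def activity(self, name: str) -> Optional[float]:
        state = self.species.get(name)
        return None if state is None else state.activity

    def molality(self, name: str) -> Optional[float]:
        state = self.species.get(name)
        return None if state is None else state.m


def ionic_strength(sample: FluidSample, config: RunConfig) -> float:
    """I = 1/2 sum m_i z_i^2, or the configured default.

    When a sample carries major-ion data the sum runs over those ions plus
    the measured charged analytes (DIC counted as HCO3-, formate and
    acetate as their anions; a deliberately coarse single-pass estimate,
    since in these dilute fluids the analytes contribute little next to
    Na/Cl/Ca). Without major-ion data the configured default applies.
    """
    _KNOWN_CHARGES = {
        "na+": 1, "k+": 1, "cl-": -1, "ca+2": 2, "mg+2": 2,
        "ca2+": 2, "mg2+": 2, "so4-2": -2, "br-": -1, "no3-": -1,
    }
    if sample.major_ions is None:
        return config.default_ionic_strength
    total = 0.0
    for ion, m in sample.major_ions.items():
        if m < 0:
            raise ValidationError(f"{sample.site_id}: negative molality for {ion}")
        z = _KNOWN_CHARGES.get(ion.strip().lower())
        if z is None:
            raise ValidationError(f"{sample.site_id}: unknown major ion {ion!r}")
        total += m * z * z
    for analyte in (sample.dic, sample.formate_total, sample.acetate_total):
        if analyte is not None:
            total += analyte  # z = 1 for the dominant anion of each pool
    return 0.5 * total


def activity_coefficient(
    charge: int, i: float, temperature_c: float, db: Optional[ThermoDB] = None
) -> float:
    """Davies-equation activity coefficient.

    log10(gamma) = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I); gamma = 1 for
    neutral species. Valid only for I <= 0.5 mol/kg.
    """
    if i < 0 or i > DAVIES_I_MAX:
        raise ValidationError(
            f"ionic strength {i} outside Davies validity range [0, {DAVIES_I_MAX}]"
        )
    if charge == 0:
        return 1.0
    db = db or default_thermo()
    a = db.davies_a(temperature_c)
    sqrt_i = math.sqrt(i)
    log_g = -a * charge * charge * (sqrt_i / (1.0 + sqrt_i) - 0.3 * i)
    return 10.0 ** log_g


def _gammas(i: float, temperature_c: float, db: ThermoDB) -> dict[int, float]:
    return {z: activity_coefficient(z, i, temperature_c, db) for z in (0, 1, 2)}


def speciate_dic(
    dic_total: float,
    ph: float,
    temperature_c: float,
    gammas: dict[int, float],
    db: ThermoDB,
) -> dict[str, SpeciesState]:
    """Distribute a DIC pool over CO2(aq), HCO3- and CO3-2.

    Mass action is honored on *activities* (a_HCO3/a_CO2 = Ka1/a_H+ etc.)
    while the molalities sum exactly to the measured total.
    """
    if dic_total < 0:
        raise ValidationError("dic_total must be >= 0")
    a_h = 10.0 ** (-ph)
    ka1 = db.acid_constant("ka1", temperature_c)
    ka2 = db.acid_constant("ka2", temperature_c)
    g0, g1, g2 = gammas[0], gammas[1], gammas[2]
    # molality ratios implied by mass action on activities
    r1 = (ka1 / a_h) * (g0 / g1)  # m_HCO3 / m_CO2
    r2 = (ka2 / a_h) * (g1 / g2)  # m_CO3 / m_HCO3
    m_co2 = dic_total / (1.0 + r1 + r1 * r2)
    m_hco3 = m_co2 * r1
    m_co3 = m_hco3 * r2
    return {
        "CO2": SpeciesState(m_co2, g0, m_co2 * g0),
        "HCO3-": SpeciesState(m_hco3, g1, m_hco3 * g1),
        "CO3-2": SpeciesState(m_co3, g2, m_co3 * g2),
    }


def speciate_monoprotic(
    total: float,
    pka: float,
    ph: float,
    gammas: dict[int, float],
) -> tuple[SpeciesState, SpeciesState]:
    """Distribute a monoprotic acid pool; returns (HA, A-) states."""
    if total < 0:
        raise ValidationError("pool total must be >= 0")
    a_h = 10.0 ** (-ph)
    ka = 10.0 ** (-pka)
    g0, g1 = gammas[0], gammas[1]
    r = (ka / a_h) * (g0 / g1)  # m_A / m_HA
    m_ha = total / (1.0 + r)
    m_a = total - m_ha
    return (
        SpeciesState(m_ha, g0, m_ha * g0),
        SpeciesState(m_a, g1, m_a * g1),
    )


def speciate(
    sample: FluidSample,
    db: Optional[ThermoDB] = None,
    config: Optional[RunConfig] = None,
) -> SpeciatedFluid:
    """Full speciation of one sample.

    Null measured pools yield null species entries for that pool while the
    others are still computed; a(H+) = 10^-pH and a(H2O) = 1 by convention.
    """
    db = db or default_thermo()
    config = config or RunConfig()
    i = ionic_strength(sample, config)
    g = _gammas(i, sample.temperature, db)
    species: dict[str, SpeciesState] = {}

    if sample.dic is not None:
        species.update(speciate_dic(sample.dic, sample.ph, sample.temperature, g, db))
    else:
        species.update({k: _NULL_STATE for k in ("CO2", "HCO3-", "CO3-2")})

    if sample.formate_total is not None:
        pka_f = db.pka("ka_formic", sample.temperature)
        ha, a = speciate_monoprotic(sample.formate_total, pka_f, sample.ph, g)
        species["HCOOH"], species["HCOO-"] = ha, a
    else:
        species["HCOOH"] = species["HCOO-"] = _NULL_STATE

    if sample.acetate_total is not None:
        pka_a = db.pka("ka_acetic", sample.temperature)
        ha, a = speciate_monoprotic(sample.acetate_total, pka_a, sample.ph, g)
        species["CH3COOH"], species["CH3COO-"] = ha, a
    else:
        species["CH3COOH"] = species["CH3COO-"] = _NULL_STATE

    for name, value in (("H2", sample.h2), ("CH4", sample.ch4)):
        if value is None:
            species[name] = _NULL_STATE
        else:
            species[name] = SpeciesState(value, 1.0, value)  # neutral, gamma = 1

    a_h = 10.0 ** (-sample.ph)
    species["H+"] = SpeciesState(a_h / g[1], g[1], a_h)
    kw = db.acid_constant("kw", sample.temperature)
    a_oh = kw / a_h
    species["OH-"] = SpeciesState(a_oh / g[1], g[1], a_oh)
    species["H2O"] = SpeciesState(None, 1.0, 1.0)  # solvent: unit activity

    return SpeciatedFluid(sample=sample, ionic_strength=i, species=species)
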