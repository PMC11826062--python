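"""Chemical affinity and per-kg energy supply of methanogenic catabolisms.

Three catabolic routes to CH4 are modeled:

* hydrogenotrophic:  4 H2 + HCO3- + H+ -> CH4 + 3 H2O
* formatotrophic:    4 HCOO- + H+ + H2O -> CH4 + 3 HCO3-
* acetoclastic:      CH3COO- + H2O -> CH4 + HCO3-

For a reaction r, affinity A_r = R T ln(K_r/Q_r) measures the energy
released per mole of reaction turnover at in-situ conditions (positive =
forward-favorable), and is reported per mole of CH4 produced. The energy
*supply* E_r = A_r * m_lim / v_lim is the energy density of one kilogram of
fluid if the reaction runs until its limiting substrate pool is exhausted.
The limiting pool is the measured total of each candidate substrate (the
whole DIC pool for HCO3-, etc.), because as the named reactant is consumed
the pool re-equilibrates to resupply it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .samples import FluidSample, RunConfig
from .speciation import SpeciatedFluid, speciate
from .thermo import ThermoDB, default_thermo


@dataclass(frozen=True)
class Reaction:
    """A catabolic reaction: signed stoichiometry plus limiting-pool map.

    ``substrate_pools`` maps each limiting-candidate reactant species to
    the FluidSample pool attribute holding its measured total. H+ and H2O
    are never candidates (solvent and pH are buffered at the kg scale).
    """

    reaction_id: str
    stoichiometry: Mapping[str, float]
    substrate_pools: Mapping[str, str]
    ch4_per_unit: float = 1.0


HYDROGENOTROPHIC = Reaction(
    "hydrogenotrophic",
    {"H2": -4, "HCO3-": -1, "H+": -1, "CH4": 1, "H2O": 3},
    {"H2": "h2", "HCO3-": "dic"},
)
FORMATOTROPHIC = Reaction(
    "formatotrophic",
    {"HCOO-": -4, "H+": -1, "H2O": -1, "CH4": 1, "HCO3-": 3},
    {"HCOO-": "formate_total"},
)
ACETOCLASTIC = Reaction(
    "acetoclastic",
    {"CH3COO-": -1, "H2O": -1, "CH4": 1, "HCO3-": 1},
    {"CH3COO-": "acetate_total"},
)

REACTIONS: dict[str, Reaction] = {
    r.reaction_id: r for r in (HYDROGENOTROPHIC, FORMATOTROPHIC, ACETOCLASTIC)
}

#: formate hydrolysis (CHO2- + H2O -> HCO3- + H2); the Hess bridge between
#: the formatotrophic and hydrogenotrophic routes.
FORMATE_HYDROLYSIS = Reaction(
    "formate_hydrolysis",
    {"HCOO-": -1, "H2O": -1, "HCO3-": 1, "H2": 1},
    {"HCOO-": "formate_total"},
)

#: pool attribute -> human-readable pool label
POOL_LABELS = {
    "h2": "H2",
    "dic": "DIC",
    "formate_total": "formate",
    "acetate_total": "acetate",
}

#: carbon substrates win limiting-reactant ties
_CARBON_SUBSTRATES = {"HCO3-", "HCOO-", "CH3COO-"}


@dataclass
class EnergyResult:
    """Affinity and energy supply of one reaction at one site."""

    site_id: str
    reaction_id: str
    ln_k: Optional[float] = None
    ln_q: Optional[float] = None
    delta_g: Optional[float] = None  # J per mole reaction
    affinity: Optional[float] = None  # kJ per mole CH4
    limiting_species: Optional[str] = None
    m_lim: Optional[float] = None  # molal
    v_lim: Optional[int] = None
    energy_supply: Optional[float] = None  # J per kg fluid


def log_k(reaction: Reaction, temperature_c: float, db: Optional[ThermoDB] = None) -> float:
    """ln K_r at temperature, assembled by Hess from formation properties."""
    if not (0.0 <= temperature_c <= 100.0):
        raise ValueError(f"temperature {temperature_c} degC outside [0, 100]")
    db = db or default_thermo()
    return db.ln_k(reaction.stoichiometry, temperature_c)


def reaction_quotient(reaction: Reaction, fluid: SpeciatedFluid) -> Optional[float]:
    """ln Q_r = sum_i v_i ln a_i; None if any required activity is null or 0."""
    total = 0.0
    for species, v in reaction.stoichiometry.items():
        a = fluid.activity(species)
        if a is None or a <= 0.0:
            return None  # unevaluable: missing datum or zero activity
        total += v * math.log(a)
    return total


def affinity(
    reaction: Reaction,
    fluid: SpeciatedFluid,
    temperature_c: Optional[float] = None,
    db: Optional[ThermoDB] = None,
) -> EnergyResult:
    """Affinity of ``reaction`` in ``fluid``: A = R T ln(K/Q), kJ/mol CH4.

    Returns a partial EnergyResult (no limiting-reactant or supply fields).
    Null activities propagate to a null affinity.
    """
    db = db or default_thermo()
    t_c = fluid.sample.temperature if temperature_c is None else temperature_c
    ln_kr = log_k(reaction, t_c, db)
    ln_qr = reaction_quotient(reaction, fluid)
    result = EnergyResult(
        site_id=fluid.sample.site_id, reaction_id=reaction.reaction_id, ln_k=ln_kr
    )
    if ln_qr is None:
        return result
    t_k = t_c + 273.15
    a_per_unit = db.gas_constant * t_k * (ln_kr - ln_qr) / 1000.0  # kJ/mol rxn
    result.ln_q = ln_qr
    result.affinity = a_per_unit / reaction.ch4_per_unit
    result.delta_g = -a_per_unit * 1000.0  # J per mole reaction
    return result


def limiting_reactant(
    reaction: Reaction, sample: FluidSample
) -> Optional[tuple[str, float, int]]:
    """(species, pool molality, |v|) of the stoichiometrically limiting pool.

    The limiting candidate minimizes m_pool/|v|; ties go to the carbon
    substrate. Returns None when any candidate pool is unmeasured.
    """
    best: Optional[tuple[str, float, int]] = None
    best_ratio = math.inf
    for species, pool_attr in reaction.substrate_pools.items():
        m = getattr(sample, pool_attr)
        if m is None:
            return None
        v = int(abs(reaction.stoichiometry[species]))
        ratio = m / v
        better = ratio < best_ratio or (
            ratio == best_ratio and species in _CARBON_SUBSTRATES
        )
        if better:
            best = (species, m, v)
            best_ratio = ratio
    return best


def energy_supply(
    affinity_kj_per_mol: Optional[float],
    m_lim: Optional[float],
    v_lim: Optional[int],
) -> Optional[float]:
    """E_r = A_r * m_lim / v_lim in J per kg fluid, clamped at 0.

    A thermodynamically unfavorable reaction (A <= 0) supplies no energy;
    the affinity itself stays signed, only the supply clamps.
    """
    if affinity_kj_per_mol is None or m_lim is None or v_lim is None:
        return None
    if m_lim < 0 or v_lim < 1:
        raise ValueError("m_lim must be >= 0 and v_lim >= 1")
    return max(affinity_kj_per_mol, 0.0) * 1000.0 * m_lim / v_lim


def evaluate_reaction(
    reaction: Reaction,
    fluid: SpeciatedFluid,
    db: Optional[ThermoDB] = None,
) -> EnergyResult:
    """Affinity plus limiting-reactant bookkeeping and energy supply."""
    result = affinity(reaction, fluid, db=db)
    lim = limiting_reactant(reaction, fluid.sample)
    if lim is not None:
        species, m, v = lim
        result.limiting_species = species
        result.m_lim = m
        result.v_lim = v
        result.energy_supply = energy_supply(result.affinity, m, v)
    return result


def energetics_table(
    samples: Sequence[FluidSample],
    db: Optional[ThermoDB] = None,
    config: Optional[RunConfig] = None,
) -> list[EnergyResult]:
    """Evaluate all three reactions for every sample (long format)."""
    db = db or default_thermo()
    config = config or RunConfig()
    out: list[EnergyResult] = []
    for sample in samples:
        fluid = speciate(sample, db, config)
        for reaction in REACTIONS.values():
            out.append(evaluate_reaction(reaction, fluid, db))
    return out


def energetics_frame(results: Sequence[EnergyResult], samples: Sequence[FluidSample]) -> pd.DataFrame:
    """Wide per-site table: pH, Si, one affinity and one supply column per
    reaction, mirroring the layout of published energy-availability tables."""
    by_site = {s.site_id: s for s in samples}
    rows: dict[str, dict] = {}
    for r in results:
        row = rows.setdefault(
            r.site_id,
            {
                "site_id": r.site_id,
                "ph": by_site[r.site_id].ph if r.site_id in by_site else None,
                "si_molal": by_site[r.site_id].si if r.site_id in by_site else None,
            },
        )
        row[f"affinity_{r.reaction_id}"] = r.affinity
        row[f"supply_{r.reaction_id}"] = r.energy_supply
    cols = ["site_id", "ph", "si_molal"]
    for rid in REACTIONS:
        cols.append(f"affinity_{rid}")
    for rid in REACTIONS:
        cols.append(f"supply_{rid}")
    return pd.DataFrame(list(rows.values()), columns=cols)
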