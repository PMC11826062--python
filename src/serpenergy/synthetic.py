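"""Seeded generator of Table-2-like serpentinized-fluid chemistries.

Emulates the two water types of a serpentinizing ophiolite aquifer and
their mixtures: hyperalkaline Type II fluids (pH ~11.2-11.65, micromolal Si
and DIC, H2 up to millimolal) and circumneutral Type I groundwater (high Si
and DIC, vanishing H2), with mixed fluids built by conservative two-end-
member blending so that Si and DIC covary as they do in the field.
Analyte concentrations are lognormal (they are strictly positive and span
orders of magnitude); pH is truncated-normal per type and linearly
interpolated for mixtures (a declared approximation: true mixing pH is set
by titration of the carbonate system, which is out of scope here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .energetics import REACTIONS, log_k
from .samples import FluidSample, FluidType
from .speciation import speciate
from .thermo import ThermoDB, default_thermo

#: analytes blended conservatively between end-members
CONSERVATIVE_ANALYTES = ("si", "dic", "h2", "ch4", "formate_total", "acetate_total")


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal analyte distribution by median and geometric sd."""

    median: float
    gsd: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("lognormal median must be > 0")
        if self.gsd <= 1:
            raise ValueError("geometric sd must be > 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median), math.log(self.gsd), size=n))


@dataclass(frozen=True)
class TypeDistributions:
    """Per-fluid-type analyte distributions."""

    ph_mean: float
    ph_sd: float
    ph_bounds: tuple[float, float]
    analytes: dict[str, LognormalSpec]

    def sample_ph(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo, hi = self.ph_bounds
        a = (lo - self.ph_mean) / self.ph_sd
        b = (hi - self.ph_mean) / self.ph_sd
        return stats.truncnorm.rvs(
            a, b, loc=self.ph_mean, scale=self.ph_sd, size=n, random_state=rng
        )


def _default_type2() -> TypeDistributions:
    return TypeDistributions(
        ph_mean=11.4,
        ph_sd=0.12,
        ph_bounds=(11.2, 11.65),
        analytes={
            "si": LognormalSpec(3e-6, 1.8),
            "dic": LognormalSpec(4e-5, 2.0),
            "h2": LognormalSpec(5e-5, 10.0),
            "ch4": LognormalSpec(3e-4, 3.0),
            "formate_total": LognormalSpec(1.5e-6, 2.0),
            "acetate_total": LognormalSpec(2e-6, 1.6),
        },
    )


def _default_type1() -> TypeDistributions:
    return TypeDistributions(
        ph_mean=7.9,
        ph_sd=0.3,
        ph_bounds=(7.0, 8.7),
        analytes={
            "si": LognormalSpec(5e-4, 1.3),
            "dic": LognormalSpec(3e-3, 1.5),
            "h2": LognormalSpec(3e-8, 3.0),
            "ch4": LognormalSpec(1e-8, 3.0),
            "formate_total": LognormalSpec(1e-6, 2.0),
            "acetate_total": LognormalSpec(5e-7, 2.0),
        },
    )


def _default_endmember(dists: TypeDistributions, si: float) -> dict[str, float]:
    vec = {name: spec.median for name, spec in dists.analytes.items()}
    vec["si"] = si
    vec["ph"] = dists.ph_mean
    return vec


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults emulate the field data ranges."""

    seed: int = 0
    n_type1: int = 1
    n_type2: int = 16
    n_mixed: int = 14
    temperature_range: tuple[float, float] = (19.0, 36.0)
    type1: TypeDistributions = field(default_factory=_default_type1)
    type2: TypeDistributions = field(default_factory=_default_type2)
    type1_endmember: dict[str, float] = field(
        default_factory=lambda: _default_endmember(_default_type1(), 8.5e-4)
    )
    type2_endmember: dict[str, float] = field(
        default_factory=lambda: _default_endmember(_default_type2(), 1.4e-6)
    )
    mixing_noise_gsd: float = 1.2

    def __post_init__(self) -> None:
        if min(self.n_type1, self.n_type2, self.n_mixed) < 0:
            raise ValueError("sample counts must be >= 0")


def endmember_mix(
    f: float,
    type1_endmember: dict[str, float],
    type2_endmember: dict[str, float],
) -> dict[str, float]:
    """Blend end-members: fraction ``f`` of Type II, (1-f) of Type I.

    Conservative analytes mix linearly; pH is interpolated between the
    end-member pH values (non-conservative approximation, see module
    docstring).
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"mixing fraction {f} outside [0, 1]")
    missing = [
        k for k in (*CONSERVATIVE_ANALYTES, "ph")
        if k not in type1_endmember or k not in type2_endmember
    ]
    if missing:
        raise ValueError(f"end-member vectors incomplete: missing {missing}")
    out = {
        k: f * type2_endmember[k] + (1.0 - f) * type1_endmember[k]
        for k in CONSERVATIVE_ANALYTES
    }
    out["ph"] = f * type2_endmember["ph"] + (1.0 - f) * type1_endmember["ph"]
    return out


def _pure_samples(
    rng: np.random.Generator,
    dists: TypeDistributions,
    n: int,
    fluid_type: FluidType,
    t_range: tuple[float, float],
    prefix: str,
) -> list[FluidSample]:
    ph = dists.sample_ph(rng, n)
    temp = rng.uniform(*t_range, size=n)
    draws = {name: spec.sample(rng, n) for name, spec in dists.analytes.items()}
    return [
        FluidSample(
            site_id=f"{prefix}{i:03d}",
            fluid_type=fluid_type,
            ph=float(ph[i]),
            temperature=float(temp[i]),
            si=float(draws["si"][i]),
            dic=float(draws["dic"][i]),
            h2=float(draws["h2"][i]),
            ch4=float(draws["ch4"][i]),
            formate_total=float(draws["formate_total"][i]),
            acetate_total=float(draws["acetate_total"][i]),
        )
        for i in range(n)
    ]


def generate(config: Optional[SyntheticConfig] = None) -> list[FluidSample]:
    """Deterministic synthetic sample set for a given (seed, config)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    samples: list[FluidSample] = []
    samples += _pure_samples(
        rng, config.type1, config.n_type1, FluidType.TYPE1,
        config.temperature_range, "SYN-T1-",
    )
    samples += _pure_samples(
        rng, config.type2, config.n_type2, FluidType.TYPE2,
        config.temperature_range, "SYN-T2-",
    )
    ln_noise_sd = math.log(config.mixing_noise_gsd)
    for i in range(config.n_mixed):
        f = float(rng.uniform(0.0, 1.0))
        mix = endmember_mix(f, config.type1_endmember, config.type2_endmember)
        noise = np.exp(rng.normal(0.0, ln_noise_sd, size=len(CONSERVATIVE_ANALYTES)))
        temp = float(rng.uniform(*config.temperature_range))
        vals = {
            k: float(mix[k] * noise[j]) for j, k in enumerate(CONSERVATIVE_ANALYTES)
        }
        samples.append(
            FluidSample(
                site_id=f"SYN-MX-{i:03d}",
                fluid_type=FluidType.MIXED,
                ph=float(mix["ph"]),
                temperature=temp,
                si=vals["si"],
                dic=vals["dic"],
                h2=vals["h2"],
                ch4=vals["ch4"],
                formate_total=vals["formate_total"],
                acetate_total=vals["acetate_total"],
            )
        )
    return samples


def make_limiting_scenario(
    reaction_id: str, target_limiting: str, seed: int
) -> FluidSample:
    """A Type II-like sample whose limiting reactant is guaranteed.

    The target pool is scaled so its m/|v| ratio sits at most half the
    smallest competing ratio (a factor >= 2 margin).
    """
    reaction = REACTIONS[reaction_id]
    if target_limiting not in reaction.substrate_pools:
        raise ValueError(
            f"{target_limiting!r} is not a limiting candidate of {reaction_id}"
        )
    rng = np.random.default_rng(seed)
    base = _pure_samples(
        rng, _default_type2(), 1, FluidType.TYPE2, (19.0, 36.0),
        f"SYN-LIM-{reaction_id[:4]}-",
    )[0]
    pools = {
        sp: getattr(base, attr) for sp, attr in reaction.substrate_pools.items()
    }
    others = [
        pools[sp] / abs(reaction.stoichiometry[sp])
        for sp in pools
        if sp != target_limiting
    ]
    if others:
        margin = float(rng.uniform(0.1, 0.5))  # <= half the best competitor
        target_ratio = min(others) * margin
        v_t = abs(reaction.stoichiometry[target_limiting])
        attr = reaction.substrate_pools[target_limiting]
        base = replace(base, **{attr: target_ratio * v_t})
    return base


def make_affinity_scenario(
    reaction_id: str,
    target_affinity_kj: float,
    seed: int,
    db: Optional[ThermoDB] = None,
) -> FluidSample:
    """A sample whose CH4 content is tuned to a prescribed affinity.

    Because CH4(aq) is neutral (activity = molality), the CH4 molality
    giving affinity A follows in closed form from
    ln a_CH4 = ln K - ln Q_rest - 1000 A / (R T).
    """
    db = db or default_thermo()
    reaction = REACTIONS[reaction_id]
    sample = make_limiting_scenario(
        reaction_id, next(iter(reaction.substrate_pools)), seed
    )
    fluid = speciate(sample, db)
    ln_q_rest = 0.0
    for species, v in reaction.stoichiometry.items():
        if species == "CH4":
            continue
        a = fluid.activity(species)
        if a is None or a <= 0:
            raise ValueError(f"cannot build scenario: {species} activity unavailable")
        ln_q_rest += v * math.log(a)
    t_k = sample.temperature + 273.15
    ln_kr = log_k(reaction, sample.temperature, db)
    ln_a_ch4 = ln_kr - ln_q_rest - 1000.0 * target_affinity_kj / (db.gas_constant * t_k)
    return replace(sample, ch4=math.exp(ln_a_ch4))
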