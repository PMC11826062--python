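"""Conservative mixing, grouped affinity statistics, and ATP feasibility.

Dissolved silica behaves conservatively between the two end-member waters
of a serpentinizing aquifer (Si-rich circumneutral Type I vs Si-poor
hyperalkaline Type II), so the Si concentration of any sample yields the
percent of serpentinized (Type II) fluid it contains by linear inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .energetics import EnergyResult


@dataclass(frozen=True)
class MixingModel:
    """Two-end-member conservative Si mixing model (molalities)."""

    si_type1_endmember: float = 8.5e-4
    si_type2_endmember: float = 1.4e-6

    def __post_init__(self) -> None:
        if self.si_type1_endmember <= 0 or self.si_type2_endmember <= 0:
            raise ValueError("end-member Si values must be positive")
        if self.si_type1_endmember == self.si_type2_endmember:
            raise ValueError("end-member Si values must be distinct")


@dataclass
class SummaryRow:
    """Affinity summary statistics for one group x reaction."""

    group: str
    reaction_id: str
    n: int
    mean: float
    sd: Optional[float]  # sample (n-1) sd; None when n = 1
    min: float
    max: float


def pct_serpentinized(si: float, model: Optional[MixingModel] = None) -> float:
    """Percent serpentinized (Type II) fluid from Si, clipped to [0, 100]."""
    if si < 0:
        raise ValueError("si must be >= 0")
    model = model or MixingModel()
    frac = (model.si_type1_endmember - si) / (
        model.si_type1_endmember - model.si_type2_endmember
    )
    return float(np.clip(100.0 * frac, 0.0, 100.0))


def summarize_affinity(
    results: Sequence[EnergyResult],
    reaction_id: str,
    group: str = "all",
) -> SummaryRow:
    """Mean / sample sd / range over the non-null affinities of one reaction."""
    values = [
        r.affinity
        for r in results
        if r.reaction_id == reaction_id and r.affinity is not None
        and not math.isnan(r.affinity)
    ]
    if not values:
        raise ValueError(f"no affinities for reaction {reaction_id!r} in group {group!r}")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else None
    return SummaryRow(
        group=group,
        reaction_id=reaction_id,
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
    )


def rank_metabolisms(
    site_results: Sequence[EnergyResult],
    metric: Literal["affinity", "energy_supply"] = "affinity",
) -> Optional[list[str]]:
    """Reaction ids at one site in descending order of ``metric``.

    Null metrics are excluded; returns None when every metric is null.
    """
    scored = [
        (getattr(r, metric), r.reaction_id)
        for r in site_results
        if getattr(r, metric) is not None
    ]
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [rid for _, rid in scored]


@dataclass(frozen=True)
class AtpFeasibility:
    max_whole_atp: int
    feasible: bool


def atp_feasibility(
    affinity: float, atp_cost: float = 45.0, n_required: int = 1
) -> AtpFeasibility:
    """Whole ATP equivalents affordable from one mole of CH4's affinity.

    ``n_required`` is the number of ATP the metabolism must invest up
    front (e.g. 2 for acetate activation via acetyl-CoA synthetase);
    feasible means the affinity covers that investment.
    """
    if atp_cost <= 0:
        raise ValueError("atp_cost must be positive")
    return AtpFeasibility(
        max_whole_atp=int(math.floor(max(affinity, 0.0) / atp_cost)),
        feasible=affinity >= n_required * atp_cost,
    )
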