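"""Per-site fluid chemistry records and table I/O.

Field concentrations are molalities (mol per kg water). Cells left blank in
the source tables mean *not measured* or *below detection*; they are carried
as ``None`` through every pipeline stage and re-emitted as empty cells,
never coerced to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml


class FluidType(str, Enum):
    """End-member classification of a serpentinizing-system fluid.

    ``type1``: shallow, circumneutral Mg-HCO3 groundwater; ``type2``:
    deep, hyperalkaline (pH > 11) Ca-OH fluid representing pristine
    serpentinized water; ``mixed``: intermediate compositions.
    """

    TYPE1 = "type1"
    TYPE2 = "type2"
    MIXED = "mixed"


_FLUID_ALIASES = {
    "type1": FluidType.TYPE1,
    "typei": FluidType.TYPE1,
    "type 1": FluidType.TYPE1,
    "type i": FluidType.TYPE1,
    "type2": FluidType.TYPE2,
    "typeii": FluidType.TYPE2,
    "type 2": FluidType.TYPE2,
    "type ii": FluidType.TYPE2,
    "mix": FluidType.MIXED,
    "mixed": FluidType.MIXED,
}


class SchemaError(ValueError):
    """Input table is missing a mandatory column."""


class ValidationError(ValueError):
    """A parsed value violates a physical invariant."""


@dataclass
class FluidSample:
    """One site's measured chemistry."""

    site_id: str
    fluid_type: FluidType
    ph: float
    temperature: float  # degC
    location: Optional[str] = None
    si: Optional[float] = None
    dic: Optional[float] = None
    h2: Optional[float] = None
    ch4: Optional[float] = None
    formate_total: Optional[float] = None
    acetate_total: Optional[float] = None
    major_ions: Optional[dict[str, float]] = None

    _CONC_FIELDS = ("si", "dic", "h2", "ch4", "formate_total", "acetate_total")

    def __post_init__(self) -> None:
        if isinstance(self.fluid_type, str):
            key = self.fluid_type.strip().lower()
            if key not in _FLUID_ALIASES:
                raise ValidationError(
                    f"{self.site_id}: unknown fluid type {self.fluid_type!r}"
                )
            self.fluid_type = _FLUID_ALIASES[key]
        if not (0.0 < self.ph < 14.0):
            raise ValidationError(f"{self.site_id}: pH {self.ph} outside (0, 14)")
        if not (-5.0 <= self.temperature <= 100.0):
            raise ValidationError(
                f"{self.site_id}: temperature {self.temperature} outside [-5, 100] degC"
            )
        for name in self._CONC_FIELDS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"{self.site_id}: {name} = {v} is not a valid molality"
                )
        if self.major_ions is not None:
            for ion, m in self.major_ions.items():
                if m < 0:
                    raise ValidationError(
                        f"{self.site_id}: major ion {ion} molality {m} < 0"
                    )


@dataclass
class RunConfig:
    """Tunable run parameters.

    ``cell_radius`` is the radius of the model cell for the diffusive-flux
    bound (m). ``default_ionic_strength`` backs the Davies activity model
    when no major-ion data accompany a sample. The silica end-members
    anchor the conservative-mixing model (% serpentinized fluid), and
    ``atp_cost`` is the energetic price of one ADP -> ATP phosphorylation.
    """

    cell_radius: float = 5e-7  # m
    default_ionic_strength: float = 0.01  # mol/kg
    si_type1_endmember: float = 8.5e-4  # molal
    si_type2_endmember: float = 1.4e-6  # molal
    atp_cost: float = 45.0  # kJ/mol
    thermo_source: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius <= 0:
            raise ValidationError("cell_radius must be positive")
        if self.si_type1_endmember == self.si_type2_endmember:
            raise ValidationError("mixing end-member Si values must be distinct")


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML key-value file (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

#: canonical column order of the sample schema
SAMPLE_COLUMNS = [
    "site_id",
    "location",
    "fluid_type",
    "ph",
    "temperature_c",
    "si_molal",
    "dic_molal",
    "h2_molal",
    "ch4_molal",
    "formate_molal",
    "acetate_molal",
]

_HEADER_ALIASES = {
    "site_id": "site_id",
    "sample": "site_id",
    "site": "site_id",
    "location": "location",
    "fluid_location": "location",
    "fluid_type": "fluid_type",
    "fluid": "fluid_type",
    "ph": "ph",
    "temperature_c": "temperature_c",
    "temperature": "temperature_c",
    "temp": "temperature_c",
    "temp_c": "temperature_c",
    "si_molal": "si_molal",
    "si": "si_molal",
    "dic_molal": "dic_molal",
    "dic": "dic_molal",
    "h2_molal": "h2_molal",
    "h2": "h2_molal",
    "ch4_molal": "ch4_molal",
    "ch4": "ch4_molal",
    "formate_molal": "formate_molal",
    "formate": "formate_molal",
    "acetate_molal": "acetate_molal",
    "acetate": "acetate_molal",
}

_MANDATORY = ("site_id", "ph", "temperature_c")

_FIELD_FOR_COLUMN = {
    "location": "location",
    "si_molal": "si",
    "dic_molal": "dic",
    "h2_molal": "h2",
    "ch4_molal": "ch4",
    "formate_molal": "formate_total",
    "acetate_molal": "acetate_total",
}


def _sep_for(path, dialect: Optional[str]) -> str:
    if dialect:
        return {"tsv": "\t", "csv": ","}[dialect]
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_samples(path, dialect: Optional[str] = None) -> list[FluidSample]:
    """Parse a per-site chemistry table into FluidSample records.

    Header names are matched case-insensitively against a set of accepted
    aliases (``sample`` for ``site_id``, bare analyte names for the
    ``*_molal`` columns, ...). Blank cells become ``None``.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, skipinitialspace=True)
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _HEADER_ALIASES:
            rename[col] = _HEADER_ALIASES[key]
    df = df.rename(columns=rename)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")

    samples: list[FluidSample] = []
    for _, row in df.iterrows():
        def cell(col: str) -> Optional[str]:
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            v = str(v).strip()
            return v or None

        site = cell("site_id")
        if site is None:
            continue  # skip fully blank rows

        def num(col: str) -> Optional[float]:
            raw = cell(col)
            if raw is None:
                return None
            try:
                return float(raw)
            except ValueError:
                raise ValidationError(f"{site}: cannot parse {col}={raw!r}") from None

        kwargs = {
            "site_id": site,
            "location": cell("location"),
            "fluid_type": cell("fluid_type") or "mixed",
            "ph": num("ph"),
            "temperature": num("temperature_c"),
        }
        for col, fld in _FIELD_FOR_COLUMN.items():
            if fld == "location":
                continue
            kwargs[fld] = num(col)
        try:
            samples.append(FluidSample(**kwargs))
        except ValidationError:
            raise
    return samples


def samples_frame(samples: Sequence[FluidSample]) -> pd.DataFrame:
    """Samples as a DataFrame in canonical column order (None -> NaN)."""
    rows = []
    for s in samples:
        rows.append(
            {
                "site_id": s.site_id,
                "location": s.location,
                "fluid_type": s.fluid_type.value,
                "ph": s.ph,
                "temperature_c": s.temperature,
                "si_molal": s.si,
                "dic_molal": s.dic,
                "h2_molal": s.h2,
                "ch4_molal": s.ch4,
                "formate_molal": s.formate_total,
                "acetate_molal": s.acetate_total,
            }
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)


def write_samples(samples: Sequence[FluidSample], path, dialect: Optional[str] = None) -> None:
    """Write samples in the canonical schema; inverse of :func:`read_samples`."""
    df = samples_frame(samples)
    df.to_csv(path, sep=_sep_for(path, dialect), index=False, na_rep="")


# ---------------------------------------------------------------------------
# result formatting
# ---------------------------------------------------------------------------


def format_sig(value: Optional[float], sig: int = 2) -> str:
    """Scientific-notation cell at ``sig`` significant figures.

    Uses the banker's (round-half-even) rounding of Python's float
    formatter; ``None``/NaN render as an empty cell, matching the blanks
    in the source tables.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.{sig - 1}E}"


def write_results(results: Sequence, path, sig: int = 2, dialect: Optional[str] = None) -> None:
    """Write a homogeneous sequence of result records to a delimited file.

    Columns follow the dataclass field order; float cells are rendered in
    scientific notation at ``sig`` significant figures (default 2, the
    printed precision of the published energy and flux tables); nulls
    are emitted as empty cells.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    first_type = type(results[0])
    if any(type(r) is not first_type for r in results):
        raise TypeError("mixed result types in write_results")
    cols = [f.name for f in fields(first_type)]
    rows = []
    for r in results:
        d = asdict(r)
        rows.append(
            {
                c: (format_sig(d[c], sig) if isinstance(d[c], float) else
                    ("" if d[c] is None else d[c]))
                for c in cols
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep=_sep_for(path, dialect), index=False
    )
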