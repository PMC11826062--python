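"""Bundled field datasets from the Samail Ophiolite (Oman).

Two small plain-text tables ship with the package:

* ``samail_fluid_chemistry.tsv`` — per-site measured fluid chemistry
  (pH, temperature, and molalities of Si, DIC, H2, formate, acetate) for
  surface-expressed serpentinized fluids and subsurface wells. Blank cells
  are unmeasured values and parse to nulls.
* ``samail_site_energetics.tsv`` — the published per-site chemical
  affinities (kJ/mol CH4) and energy supplies (J/kg) for the three
  methanogenic catabolisms at the same sites. The affinities rest on a
  full EQ3/6-grade speciation (including CH4 activities from companion
  datasets) and therefore serve as *inputs* to the supply arithmetic and
  summary statistics, and as an external check on this package's own
  affinity calculations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .samples import FluidSample, read_samples


def _data_path(name: str):
    return resources.files("serpenergy.data").joinpath(name)


def load_fluid_chemistry() -> list[FluidSample]:
    """The per-site measured chemistry table as FluidSample records."""
    with resources.as_file(_data_path("samail_fluid_chemistry.tsv")) as p:
        return read_samples(p, dialect="tsv")


def load_site_energetics() -> pd.DataFrame:
    """Published per-site affinities and energy supplies (wide format).

    Columns: site_id, fluid_type, subsurface (0/1), ph, si_molal, then
    ``affinity_<reaction>`` (kJ/mol CH4) and ``supply_<reaction>`` (J/kg)
    for the hydrogenotrophic, formatotrophic and acetoclastic routes.
    """
    with resources.as_file(_data_path("samail_site_energetics.tsv")) as p:
        return pd.read_csv(p, sep="\t")
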