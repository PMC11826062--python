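# serpenergy

Bioenergetics of methanogenesis in serpentinized fluids.

Water-ultramafic-rock reaction (serpentinization) produces hyperalkaline
(pH > 11), H₂-rich fluids that are nearly devoid of dissolved inorganic
carbon — a paradoxical habitat where the electron donor for methanogenesis
is abundant but the carbon substrate is scarce. `serpenergy` quantifies
what that means for hydrogenotrophic (4H₂ + HCO₃⁻ + H⁺ → CH₄ + 3H₂O),
formatotrophic (4CHO₂⁻ + H⁺ + H₂O → CH₄ + 3HCO₃⁻) and acetoclastic
(C₂H₃O₂⁻ + H₂O → CH₄ + HCO₃⁻) methanogens, for geomicrobiologists and
astrobiologists assessing the habitability of such systems. It is built
around the per-site chemistry of surface-expressed and well fluids of the
Samail Ophiolite (Oman), shipped with the package as plain-text tables.

## What it computes

For each fluid sample and reaction *r*:

* **Speciation** — measured totals (DIC, Σformate, Σacetate) distributed
  over acid/base partners by mass action at in-situ pH, with
  Davies-equation activity coefficients, yielding activities *aᵢ*.
* **Chemical affinity** — *A_r* = *RT* ln(*K_r*/*Q_r*) with
  *Q_r* = Π *aᵢ^{ν_{i,r}}*, reported in kJ per mole CH₄; *K_r* assembled
  from standard formation properties by Hess's law with van't Hoff
  temperature adjustment.
* **Energy supply** — *E_r* = *A_r* · *m*_lim/*ν*_lim in J per kg fluid:
  the energy density if the reaction runs until its limiting substrate
  pool (min of *m*/|ν| over candidate pools) is exhausted. Unfavorable
  reactions (*A* ≤ 0) supply 0.
* **Potential flux** — *J* = 4π*DR*(*C*∞ − *C_R*) in attomoles/day: the
  diffusive upper limit on delivery of each substrate species to a
  0.5 µm cell, with *C_R* bounded below by the substrate concentration in
  equilibrium with the metabolism.
* **Mixing & summaries** — percent serpentinized fluid from conservative
  two-end-member Si mixing, grouped affinity statistics, per-site
  metabolism rankings, and whether the affinity covers the ~45 kJ/mol
  cost of ATP synthesis.

A seeded generator (`serpenergy.synthetic`) emulates the field dataset's
per-fluid-type chemistry so every stage is testable without field data.

## Worked example

```python
>>> import serpenergy as sp
>>> samples = sp.datasets.load_fluid_chemistry()
>>> z = next(s for s in samples if s.site_id == "140115Z")   # Type II, pH 11.3
>>> sp.limiting_reactant(sp.HYDROGENOTROPHIC, z)
('HCO3-', 3.4e-05, 1)
>>> sp.energy_supply(65.2, 3.4e-05, 1)   # published affinity x m_lim/v_lim
2.2168
```

At this site DIC (3.4×10⁻⁵ molal) limits hydrogenotrophic methanogenesis
— not H₂ (2.3×10⁻⁴/4 = 5.75×10⁻⁵) — and the fluid holds 2.2 J of
hydrogenotrophic energy per kg. Speciation shows why carbon is so scarce:

```python
>>> fl = sp.speciate(z)
>>> f"{fl.molality('CO2'):.1e}", f"{fl.molality('CO3-2'):.1e}"
('2.0e-11', '3.2e-05')
```

at pH 11.3 essentially all DIC sits as carbonate ion; free CO₂(aq) is six
orders of magnitude below the pool. The analysis drivers under `analysis/`
(`01_simulate_fluids.py` … `05_summary.py`) run the full pipeline and
write their tables to `results/`; the summary stage prints, for the 22
sites with an acetoclastic affinity,

```
acetoclastic affinity: 38 +/- 9 kJ/mol CH4 (n=22)
ATP check at 45 kJ/mol: max whole ATP = 0, acetate activation (2 ATP) feasible = False
```

— on average acetoclastic methanogenesis yields 38 ± 9 kJ/mol CH₄,
below even one 45 kJ ATP equivalent and far below the two ATP needed to
activate acetate via acetyl-CoA synthetase.

There is also a CLI (`serpenergy speciate|energetics|flux|mix|summarize|simulate`)
over the same library.

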