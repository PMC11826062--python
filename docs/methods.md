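# Methods

## Model

The package treats each fluid sample as a well-mixed aqueous phase at its
measured pH and temperature and asks three questions about the three
methanogenic catabolisms (hydrogenotrophic, formatotrophic, acetoclastic):
how much energy each releases per mole of CH₄ (*affinity*), how much
energy a kilogram of fluid holds if the reaction runs to substrate
exhaustion (*energy supply*), and how fast diffusion could physically
deliver each substrate to a cell (*potential flux*).

**Affinity.** For reaction *r*, *A_r* = *RT* ln(*K_r*/*Q_r*), with
*Q_r* = Π *aᵢ^{ν_{i,r}}* (products positive, reactants negative) and
*R* = 8.314 J/(mol·K). *A_r* is positive when the forward reaction
releases energy and is normalized per mole of CH₄ produced (a division by
the CH₄ stoichiometric count, 1 for all three reactions as written, kept
explicit so that rescaling a reaction is a tested no-op). ln *K_r* is
assembled from species standard formation properties (ΔG°f, ΔH°f at
25 °C; CODATA/SUPCRT-lineage compilation values of Shock & Helgeson and
Amend & Shock, with each entry carrying its source string) and shifted to
in-situ temperature with the van't Hoff relation. Because every constant
descends from one formation-property table, Hess's law holds by
construction: the identity
*A*(formatotrophic) = *A*(hydrogenotrophic) + 4·*A*(formate hydrolysis)
is asserted to 10⁻⁶ kJ in the tests. Over the 19–36 °C span of these
fluids the neglected heat-capacity terms are below the 2-significant-
figure display precision.

**Speciation.** Measured totals are pools: DIC over
{CO₂(aq), HCO₃⁻, CO₃²⁻}, Σformate over {HCOOH, HCOO⁻}, Σacetate over
{CH₃COOH, CH₃COO⁻}, distributed by closed-form ionization fractions at
the sample pH with mass action honored on activities. The pools are
redox-decoupled: speciation never converts DIC into formate, CH₄ into
CO₂, etc., mirroring the standard practice of suppressing redox couples
when speciating a disequilibrium fluid. H₂(aq) and CH₄(aq) are neutral
species carried at their measured molalities; a(H⁺) = 10^(−pH);
a(H₂O) = 1; γ = 1 for all neutral solutes (dilute fluids). Ion activity
coefficients come from the Davies equation,
log₁₀γ = −A·z²(√I/(1+√I) − 0.3 I), with A(T) from a quadratic fit
(A(25 °C) = 0.509) and validity capped at I = 0.5 mol/kg. Where samples
carry no major-ion data the ionic strength defaults to 0.01 mol/kg, a
representative value for these fluids; when major ions are given, I is a
single-pass sum that counts each carbon pool once at charge 1. Carbonate
complexes of Ca and Mg (CaHCO₃⁺ etc.) are not speciated — their role in
pool accounting is honored instead by using the measured total as the
limiting pool (below).

**Energy supply.** *E_r* = *A_r*·*m*_lim/*ν*_lim (J per kg fluid). The
limiting candidate minimizes *m*_pool/|ν| over the reaction's substrate
pools (H₂ and DIC for hydrogenotrophic; Σformate, Σacetate for the
others); H⁺ and H₂O are never candidates, since solvent and pH are
buffered at the kg scale. *m*_lim is the *measured total* pool molality,
not an activity sum: as the named reactant is consumed the pool
re-equilibrates to resupply it until the whole pool is spent, and the
measured total is the faithful desk-scale expression of that pool.
Ties in *m*/|ν| break to the carbon substrate. A reaction with *A* ≤ 0
supplies exactly 0 J/kg while its affinity stays signed. Unmeasured pools
propagate as nulls and blank the affected cells — nothing is imputed.

**Potential flux.** *J* = 4π*DR*(*C*∞ − *C_R*), converted to
attomol/day, for six species: the neutral acids CO₂(aq), HCOOH, CH₃COOH
(membrane-permeant) and the anions HCO₃⁻, HCOO⁻, CH₃COO⁻ (transporter-
dependent). *D* values are the tabulated 25 °C, 1 bar coefficients with
no temperature correction; *R* defaults to 0.5 µm; activities are taken
as numerically equal to molarity in both *C*∞ and *C_R* (dilute fluids,
no density correction). *C_R* for each anion solves the one-variable
equilibrium condition a_eq = (K/Q_rest)^(1/ν_s) of its metabolism in
closed form (cross-checked against a bracketing root-finder in log-
activity space); the paired acid is then placed at acid/base equilibrium
with that anion at the sample pH. Negative gradients (C∞ < C_R) clamp to
J = 0 with a flag, since the construct is an upper bound on uptake and
efflux is out of scope. Each species diffuses independently; resupply of
the acids by near-cell protonation of their anions is not modeled, so
acid-form fluxes may be underestimates.

**Mixing and summaries.** Percent serpentinized fluid inverts linear Si
mixing between end-members (defaults: Type I 8.5×10⁻⁴ molal — the
highest measured Type I value, which the published table assigns 0.0% —
and Type II 1.4×10⁻⁶ molal, the 100.0% site), clipped to [0, 100].
Published percent values deviate from any single end-member pair by up to
~0.5%, so the end-members are configurable. Affinity summaries use the
arithmetic mean and sample (n−1) standard deviation over non-null values.
ATP feasibility reports floor(max(A,0)/45 kJ) whole ATP equivalents and
whether A covers an explicit n_required×45 kJ investment (n_required = 2
for acetate activation by acetyl-CoA synthetase); the interpretive
rounding of "38 ± 9 ≈ one ATP" is left to the caller.

## Bundled data and what the pipeline does with it

Two plain-text tables under `src/serpenergy/data/` hold the per-site
measured chemistry and the published per-site affinities/supplies for the
Samail Ophiolite sites. The measured table carries no CH₄ column, and an
affinity requires a CH₄ activity, so on the field data the package's own
affinity cells are blank and the published affinities (which rest on a
database-grade speciation with CH₄ from companion datasets) serve as
inputs to the supply arithmetic. Recomputing every printed supply cell
from the printed affinity and the measured pools reproduces 58 of 77
cells exactly at 2 significant figures, including all six benchmark
cells; the remainder differ by one unit in the last printed digit, the
expected residual when both inputs are themselves rounded to 2–3
significant figures and the published pools were activity sums rather
than measured totals. The published *affinity* and *flux* columns
themselves are approximation targets only: they depend on the EQ3/6/WORM
thermodynamic database and supplementary activity sets that are not
printed, so the package asserts thermodynamic identities (equilibrium
zero, reversal antisymmetry, Hess closure, round trips) and qualitative
orderings against them rather than cell-exact equality.

## Synthetic-fluid generator

`serpenergy.synthetic` emulates the field dataset's structure: pH
truncated-normal per type (Type II mean 11.4, sd 0.12, bounds
[11.2, 11.65]; Type I mean 7.9, sd 0.3, bounds [7.0, 8.7]), temperature
uniform on [19, 36] °C, and lognormal analytes by (median, geometric sd):
Type II Si 3×10⁻⁶ (gsd 1.8), DIC 4×10⁻⁵ (2), H₂ 5×10⁻⁵ (10), formate
1.5×10⁻⁶ (2), acetate 2×10⁻⁶ (1.6); Type I Si 5×10⁻⁴ (1.3), DIC 3×10⁻³
(1.5), H₂ 3×10⁻⁸ (3), with loosely constrained formate/acetate medians
(10⁻⁶/5×10⁻⁷) since the field data hold a single Type I representative.
CH₄ is drawn too (Type II median 3×10⁻⁴ molal, gsd 3, reflecting the
mM-level CH₄ reported for hyperalkaline Samail fluids; Type I 10⁻⁸) so
that affinity and flux stages are exercisable on synthetic data even
though the measured table lacks CH₄. Mixed fluids blend end-member
vectors conservatively with f ~ U(0,1) and multiplicative lognormal noise
(gsd 1.2); their pH is linearly interpolated between end-member pH values
rather than recomputed from mixed alkalinity — a declared approximation
(true mixing pH is a titration problem, out of scope) that nevertheless
spans the observed pH 7.4–11.3 range smoothly. Scenario builders
(`make_limiting_scenario`, `make_affinity_scenario`) construct samples
with a guaranteed limiting reactant (≥2× margin) or an exactly prescribed
affinity (closed-form inversion through the CH₄ activity) for
parameter-recovery tests.

What passing tests on synthetic data do **not** show: real fluids have
correlated pH–DIC–H₂ structure set by water–rock reaction paths, major-ion
matrices that shift activity coefficients, and detection-limit censoring,
none of which the generator reproduces.

## Numerical choices

* Closed-form ionization fractions make pool mass balance exact to
  machine precision (asserted at 10⁻¹⁰ relative).
* Equilibrium boundary activities are solved in log space; the test
  oracle root-finds in log-activity coordinates so brackets stay well
  scaled for activities down to ~10⁻¹⁴.
* Display rounding is round-half-even at 2 significant figures (the
  printed precision of the source tables); full precision is retained
  internally and in the long-format results.
* Zero or null required activities make a reaction quotient unevaluable
  (null), never ±∞.
* Temperature guard: reaction log K evaluation refuses T outside
  [0, 100] °C; the Davies model refuses I > 0.5 mol/kg.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| cell radius R | 5×10⁻⁷ | m | cell-like length scale for the flux bound |
| default ionic strength | 0.01 | mol/kg | representative of these dilute fluids when major ions are unreported |
| Si end-members (Type I / II) | 8.5×10⁻⁴ / 1.4×10⁻⁶ | molal | the 0.0% and 100.0% sites of the published table |
| ATP cost | 45 | kJ/mol | canonical ADP→ATP phosphorylation cost |
| gas constant | 8.314 | J/(mol·K) | — |
| diffusion coefficients | per species | m²/s | 25 °C, 1 bar literature values, no T correction |

## Limitations

* No Pitzer or B-dot activity model, no mineral saturation, no gas–
  solution equilibria, no Ca/Mg carbonate complexes: the speciation is a
  dilute-solution approximation adequate for pool partitioning, not a
  database-fidelity replacement.
* No kinetics: affinities and supplies are thermodynamic ceilings, and
  potential fluxes are physical upper limits (equilibrium boundary
  concentration, perfectly absorbing sphere), not rates.
* Charge balance is not re-imposed per sample; the measured pH is taken
  as-is. The per-sample charge-balance choice used in the original
  speciation of these fluids is recorded in data provenance, not
  resolved here.
* The problem sizes used by the test suite and drivers (≤1000 synthetic
  samples, 30–50 random fluids per property) were chosen as comfortable
  Monte-Carlo sizes for the stated tolerances.
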