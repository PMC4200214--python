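# Methods

`particledose` implements a comparative dosimetry chain for low-solubility
metal-oxide nanoparticles — here parameterized for carboxylated
superparamagnetic iron oxide (SPIO, magnetite) — that places in vitro and in
vivo exposure data on a common *target-cell dose* scale (μg per cm² of cells,
or pg per macrophage). This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## Particle and agglomerate physics

Suspended nanoparticles travel as fractal agglomerates. Given the primary
diameter d_p, the hydrodynamic (DLS) diameter d_agg, fractal dimension DF and
packing factor PF, the Sterling relation gives the particle count per
agglomerate, N = PF·(d_agg/d_p)^DF, and the solid volume fraction
φ = N·(d_p/d_agg)³ yields the effective density
ρ_eff = ρ_f + (ρ_p − ρ_f)·φ, bounded between the medium and bulk densities.
Transport coefficients are classical: Stokes–Einstein diffusivity
D = k_B T / (3πμd) and Stokes settling velocity V = g d² (ρ_eff − ρ_f)/(18μ),
both evaluated at the *agglomerate* size. With the default parameters
(d_p = 13 nm, ρ_p = 5.2 g/cm³, d_agg = 276 nm, DF = 2.1, PF = 0.637, μ =
7.4·10⁻⁴ Pa·s, T = 310 K) this gives N ≈ 390, ρ_eff ≈ 1.17 g/cm³,
D ≈ 2.2·10⁻¹² m²/s and V ≈ 9.6·10⁻⁹ m/s.

Mass/number/surface conversions treat the material as monodisperse primary
spheres (per-sphere mass ρπd³/6, surface-to-mass 6/(ρd)); at 13 nm and
5.2 g/cm³ one picogram is ≈1.67·10⁵ particles with ≈8.88·10⁻⁷ cm² of
surface. Aerosol count↔mass median conversion uses the single-mode
Hatch–Choate relation MMD = CMD·exp(3 ln²GSD); multimodal spectra are out of
scope. Physical constants are fixed at their exact SI values
(k_B = 1.380649·10⁻²³ J/K, g = 9.80665 m/s²).

Units follow bench convention on input (nm, g/cm³, Pa·s, K, mg/m³, ml, mm,
h) and are converted to SI internally; every field, argument and returned
key carries its unit in its name (`surface_area_cm2`, `rate_ug_per_h`)
rather than in a wrapper object — the same protection against silent 10³
errors with a lighter API.

## In vitro delivery (sedimentation–diffusion transport)

Delivery to cells at the bottom of a culture well is modeled as 1-D
advection–diffusion of the suspended concentration over the media column
height h (default 2.6 mm, 2.5 ml), with a uniform initial condition, a
perfectly absorbing cell plane (delivery = irreversible arrival; association
is a separate multiplicative step) and zero total flux at the free surface.
Agglomerates are monodisperse (one DLS size class); polydispersity is a
documented extension point.

Numerics: cell-centred finite volumes, first-order upwinded advection,
backward-Euler time stepping (unconditionally stable; no user input can
destabilize it). Defaults are 400 uniform cells and a 5 s maximum step,
at which halving both Δx and Δt changes the 24-h delivered fraction by
≈0.1% under the default parameters. The delivered fraction is computed from
the mass balance (initial − suspended), so conservation holds by
construction; the integrated bottom-boundary flux is tracked independently
and the solver raises if the two accounts disagree beyond 10⁻⁶, or if the
state becomes non-finite or negative. Correctness is anchored by two closed
forms: the plug-flow limit (D→0, fraction = min(1, Vt/h)) and the
pure-diffusion eigen-series for an absorbing/reflecting slab (truncated at
10⁻¹⁰), plus self-convergence against a 4× finer grid. Buoyant particles
(ρ_eff < ρ_f) are legal; delivery is then diffusion-limited.

## Cell association

The association fraction f(t) = measured cell-associated mass / modeled
delivered mass is reported per timepoint (raw, and clipped to [0, 1] for
prediction; values above 1 + 0.05 raise a recorded warning). A smooth
saturable model — a four-parameter decreasing logistic
f(u) = f_min + (f_max − f_min)/(1 + (u/K)^n) — can be fitted by ordinary
(unweighted) least squares, with the covariate u selectable between
cumulative delivered mass and time: the data pattern (decline at later,
higher-dose timepoints) does not distinguish the two, so the choice is a
config flag, not a hard-coded assumption. The logistic was chosen as the
minimal smooth saturable family; the empirical fractions are always
reported alongside so it stays falsifiable. The curve fit needs at least
four timepoints (the parameter count); with a five-point course K and n are
only weakly identified, which is why the parameter-recovery guarantee is
stated for adequately dense designs while per-timepoint fractions are
reliable at any design.

## In vivo dose chain

Total inhaled mass = measured minute volume × duration × aerosol mass
concentration. The measured total deposited lung burden and the
per-generation fractional-deposition table are *inputs* (the deposition
table is the output of a multiple-path lung deposition model, which this
package deliberately does not re-implement). Allocation renormalizes the
fractions to sum to 1 (logged) so per-generation masses conserve the
measured total exactly; note the conventionally quoted regional split
(2.8/34/62%) sums to 0.988, so renormalization shifts desk arithmetic by
~1.2%. Surface dose divides each generation's mass by its epithelial area.
Macrophage dose distributes a fixed alveolar macrophage pool (default
1.25·10⁶ for the mouse) across alveolar generations in proportion to
alveolus count, then divides the scavenged share of each generation's mass
by its macrophage count. The scavenging fraction defaults to 1.0 (complete
scavenging of alveolar-deposited particles), with 0.2–0.8 sweeps supported;
published size-dependent scavenging near ~50% halves the per-macrophage
band. Bifurcation hot spots are handled as a scalar enhancement factor on
the regional average surface dose (the published CFD-derived value of 65
for a 100 μm patch is the packaged default), not by flow modeling.

## Clearance

Retained lung burden is fitted with a zero-order line m(t) = m₀ − k·t by
ordinary least squares (optionally 1/SD²-weighted), reporting the absolute
rate (μg/h) and the rate normalized to the intercept (%/day = k·24/m₀·100).
A first-order exponential alternative is fitted alongside and compared by
AIC (Gaussian residuals) so the "linear, single phase" description is a
checkable model-selection outcome, not an assumption; the linear model is
always the reported one. The intercept is free (not pinned to the measured
burden); a negative fitted rate is flagged, never clamped, and predicted
retention is clamped at zero with a logged warning.

## Occupational-limit extrapolation and band comparison

An exposure limit stated "as Fe" is converted to the particle-mass scale by
dividing by the iron mass fraction computed from IUPAC atomic weights
(Fe₃O₄ → 0.7236, Fe₂O₃ → 0.699, FeO → 0.777); 10 mg/m³ as Fe is then
≈13.8 mg/m³ as magnetite (commonly quoted as 14, the rounding of 10/0.72).
The human scenario pushes an 8-h exposure at the adjusted limit through the
same regional chain, with deposited mass = inhaled mass × per-generation
deposition fractions and clearance deliberately excluded. Cross-system
comparison treats dose intervals as closed bands sharing a metric and
reports interval intersection and midpoint ratios; effect thresholds follow
the lowest-observed-effect-level convention (the lowest tested dose with a
significant effect) since no dose–response fitting procedure is defined for
the band endpoints.

## Synthetic data

Generators provide every pipeline input with the statistical structure the
fitting stages assume:

* **Deposition tables** — smooth within-region per-generation profiles with
  seeded jitter, renormalized so the regional rollup matches the requested
  split exactly; surface areas increase distally within each region
  (geometric profiles scaled to literature-order regional totals: mouse
  1.5 / 5 / 500 cm², human 250 / 2000 / 7·10⁵ cm²); alveoli only in alveolar
  rows, in proportion to area. The human-like table additionally folds in a
  total deposition efficiency (default 0.30 of inhaled) and a macrophage
  pool of 2·10⁹, values chosen once within literature ranges such that the
  packaged human-at-limit scenario reproduces the qualitative ordering
  (human regional doses ≥ mouse). Both tables are synthetic stand-ins for
  deposition-model output and are labeled as such — they are not real
  airway morphometry.
* **Retention series** — linear decay with mean-preserving multiplicative
  lognormal noise (default 5% relative SD, of the order of gravimetric
  repeatability), which cannot produce negative masses.
* **In vitro time courses** — transport-solver delivered dose × a known
  association fraction × lognormal noise (default 2%, calibration-level),
  exactly linear in nominal concentration.
* **Standard curves** — signal = gain × mass × noise, with matrix-specific
  gains (cells vs tissue); quantification inverts a least-squares line.

All generators are bit-reproducible for a fixed seed, and every noiseless
mode is an exact inverse-crime fixture for its downstream fit. What passing
tests show is therefore internal consistency — that each estimator recovers
the truth its generator encodes under realistic noise — not agreement with
any real instrument; real aerosol spectra, animal-to-animal variability,
dissolution, convection from plate handling and multi-compartment clearance
are all outside the generators' scope.

## Problem sizes and determinism

The packaged analyses use the study-scale problems throughout: 5 in vitro
timepoints over 24 h, 6 retention timepoints over 168 h, 22 (mouse) or 23
(human) airway generations, 100-replicate seeded recovery studies, 400-cell
PDE grids with 4× refinement checks. Every stochastic step takes an
explicit seed; reruns of the pipeline driver with the same config and seed
are byte-identical, and a provenance record (config SHA-256, seed, package
versions) is written with every run.

## Known limitations

* Monodisperse transport; no dissolution, convection or particle–particle
  interaction in the well.
* The deposition table is trusted input; errors in it propagate linearly.
* The saturable association form is one convenient family among several
  the five-point study design cannot distinguish.
* Human extrapolation ignores interspecies clearance differences by design
  (deposited dose only).
* Aerodynamic-diameter conversions, slip correction and charge effects are
  not implemented.
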