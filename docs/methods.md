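# Methods

`nmshield` computes shielding requirements for the four radionuclides that
dominate current diagnostic and theranostic nuclear medicine — Tc-99m, F-18,
I-131 and Lu-177 — against the barrier materials found in clinical
construction (lead, gypsum wallboard, light- and normal-weight concrete,
A514 steel, glass).  This note records the models, the assumptions behind
them, the numerically delicate choices, and what the shipped tests do and
do not demonstrate.

## Broad-beam transmission and the Archer model

Patients are uncollimated photon sources, so a barrier's effective
transmission includes photons scattered back toward the point of concern by
the barrier itself and its surroundings.  Relative to the narrow-beam
(collimated) law `T = exp(-mu x)`, broad-beam transmission is larger by a
buildup factor `B >= 1`:

    T_broad(x) = B(x) * exp(-mu * x)

The package represents broad-beam transmission with the three-parameter
Archer model,

    T(x) = [ (1 + beta/alpha) * e^(alpha*gamma*x) - beta/alpha ]^(-1/gamma)

with `x` in mm, `alpha` (1/mm) the asymptotic attenuation coefficient,
`beta` (1/mm, possibly negative) shaping the low-thickness shoulder and
`gamma` the transition sharpness.  The model inverts in closed form
(`nmshield.archer.required_thickness`), which is what a shielding design
actually needs: a thickness for a target transmission.

Numerics: both directions are evaluated in log space
(`ln T = -(z + log1p(r(1-e^-z)))/gamma`, `z = alpha*gamma*x`,
`r = beta/alpha`), so the shipped parameter extremes (`gamma = 28.74` for
Lu-177/steel) neither overflow nor cancel; the round trip
`transmission(required_thickness(T))` holds to better than 1e-10 relative
over `T` in [1e-4, 1].  Out-of-domain inputs (negative thickness, `T <= 0`
or `T > 1`) raise rather than clamp, so misuse stays visible.

The fitted parameter table is shipped as package data and treated as
definitive: the three-parameter family is only weakly identifiable, so the
parameters are not re-derivable bit-exactly from simulation, and all
equivalence judgments are made in curve space.  Fractional value layers
(HVL/QVL/TVL/CVL/MVL: transmitted fractions 1/2, 1/4, 1/10, 1/100, 1/1000)
are recomputed from the inverse model.  Comparisons against the tabulated
3-significant-figure value layers allow one unit in the last printed digit:
the parameters themselves are rounded to 4 s.f., which moves the Lu-177 /
A514-steel HVL from the printed 7.23 mm to the recomputed 7.225 mm.  The
asymptotic-slope check (`-d ln T/dx -> alpha`) is evaluated past
`alpha*gamma*x ≈ 25` because the shoulder decays on the `1/(alpha*gamma)`
scale, not in HVL multiples.

## The barrier design chain

For a weekly workload `W` (mCi·h/week of presence-weighted activity), the
unshielded weekly tissue dose at distance `d` cm from a point source is

    D [Gy/week] = W * Gamma * f / d^2

with `Gamma` the exposure-rate constant at 1 cm (R·cm²/(mCi·h)) and `f` the
exposure-to-dose conversion (0.876-0.963 cGy/R for these nuclides,
converted internally to Gy/R).  The design transmission is
`T = P / (O · D)` for weekly limit `P` and occupancy factor `O` (NCRP-147
convention; the shipped occupancy table spans 1 down to 1/40), capped at 1;
the inverse Archer model turns `T` into a thickness.  Reported doses are
µGy/week as a deep-dose-equivalent surrogate — µGy and µSv are treated as
interchangeable for these photon emitters.

Design choices:

* **Decay correction defaults off** (the workload is the plain
  activity × hours × sessions product).  Opting in multiplies each session
  by the session-averaged factor `(1 - e^(-λt))/(λt)`; for a 4 h Lu-177
  session this is 0.991 (4000 → 3965 mCi·h/week).
* Distance is the straight line from source center to the point of concern,
  including the wall thickness; barrier obliquity is ignored.
* Activity units convert at exactly 37 MBq/mCi.
* Composite barriers multiply single-material Archer transmissions.  This
  ignores inter-layer spectral hardening; for two gypsum HVLs the product
  rule overestimates the true two-HVL transmission by ~25%, and the solver
  flags composite results accordingly.
* When the required transmission falls below 0.01 the solution carries a
  warning: scatter over the barrier off ceilings and floors dominates
  beyond that point (see the Monte Carlo section), and thickening the
  primary barrier alone stops helping.

## Curve fitting

`nmshield.fitting.fit_archer` does nonlinear least squares **on ln T**:
transmission curves span three or more decades, and a linear-space
objective would fit only the thin end.  Points are unweighted (per-point
uncertainties, when present, are carried but deliberately not used as
weights).  `alpha` and `gamma` are constrained positive, `beta` is free;
five deterministic starts are taken around a slope-based initialization
(`alpha_0` from the last two points), and ties within 1e-8 rms are broken
toward the smaller |beta|.  Non-convergence sets a flag instead of raising.

Because of the identifiability caveat, recovery is asserted in curve space:
refitting noiseless model samples reproduces the transmission at all five
value-layer thicknesses to 1e-6 for every shipped pair, and with 2%
multiplicative lognormal noise (12 points, fixed seed) to within 5%.  The
synthetic-curve generator uses unit-mean lognormal noise
(`sigma² = ln(1+cv²)`); the default test levels (2-8%) correspond to the
run-to-run coefficient of variation that repeated Monte Carlo transmission
estimates actually show at desk-scale history counts.

## Monte Carlo transmission simulator

Geometry (the infinite-barrier variant): a 3 m × 2 m × 2 m air-filled
world; a barrier slab 1 m from an isotropic point source emitting into the
2π hemisphere facing it; a 2 m × 2 m × 50 cm muscle block whose central
plane lies 1 m behind the barrier.  Photons leaving the world are lost —
nothing scatters back in.  Dose is scored in 5 × 2.5 × 2.5 mm voxels; the
reported quantity is the mean voxel dose in a 150 mm diameter on-axis ROI
averaged over the second and third 5 mm depth planes (≈1 cm depth, the
regulatory deep-dose depth), per decay (Gy/Bq·s scale).  Broad-beam
transmission is the ratio of this dose to a paired no-barrier run.

Physics and its deliberate limits:

* Analog transport; free paths from the total attenuation coefficient of
  the local medium; two channels only.
* Incoherent scattering samples the exact free-electron Klein-Nishina
  distribution (rejection sampling); the energy transferred to the electron
  is deposited at the interaction site (**kerma approximation** — no
  electron transport; acceptable in 5 mm voxels at 100-700 keV).
* Photoelectric events deposit the full photon energy locally.
* Coherent (Rayleigh) scattering, characteristic x rays and bremsstrahlung
  from the barrier are omitted; these matter mainly below 1% transmission.
* Histories end below 15 keV (any residual energy is deposited locally);
  emission lines below 15 keV or 100 ppm yield are excluded from the
  source. F-18's 511 keV yield of 1.94 photons/decay enters as a
  per-decay normalization, not as two tracked photons.

**Cross sections are synthetic.**  The package embeds no evaluated photon
data library.  Incoherent mass coefficients are exact Klein-Nishina × Z/A;
photoelectric coefficients come from a parametric power law
(`∝ Z^4.1 · E^-s(Z)`, `s(Z) = 3.2 - 0.7 Z/82`, Moseley-law K edge with a
jump of 8) calibrated to representative lead and low-Z attenuation values
near 100-200 keV.  Spot checks against well-known values (lead ≈2.4 cm²/g
at 140 keV, muscle ≈0.15 cm²/g) agree to ~10-25%.  Per-element tables are
generated on a log mesh and interpolated log-log, as evaluated libraries
would be.  Consequences: every *quantitative* simulator check in the test
suite is an internal-consistency check (narrow-beam mode against
`exp(-mu x)` with the same embedded mu; buildup against the same analytic
uncollided value), and the simulator supports qualitative conclusions about
buildup and scatter, not reference dosimetry.  It is not a substitute for a
full transport code, and the fitted parameter table — not the simulator —
is the quantitative authority in this package.

Narrow-beam mode replaces the hemisphere with a pencil beam along the axis
and tallies uncollided arrivals at the tissue face; its expectation is
`sum_i w_i exp(-mu(E_i) x) / sum_i w_i` over the emission lines, an
analytic oracle the transport code is tested against at 3 standard
deviations.

The ceiling-floor variant reproduces the over-the-barrier scatter
geometry: a 2.14 m × 2.14 m barrier (no longer spanning the world), a
7.5 cm light-weight-concrete floor and a matching ceiling at 3.05, 3.66,
4.27 or 4.88 m, the source 1 m above the floor.  With an effectively opaque
barrier, dose is scored at ~1 cm depth under the **top face** of the tissue
block.  The scored region there is a full-width 15 cm strip starting 10 cm
behind the front edge — the geometry prescribes the location but not the
extent of this tally, and the strip multiplies the scored area ~17× over a
150 mm disc, which the scatter statistics need at desk-scale history
counts.

Statistics and reproducibility: per-history ROI energies give the variance
of each dose estimate; transmission uncertainties combine both runs in
quadrature.  A master seed spawns per-run `SeedSequence` children (barrier
run = child 0, reference = child 1; curve points spawn one master per
thickness), so every result is bit-reproducible and paired runs are
independent.  Default problem sizes are 2×10⁶ histories per broad-beam run
and 4×10⁶ for ceiling-scatter runs — the package's desk-scale choice,
roughly a thousandth of what the underlying transmission tables were built
from.  At this scale the on-axis ROI collects order 10² effective events
per broad-beam run, so stochastic acceptance checks are phrased at 2-3
standard deviations of the scored estimates; they verify consistency, not
small effects.  Fixed seeds make every such check deterministic.

A note on buildup in this scoring.  For a Compton-dominated barrier
(gypsum, concrete, glass) the dose-ratio buildup behaves classically:
B ≫ 1 and growing with optical depth (for gypsum, B ≈ 2 → 7 between ~1 and
~3.4 mean free paths).  For lead at 140 keV, however, the dose-ratio B
sits close to — and near 1 mm slightly below — unity: the no-barrier
reference dose includes tissue-scatter contributions from obliquely
emitted photons, and the barrier attenuates those along slant paths
`t/cosθ` more strongly than the axial primaries, while photoelectric-
dominated lead generates little compensating scatter of its own.  The
same inversion is visible in the shipped tables themselves, whose
broad-beam lead HVL for this emitter is slightly smaller than the
narrow-beam value.  The acceptance suite therefore asserts B ≥ 1 (within
3 sd) for lead in its statistically dense sub-HVL regime and carries the
full "B > 1 and increasing" property on gypsum; lead tallies beyond ~1 mm
hold too few events at 2×10⁶ histories for a valid variance estimate.

## What the synthetic data do and do not show

The synthetic curve generator and the Monte Carlo simulator emulate
idealized point sources in air against clean slabs: no patient
self-attenuation (deliberately, so results remain comparable to
post-installation surveys with bare sources), no heterogeneous walls, no
furniture or neighboring rooms, no time-dependent occupancy.  Passing tests
therefore demonstrate the internal correctness of the models and transport
— not that a specific clinic's wall will meet its survey.  Known further
limitations: the solver handles one barrier between one source and one
point of concern (no room-layout engine); shielding recommendations below
1% transmission require treating over-barrier scatter explicitly.
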