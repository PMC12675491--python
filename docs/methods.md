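# Methods

## Model chain

A negatively buoyant particle released in still water accelerates
until drag balances its effective weight; the package predicts that
terminal (settling) velocity

    ω = sqrt( (4/3) · (ρ/ρ_sw − 1) · g · d_n · S_f^(2/3) / C_D )

from three traits: volume V (→ nominal diameter
d_n = 2·(3V/4π)^(1/3)), wet weight W (→ density ρ = W/V) and shape
(→ Corey shape factor S_f = c/√(ab)).  The shape correction
S_f^(2/3) treats the particle as an ellipsoid; Model A omits it.  The
drag coefficient follows the two-group dimensionless form
C_D = (X₂·ν/(d_n^1.5·g^0.5) + X₃)^X₁, whose first term dominates in
the laminar limit and whose additive part represents the turbulent
limit.  The three shipped closures differ in how much shape enters
C_D; their constants are empirical and bound to SI inputs (Model A's
drag group ν/(d_n·g) is not dimensionless — its constant silently
carries units — so the API refuses non-SI evaluation throughout).

Assumptions: steady terminal settling in still water (no acceleration
phase, no ambient currents), rigid effective shape (thallus
reconfiguration and flexibility are folded into the empirical
constants), and a single well-mixed medium per observation.

## Axis-derivation routes

Irregular thalli rarely expose all three perpendicular axes.  Both
derived routes rest on the volume closure V = a·b·c:

* flattened (blades, leaves, also unbranched cylinders scanned flat):
  the scanned projection area P ≈ a·b, so thickness c = V/P and
  S_f = V·P^(−3/2);
* branched: mean youngest-branch width ≈ c, so a·b = V/c and
  S_f = c^(3/2)/√V;
* rigid objects: axes measured directly.

A derived S_f > 1 is reported as a morphology misclassification, not
clamped (only values a few ulp above 1, from rounding on exact
spheres, are snapped back to 1).  Replicate V/W measurements are
averaged; a spread above 5% of the mean triggers a warning but no data
are dropped, mirroring the originating measurement protocol's
repeat-on-divergence rule.

## Medium properties

ρ_sw(T, S) uses the one-atmosphere EOS-80 polynomial (Millero &
Poisson 1981); dynamic viscosity uses Sharqawy, Lienhard & Zubair
(2010), with ν = μ/ρ_sw.  Validity is restricted to 0–40 °C and
0–42 psu at surface pressure; practical salinity is used directly as
the correlation's mass-fraction argument (psu/1000), adequate at the
≲0.5 % level these correlations carry here.  Both correlations are
verified in the tests against pure-water reference values and required
to reproduce the study-median state (ν = 1.0915×10⁻⁶ m² s⁻¹ at ~15 psu,
17–18 °C) within 5 %.  `override_properties` injects known (ρ_sw, ν)
directly, bypassing the correlations, and
`STUDY_MEDIAN_MEDIUM` ships the median conditions the fitted constants
derive from (ρ_sw = 1009.45 kg m⁻³, ν = 1.0915×10⁻⁶ m² s⁻¹,
g = 9.81 m s⁻²).

## Numerical choices

* High powers of S_f (exponents ≈ 2.97 and ≈ 52) are evaluated as
  exp(p·log S_f) with underflow to zero permitted; for S_f ≤ 0.5 the
  52-power term is below 1e−15 and numerically irrelevant.
* Model C's drag base can turn negative (for the shipped constants:
  roughly S_f ≳ 0.25 at macrophyte sizes, and within the macrophyte
  d_n span already for S_f ≳ 0.03–0.07 at the largest diameters).
  Scalar evaluation raises a dedicated `DomainError` with the offending
  (d_n, S_f); grid evaluation masks cells instead of failing the grid.
  Buoyant particles (ρ ≤ ρ_sw) raise a separate `BuoyancyError`;
  exact neutral buoyancy returns ω = 0.
* ω = 0 exactly at ρ = ρ_sw for all three models.

## Genetic-algorithm refitting

Constants are refitted by minimising the mean squared error between
predicted and per-specimen aggregated observed velocities (mean of
replicates by default; median selectable).  Defaults follow the
original optimisation protocol: population 5000, crossover probability
0.8, mutation probability 0.1, elitism 250, at most 500 000
generations, stopping after 5000 generations without improvement.
Choices the protocol leaves open were made as follows:

* encoding: multiplicative constants in log10 (they span 0.89 to
  4.6×10⁶; a linear encoding cannot move), exponents linear in
  [0, 100]; default bounds ±3 decades around the shipped preset per
  multiplicative constant, user-overridable;
* operators: tournament selection (size 3), blend (BLX-0.5)
  crossover, and mutation that is Gaussian with per-gene scale tied to
  the current elite's spread (self-annealing: as the elite converges
  the search becomes local, which drives noiseless objectives to
  numerical zero) plus a 20 % uniform-redraw component that keeps
  exploring other basins of the rugged 8-constant landscape;
* out-of-domain candidates receive a finite penalty of 10³ × the worst
  in-domain squared error in the current population, preserving
  selection gradients near the domain boundary;
* elitism copies the best individuals unchanged, so the best-objective
  history is non-increasing by construction; identical seed, config
  and data give bit-identical results.

Reduced settings used by the test-suite (documented as the package's
own problem sizes): population 200, stall window 200 for the
single-constant structures A and B — which recover the shipped
constants to machine precision from 20 noiseless synthetic
observations in ~1 s — and population 600, stall window 500, cap
30 000 generations for the 8-constant structure C (~45 s).

## Synthetic data: what it emulates, and what it does not

The generator draws d_n log-uniform over 0.576–4.844 cm and S_f
log-uniform over 0.00029–0.0689 (both spanning ~2 decades, hence the
log draws), ρ lognormal around the median 1104.44 kg m⁻³ (spread 0.03
in log, keeping ~99.9 % of draws negatively buoyant in the median
medium), the medium fixed at the study-median state, and 5 replicate
velocities per specimen with multiplicative lognormal noise of CV 0.1
(replicate spread scales with velocity and stays positive).  Raw route
fields are back-computed from (V, S_f), so the trait-derivation
routes reproduce the drawn values exactly — a closed-loop oracle.

Settling campaigns (observation generation for fitting) default to the
same ranges but the test-suite restricts S_f to 0.00029–0.0278, the
span actually observed among negatively buoyant specimens; larger
shape factors occurred only in floating specimens, which contribute no
velocity observations, and they push samples against Model C's domain
boundary where its predictions become arbitrarily sensitive.  Samples
out of the generating model's drag domain are resampled (≤100 attempts
per specimen, then an error), and floating specimens are emitted
flagged, without velocities.

Not emulated: trait covariances (S_f, d_n, ρ drawn independently),
species identity, batch structure, day-to-day medium drift, and any
surface-material effect on drag.  Passing the synthetic closure tests
therefore demonstrates correctness of the computational chain, not
predictive skill on new field data.

## Predictive-recovery check for structure C

The 8-constant surface is partially degenerate: on the macrophyte
shape range the 52-power term is numerically zero, and several
constant combinations fit finite data equally well.  Recovery is
therefore assessed predictively: a refit on 40 noisy (CV 0.1)
synthetic observations must reproduce the generating model's
predictions on an independent specimen draw within 2 % RMS of the
per-specimen relative differences.  This is close to the statistical
limit √(p/n)·CV_eff ≈ 2 % (CV_eff ≈ 4.5 % after averaging 5
replicates), which is why the campaign uses the sinking-specimen shape
range: near Model C's domain boundary the surface's sensitivity makes
any finite-data fit diverge from the generator by far more than the
parametric noise floor.

## Known limitations

* The drag closures are empirical; extrapolation beyond the measured
  trait ranges (d_n 0.58–4.8 cm, S_f 3×10⁻⁴–0.07 for macrophytes) is
  unvalidated, and Model C is structurally unable to represent
  sphere-like particles.
* The seawater correlations are surface-pressure only; no
  absolute-salinity conversion is attempted.
* GA bounds default to ±3 decades around the shipped presets; a refit
  for a genuinely different particle class may need wider bounds and
  will inherit the degeneracy discussed above.
* MSD is read literally as the median of squared residuals (units
  m² s⁻²); the mean squared error is reported alongside since the GA
  optimises the mean.  Quartiles use linear interpolation (type 7),
  recorded in report metadata.
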