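# Methods

`canophot` estimates whole-plant photosynthesis of a greenhouse sweet-pepper
(paprika) canopy by chaining four models: a parametric 3D reconstruction of
the plant, Monte Carlo ray tracing of the light field, the
Farquhar–von Caemmerer–Berry (FvCB) leaf biochemistry evaluated per canopy
layer, and an area-weighted integration to the whole plant.  A closed-chamber
inversion converts logged CO2 draw-down into measured rates for validation.
This note records the model assumptions, the numerical choices, and the
places where the design was genuinely open.

## Plant architecture

A greenhouse paprika pruned to two primary stems ("V" trellis) is described
by a per-node structural table: leaf area (cm² per leaf), petiole length
(cm), blade droop below horizontal (degrees), internode length (cm), stem
radius (mm).  Each stem carries 15 nodes with one leaf per node; the packaged
reference table measures odd nodes 1..15 and even nodes are filled by linear
interpolation between bracketing measurements.  Droop is applied to the blade
at the petiole tip; the petiole itself is horizontal.

Choices that the structural data do not constrain, fixed once here:

* **Leaf outline.** A flat cordate polygon (24-triangle fan) of unit area,
  scaled to the target planform area.  At canopy scale, interception is
  governed by area and angle, not by outline detail, so any reasonable blade
  shape with the right area is adequate.
* **Phyllotaxis.** Azimuths alternate 180° node-to-node with a seeded
  Gaussian jitter (σ = 10°); no azimuth measurements exist for the reference
  plant.  The two stems lean ±30° from vertical in the row plane.
* **Leaf count per layer.** The structural table's per-layer leaf count n = 4
  is read as per layer per plant; with one leaf per node per stem this is
  consistent for a two-node layer (2 nodes × 2 stems).  The build therefore
  produces 30 leaves per plant.
* **Units and frame.** Metres internally (cm/mm at the CSV boundary);
  right-handed, z-up, ground at z = 0, rows along x.

The build is deterministic for a fixed seed (bit-identical meshes), every
blade's mesh area equals its specified area to round-off (the 1% contract has
large margin), and export to OBJ (named groups per organ) round-trips through
re-import with identical triangle counts and total area to 1e-6 relative.

## Light transport

Forward Monte Carlo from the sources into the scene, with equal-energy rays.
The sky is split into a direct beam (parallel rays along the sun vector,
computed by a NOAA-style solar-position algorithm accurate to well under
0.1°) and an isotropic diffuse sky; both are emitted from a horizontal plane
above the scene whose *horizontal* photon flux equals the measured global
PPFD, so per-leaf scores are directly in μmol m⁻² s⁻¹ of absorbed PPFD.

* **Leaf optics.** Bi-Lambertian with reflectance ρ = 0.10 and transmittance
  τ = 0.07 on both blade sides (integrating-sphere values for paprika);
  stems are opaque black.  At a leaf hit the fraction 1−ρ−τ of the ray's
  energy is scored to that leaf and the ray continues with the remainder,
  choosing reflection vs transmission with probability ρ/(ρ+τ) vs τ/(ρ+τ)
  and a cosine-weighted direction about the surface normal on the chosen
  side.  Only the direction is random; energy attenuation is deterministic,
  which makes the per-trace energy identity
  absorbed + escaped + truncated + opaque = emitted hold to round-off.
* **Ray budget.** Rays terminate on escape or after `max_impacts` = 10
  interactions (residual energy booked as truncated; with ρ+τ = 0.17 the
  truncated share after 10 impacts is ≤ 0.17¹⁰ ≈ 2·10⁻⁸ of the emitted
  flux).  The desk-scale default is 10⁶ rays per trace; accuracy scales as
  1/√n so larger budgets are a linear-cost knob, and the per-leaf Monte
  Carlo standard error is estimated from 16 batch means.
* **Reproducibility.** Every ray owns a counter-based splitmix64 stream
  seeded by (trace seed, global ray index), so results are bit-reproducible
  and independent of traversal order or batch partitioning.  Acceleration is
  a uniform voxel grid with Amanatides–Woo traversal — chosen over a BVH
  because it is simpler to verify and plenty fast at these scene sizes
  (~10³–10⁵ triangles).
* **Low sun.** Within 5° of the horizon the direct share is folded into the
  diffuse sky: the horizontal-flux convention would otherwise imply an
  unbounded beam radiance as cos(zenith) → 0, and near-horizon global light
  is diffuse-dominated in reality.  Between roughly 70° and 85° zenith the
  convention still inflates the beam radiance when paired with a synthetic
  diurnal PPFD profile that is not derived from the sun path; the FvCB
  saturation makes the plant-rate consequence small, and closed-loop tests
  are unaffected because both directions of the loop share the machinery.
* **Chamber and greenhouse surfaces** default to fully transparent
  (configurable); no spectral resolution, no penumbra.

Verified physics: single-surface absorption (1−ρ−τ)·I₀·cos(incidence) within
3 MC SE; the two-plate multiple-reflection series 0.83·τI₀/(1−ρ²); black-leaf
shadowing monotonicity (exact, by shared ray streams); and the turbid-medium
limit, where random small horizontal black leaves reproduce Beer–Lambert
extinction exp(−LAI).  The exponential is an *expectation over placements* —
a single random arrangement of 7500 leaves deviates by several percent from
it (verified against exact coverage integration), so the tests average a few
seeded placements.

## Leaf biochemistry

Standard FvCB at 25 °C in pressure units: Al = min{Av, Aj} − Rl, with
Av = Vl(ci−Γ*)/(ci+K′), K′ = Kc(1+O/Ko), Aj = J(ci−Γ*)/(4(ci+2Γ*)), J the
smaller root of θJ² − (Ile+Jm)J + IleJm = 0, and Ile = Il(1−f)/2.  Kinetic
constants: Kc 40.4 Pa, Ko 24.8 kPa, O 20.5 kPa, Γ 4.4 Pa, Γ* 3.69 Pa,
f 0.15, θ in 0.68–0.83 (default 0.75).  Temperature response and TPU
limitation are deliberately out of scope (all calibration data are at 25 °C).

Two respiration rules are exposed because they disagree slightly at these
constants: a fixed coefficient Rl = 0.0089·Vl (the default), and the
compensation-ratio form Rl = Vl(Γ−Γ*)/(Γ+K′) = 0.00908·Vl, which forces the
net rate to cross zero exactly at Γ.  The quadratic for J uses the
2c/(−b+√(b²−4ac)) form to avoid cancellation at low light; the discriminant
is non-negative for θ ≤ 1 and round-off is clamped.

## Capacity estimation from gas exchange

The measurement protocol is a LI-6400-style auto program: 20-point A/Ci
curves (external CO2 0–120 Pa at PPFD 1000) and light curves (PPFD 50–1000
at external CO2 100 Pa), per canopy layer (8 layers of 4 leaves counted
acropetally).

* **Amax** from the light curve by non-rectangular-hyperbola least squares
  (trust-region, 3 deterministic starts, bounds 0 < θ < 1, φ ≤ 0.125,
  Rd ≥ 0); non-convergence is flagged, not raised.
* **Vcmax** from the Rubisco-limited window Γ* < ci < 30 Pa.  The objective
  treats measured A as *net* and couples respiration to Vcmax inside the fit
  (A = Vl[(ci−Γ*)/(ci+K′) − r]); this makes the model linear in Vl, solved in
  closed form with an exact standard error.  A fixed-Rl mode exists because
  calibration protocols differ on how respiration entered the regression.
* **Jmax** from the window ci > 40 Pa by exact per-point algebraic inversion:
  gross Aj = A + Rl, J = 4Aj(ci+2Γ*)/(ci−Γ*), Jm = J(Ile−θJ)/(Ile−J); the
  estimate is the per-point mean and the SE their standard error.  Points
  implying J ≥ Ile are unphysical and dropped with a warning.  θ defaults to
  the same layer's light-curve fit, falling back to 0.75.

A caveat the tests encode: for bottom-canopy leaves (Vcmax ≈ 20, Jmax ≈ 50)
the Av/Aj crossover on a ci = 0.7·ca curve sits near ci ≈ 95 Pa, so the
ci > 40 Pa window of a full min-model curve is still Rubisco-limited and
Jmax is not identifiable from it; the synthetic generator therefore offers
single-limb curves for exact Jmax round-trips, and the full-model round trip
is exercised at top-layer capacities where the window is genuinely
RuBP-limited.

## Whole-plant integration and chamber validation

Leaves are grouped acropetally into layers of four (node order, both stems;
a remainder joins the top layer, so the 30-leaf reference plant has 7 layers
with 6 leaves in the top one).  Per half-hour step: solar position → ray
trace → area-weighted mean absorbed irradiance per layer on the centre plant
→ per-layer FvCB → plant rate Σ A_l·area_l.  Capacity profiles tabulated on
other layer labellings are mapped by linear interpolation over relative
canopy depth, preserving the top and bottom values.

Internal CO2 during simulation is set by a configurable rule, default
ci = 0.7·ca with ca the chamber CO2 setpoint (default 150 Pa, the midpoint
of the 100–200 Pa operating band).  The measurement campaign held chamber
CO2 above saturation, so the simulated rate is insensitive to the exact
ratio; the rule is still surfaced prominently because nothing in the
calibration data pins it down.

The validation chamber is a stirred 1×1×2 m volume at 25 °C and 101.325 kPa
with a measured leak of 0.2–0.3 μmol CO2 s⁻¹ (default 0.25).  Whole-plant
uptake is the least-squares slope of CO2 *mole fraction* vs time multiplied
by the chamber's molar air content PV/RT ≈ 81.75 mol.  CO2 injections (the
supply refills the chamber when it falls to ~100 Pa) appear as sawtooth
jumps: samples are masked from each detected jump (rise > 2 Pa per 10-s
sample) until the decline resumes plus a 2-minute guard (the valve's
exponential tail can balance uptake and fake a zero slope), and the slope is
fitted per contiguous unmasked segment — a single regression across the jump
would see the level shift as a spurious positive slope.  Segment slopes are
combined weighted by sample count; windows with fewer than 10 clean samples
report a missing value.  Leak subtraction is optional (default off, matching
the convention of reporting the raw draw-down rate).

## Synthetic data

The generators emulate the measurement campaign with known truth: protocol
gas-exchange curves with additive Gaussian noise on A (σ default
0.5 μmol m⁻² s⁻¹, chosen so replicate SEs land in the range reported for
this protocol); a half-sine diurnal PPFD profile sampled half-hourly from
09:00 to 18:00 on an autumn day with configurable diffuse fraction; and a
forward-Euler chamber mass balance with a first-order injection ramp (time
constant 60 s, fixed 300 s valve-open time) so the jump masking is genuinely
exercised.  What the generators do *not* emulate: instrument drift,
non-Gaussian outliers, imperfect chamber mixing (visible in real logs as a
lag between light fluctuation and CO2 response), leaf ageing within a layer,
and a diurnal PPFD course consistent with the actual sun path.  Passing the
closed-loop tests therefore demonstrates the internal consistency of the
chain — forward simulation and inverse estimation agree — not field accuracy
against those unmodelled effects.

## Problem sizes used in the shipped tests

Desk-scale budgets keep the full suite in the tens of seconds to minutes:
10⁶ rays for single-surface radiometry checks, 4 × 3·10⁵ rays for the
turbid-medium limit, 3·10⁵ rays per half-hour step for the end-to-end day
(19 steps, twice), and 100 replicates for the noise-calibration studies.
All are configuration knobs; accuracy scales as 1/√n_rays.

## Known limitations

* No stomatal-conductance coupling: ci is prescribed, not solved.
* No temperature functions; valid at 25 °C only.
* Beam radiance inflation at 70–85° solar zenith when the PPFD series is not
  derived from the sun path (see above).
* The turbid-medium Beer–Lambert agreement is statistical over placements.
* Layer ↔ parameter mapping across different layer counts is linear in
  relative depth; a plant whose capacity profile is strongly non-linear in
  depth would need a denser profile table.
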