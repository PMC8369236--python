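# Methods

`braggshift` models what a uniform magnetic field — such as the fringe-free
idealization of an MRI magnet in MRI-guided proton therapy — does to a
scanned proton pencil beam stopping in water: the Bragg peak moves sideways
(lateral shift, WD), pulls back in depth (retraction, ΔDD), and the dose
spot at the peak becomes asymmetric. The package provides (i) a closed-form
model of the shifts and its algebraic inversion for energy selection,
(ii) a desk-scale transport surrogate that scores 3D dose grids, and
(iii) the measurement operations that extract shifts and asymmetry metrics
from such grids.

## Closed-form shift model

Stopping is described by the Bragg–Kleeman range–energy law

    R(E) = α E^p,       α = 2.43×10⁻³ cm·MeV⁻ᵖ,  p = 1.75  (water),

with the consistent stopping power S(E) = E^(1−p)/(αp), so that
∫₀^E dE′/S(E′) = αE^p identically. A proton of charge q and kinetic energy
E in field B has curvature κ = 0.29979·qB/pc[GeV] per metre; in the
non-relativistic approximation pc = √(2mc²E), so κ(E) = κ₀/√E with
κ₀ = 2.9979·qB/√(2mc²) (cm⁻¹·MeV^½ in the package's cm/MeV/T units).

Under the continuous slowing-down approximation the residual range at
depth z is R−z, so E(z) = ((R−z)/α)^(1/p). Integrating the small-angle
deflection twice gives the lateral Bragg-peak shift in closed form,

    WD = (2p/(4p−1)) · κ₀ · α² · E₀^((4p−1)/2),

which at p = 1.75 is exactly (7/12)·κ₀·α²·E₀³; and integrating ½θ(z)²
gives the depth retraction

    ΔDD = κ₀² · α³ · E₀^(3p−1) · 2p²/((4p−1)(3p−1)).

Both are exact integrals of the small-angle, non-relativistic model —
the test suite checks them against independent numerical quadrature of
the same integrals to ≪0.5%. A first-order relativistic momentum
expansion multiplies WD by (1 − (3/8)·E₀/(2mc²)); this factor is < 1 and
decreasing in energy. The non-relativistic forms invert algebraically:

    E₀ = (WD / ((2p/(4p−1))κ₀α²))^(2/(4p−1)),
    E₀ = (ΔDD / (κ₀²α³·2p²/((4p−1)(3p−1))))^(1/(3p−1)),

which is how a prescribed shift (e.g. steering the peak away from an organ
at risk) selects the incident energy at a given field strength. The
inversions return continuous MeV; the CLI also prints the nearest integer.
WD is exactly linear and ΔDD exactly quadratic in B.

The deflection angle of the peak position is defined as
arctan(WD / (R − ΔDD)) — the retracted depth is the adjacent side. This
choice is isolated in one function (`deflection_angle`) since other
conventions (e.g. the unretracted range) differ by < 0.1° over the
studied grid.

## Transport surrogate

The simulator replaces a general-purpose Monte Carlo code at desk scale.
Geometry is fixed: beam along +z, field along +y, bending in the x–z
plane (the deflection sense, −x for protons, is recorded; analyses use
magnitudes). Other geometries raise an unsupported-geometry error.

**Central track.** The trajectory is parametrised by residual range: at
arc length s the energy is E(s) = ((R−s)/α)^(1/p) exactly, so step size
affects only geometric resolution. Per step (default 0.01 cm) the
direction is rotated by κ(E)·Δs on an exact circular arc; relativistic
momentum is the default in transport. Integration stops at the cutoff
energy (default 0.1 MeV, a standard transport limit) and deposits the
residual locally; halving the step changes the endpoint by < 0.1 mm.

Because the closed forms are non-relativistic, consistency tests compare
them with the **non-relativistic** track, where the only discrepancy is
the small-angle approximation (≤ 1.3% in WD, ≤ 0.8% in ΔDD over
E ∈ [70, 170] MeV, B ≤ 3 T). The relativistic track disagrees with the
non-relativistic ΔDD formula by up to ~7% at 170 MeV — that is the
momentum correction, not an integration error — and is instead validated
against the published Monte-Carlo outcomes of the energy-selection worked
example (2.0 cm and 0.24 cm at 3 T), which it reproduces within 5%.

**Dose scoring.** Both modes score deposited energy (MeV) on a voxel grid,
default 20×20×35 cm with 0.5 mm lateral and 1 mm depth voxels. (A much
finer binning would be needed only for sub-0.1 mm questions; peak
positions are refined to sub-voxel precision by interpolation instead.)

* *Pencil mode* (deterministic): each central-track sample carries a
  lateral Gaussian whose variance is the entrance spot (σ = 5 mm)
  plus the accumulated multiple-Coulomb-scattering second moment
  (Fermi–Eyges-style: var(s) = Σⱼ θ₀²(sⱼ)·(s−sⱼ)²), and its energy
  deposit is spread over depth slabs with an analytic Gaussian
  range-straggling kernel (per-slab erf integral, σ projected onto z by
  the local track direction). Deposits sum to the beam energy exactly,
  up to the mass recorded as truncated outside the grid.
* *MC mode* (sampled): each history draws an entry position from the 2D
  Gaussian spot and a Gaussian range perturbation σ_R = 0.012·R^0.935 cm
  (a standard water parameterization that sets the Bragg-peak width),
  then is transported with per-step Lorentz rotation (Rodrigues, about
  the field axis) and Gaussian Highland scattering kicks
  θ₀ = (14.1 MeV/pv)·√(t)·(1 + log₁₀t/9), t = Δs/X₀, X₀ = 36.08 cm,
  with the logarithmic factor clamped at zero so θ₀ → 0 with the step.
  Each history's energy profile is scaled to start exactly at E₀, so
  deposited energy is conserved per history. Transport is vectorized
  over histories; the default step is 1 mm. Runs are reproducible
  bit-for-bit from the recorded seed; batched runs (n ≥ 2) attach a
  per-voxel relative-standard-error grid whose mean scales as 1/√n on
  Poisson deposits.

**What the surrogate does not model.** Nuclear interactions, secondary
particles and δ-electrons are omitted, so the entrance region lacks the
dose build-up of a full Monte Carlo code and absolute entrance-normalized
peak ratios differ from measured beams; no analysis in this package
depends on absolute entrance dose. Energy-loss straggling is Gaussian
(no Vavilov/Landau tails), heterogeneities and non-uniform fringe fields
are out of scope. Passing tests therefore demonstrate the geometry and
scaling of the field-induced perturbations, not beam-data-grade dosimetry.

## Measurements

* **Peak location.** The generic `find_bragg_peak` takes the 3D argmax
  with 3-point parabolic sub-voxel refinement per axis (ties broken
  toward smaller depth, then smaller |x|). Shift measurement
  (`measure_shifts`) instead locates the depth peak on the
  laterally-integrated depth–dose curve and the lateral peak on the
  peak-slab profiles, because the 3D argmax is biased upstream where the
  lateral spread grows with depth; this matches how depth-dose and
  profile curves are conventionally read. WD is measured against the
  field-free beam axis; ΔDD as field-free minus in-field peak depth.
  With 1 mm depth slabs, sub-voxel retractions (e.g. 0.1 mm at 70 MeV,
  3 T) are at the localization limit; grid-based ΔDD is validated to
  max(5%, 0.3 slab) against the closed form.
* **Planar asymmetry.** The peak z-slab is max-normalized with axes
  u = bending axis, v = field axis (the asymmetry is expected along u,
  where the Lorentz deflection acts). 1D Gaussian fits use least squares;
  `sigma_ratio` fits the marginal (summed) profiles by default —
  identical to central cuts for Gaussian spots, far more robust to
  sampling noise — and reports σ_u/σ_v. An optional in-plane Gaussian
  smoothing (in pixels) de-noises sampled slabs before contouring.
* **Isodose skewness.** Contours at fractions of the slab maximum
  (default 0.8/0.5/0.2; the levels are relative) are extracted by
  marching squares and must close around the peak. A single shared
  center minimizing the annulus area π(r_EC² − r_IC²) is found by a
  15×15 coarse grid plus Nelder–Mead refinement; r_IC/r_EC are the
  min/max center-to-contour distances. The radius difference is the
  skewness metric; the "standard radius" is the field-free fitted circle
  radius at the same level. The fit is rotation- and
  translation-invariant to ~10⁻³ cm and returns a zero difference for
  circles.
* **FWHM scan.** Lines through the refined peak rotate in the bending
  plane (default; the field plane by flag) from the beam axis over
  [0°, 180°) in 1° steps, sampled by trilinear interpolation at half the
  smallest voxel; FWHM comes from linearly-interpolated half-maximum
  crossings. The scan recovers a constructed principal-axis angle within
  one step and the closed-form 2.3548·σ of an isotropic Gaussian to 1%.

## Study conditions and problem sizes

The analytic grid follows the studied conditions: energies
70–170 (10 MeV steps), 200 and 270 MeV; fields 0–3 T in 0.5 T steps.
The asymmetry measurements use sampled transport at 2×10⁵ histories per
spot for 100/150/200 MeV at 0 and 3 T, scored on 2 mm analysis pixels
with 1-pixel smoothing — the history count and pixel size are chosen
together so the fitted-sigma noise (≈0.3%) sits below the physical
asymmetry signal (≈0.5–2% in σ_u/σ_v across that energy range).
At these statistics the field-off sigma ratio stays within [0.98, 1.02]
and both asymmetry metrics increase monotonically with energy at 3 T.
Published absolute FWHM-scan values and percentage tables that depend on
10¹⁰-history transport physics are represented by the packaged reference
tables and their comparison arithmetic, not recomputed.

## Numerical choices

cm/MeV/Tesla units throughout; conversions confined to `PhysicsConstants`.
Model constants (α, p, mc² = 938.272 MeV, cutoff) are overridable through
the configuration for sensitivity studies. Degenerate inputs raise typed
errors (`NoPeakError`, `ContourError`, `UnsupportedGeometryError`,
`FormatError`, …) rather than returning sentinels. Dose grids persist as
raw little-endian float32 NRRD with provenance embedded and mirrored in a
JSON sidecar; reading rejects files without voxel spacing or complete
provenance. CSV outputs are written at 9 significant digits so pipeline
re-runs are byte-identical.

## Known limitations

The surrogate's planar asymmetry at the Bragg peak is weaker than what
full-physics transport shows at high energy (no nuclear halo, Gaussian
straggling only), so asymmetry results are validated as orderings and
scalings, not absolute values. The 270 MeV range (≈ 43.7 cm by the range
law) exceeds the default 35 cm phantom depth; the simulator records the
truncated energy in the provenance, and no shipped analysis uses 270 MeV
absolute depths. Oblique beam–field geometries and ions other than
protons are unsupported by design.
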