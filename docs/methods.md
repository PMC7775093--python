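# Methods

## Model

CT attenuation is written per unit mass: the mass attenuation coefficient
μ/ρ of a material is the mass-fraction-weighted sum of elemental μ/ρ (the
mixture rule), and the mass-density-normalized Hounsfield unit

HU_ρ = 1000·(μ/ρ − (μ/ρ)_water)/(μ/ρ)_water

is therefore a property of composition and beam spectrum alone. Two exact
scalar identities connect it to measured HU: HU_ρ = (HU+1000)/ρ − 1000 and
ρ = (HU+1000)/(HU_ρ+1000). In the four-component tissue model (mass
fractions ω over water/lipid/protein/mineral, Σω = 1), HU_ρ and the
electron ratio ρ_e/ρ are affine in ω with water the zero reference:
HU_ρ = Σ_{i≠water} ω_i α_i and ρ_e/ρ = 1 + Σ ω_i β_i, where
α_i = 1000·((μ/ρ)_i/(μ/ρ)_water − 1) (spectrum-weighted, hence
beam-specific) and β_i = (Z/A)_i/(Z/A)_water − 1 (chemistry only).
Electron density follows as
ρ_e = (HU+1000)·(1+Σω_iβ_i)/(Σω_iα_i+1000); this factorizes exactly as
ρ·(ρ_e/ρ) and the package asserts that identity rather than assuming it.

Assumptions: tissues are mixtures of the four molecule classes; the
mineral axis is hydroxyapatite Ca5(PO4)3(OH); attenuation of a mixture is
element-additive (no molecular binding effects); the beam spectrum is
fixed across the field of view (no beam hardening or scatter modeling).

## Parameters and defaults

* **α (HU_ρ units, per beam).** Calibrated either from a spectrum
  (method 1) or from a phantom scan (method 2). The bundled phantom table
  yields kV (−50.8, −58.1, 604.8) and MV (4.5, −54.7, −77.9) for
  lipid/protein/mineral. `fixtures.published_params(beam)` carries the
  published method-2 values as inputs for sensitivity tables and
  examples; refitting the bundled table reproduces them.
* **β (dimensionless, beam-independent).** Tissue regression gives
  (0.00494, −0.0444, −0.0990) with R² = 0.9995 on the bundled tissue set;
  analytic hydroxyapatite gives β₃ = −0.103. The published values
  (0.00499, −0.0419, −0.113) are the default working set.
* **kV beam.** A bundled CSV: Kramers bremsstrahlung at 120 kVp filtered
  by 1.25 mm Cu, mean energy 78 keV. kV spectra are accepted as input
  tables; the bundled one is an example, not a tube simulation.
* **MV beam.** Gamma probability density on a 20–3490 keV grid. Scale is
  tied to shape so the fluence-weighted mean is 0.86 MeV, matching a
  3.5 MV fan-beam CT treatment beam; the default shape 3.2 additionally
  sets the low-energy width so the spectrum route reproduces the
  published hydroxyapatite mineral α at MV (−76.7). Both are ordinary
  user parameters for other beams.
* **QC threshold.** Materials with chlorine mass fraction ≥ 1%
  (inclusive) are flagged as non-biological surrogates; exclusion is the
  caller's decision and every fit logs which materials entered.

## Numerical choices

* Attenuation interpolation is log-log linear on an XCOM-style grid
  (10 keV–5 MeV, 3–4 significant figures); the biologically relevant
  elements have no absorption edges in range. Queries outside the grid
  raise rather than extrapolate.
* Fits are unweighted ordinary least squares with **no intercept** — the
  model forces pure water through zero, so an intercept would absorb
  calibration error into a nonphysical offset. Rank deficiency raises
  with a message naming the problem; R² is reported about the response
  mean, RMSE over all points.
* Printed-table comparisons round half away from zero to the table's
  displayed precision; internal computation is never rounded. Of the 18
  HU_ρ cells in the bundled commercial-phantom table, 15 follow exactly
  from the printed HU and ρ; three MV cells (Adipose, Muscle, Liver)
  differ by one integer unit, consistent with the published column having
  been computed from HU values before they were rounded for print. The
  table carries the printed values verbatim.
* Compositions off unit sum by ≤ 1e-3 are renormalized with a log entry
  (hand-entered tables); larger deviations raise. The phantom table's
  ρ_e column derives from undisclosed manufacturer elemental data and is
  stored as a fixture value, never recomputed.
* Scalar conversions raise on HU < −1000 (negative density) and on
  non-positive ρ or HU_ρ ≤ −1000; bulk volume conversion instead maps
  air-labeled and HU ≤ −1000 voxels to ρ = ρ_e = 0 and logs the count.
* The piecewise-linear lookup interpolates between breakpoints, averages
  duplicate-HU breakpoints, and continues its terminal segments linearly
  outside the calibrated range with a warning beyond 10% past it.
* Sensitivity errors are reported as 100·(estimated − true)/estimated,
  with the true material at unit density; the percent errors are provably
  density-invariant under the linear forward model (asserted in tests).

## Uncertainty propagation

Ground-truth phantom measurements propagate to first order (delta
method): σ_ρ/ρ = sqrt((σ_m/m)² + (σ_V/V)²) for a poured material of
measured mass and volume, and
σ_ρe² = (r·σ_ρ)² + (ρ²/(Z/A)_water²)·Σ_i((Z/A)_i σ_ωi)² with r the
nominal electron ratio, treating the elemental-fraction errors as
independent. Per-mil scale mass/volume errors give σ_ρ ≈ 0.002 g/cc on
water-like materials, the scale quoted for carefully mixed phantoms.

## Synthetic data

The phantom generator assigns each box region the noiseless HU its
material would image at under the forward model
HU = ρ·(1000 + Σω_iα_i) − 1000, then adds seeded Gaussian HU noise with a
single standard deviation per scan — the minimal stand-in for CT number
statistics. It emulates ROI statistics only: no reconstruction artifacts,
beam hardening, partial-volume mixing, or spatially correlated noise.
Passing end-to-end tests therefore demonstrates self-consistency of the
calibration/conversion chain and its noise behavior, not robustness to
scanner physics the generator does not model. Composition sampling draws
each nonzero fraction from a gamma distribution with the base fraction as
mean and a chosen coefficient of variation (default scenarios use 10%,
the natural spread reported for soft tissue), then renormalizes to the
simplex.

Test and example problem sizes (ROIs of ~10³ voxels, grids of ~10⁴–10⁵
voxels, 10³ composition draws) are chosen as the smallest sizes at which
the standard-error bounds being asserted are meaningful.

## Known limitations

* The four-component model does not cover non-hydroxyapatite minerals
  (e.g. cartilage's phosphorus without calcium) or exogenous materials
  (implants, contrast agents).
* Spectrum-route α values depend on the fidelity of the supplied
  spectrum; the bundled kV spectrum is a filtered-Kramers example, and
  lipid/protein α from method 1 additionally depend on which reference
  molecules stand in for the molecule classes. Phantom-route calibration
  (method 2) avoids both dependences and is preferred in practice.
* The bundled tissue table is a representative literature compilation;
  regressed β values shift at the few-percent level with the chosen
  tissue subset.
* Voxelwise conversion requires a composition label per voxel; how to
  obtain compositions in vivo (segmentation plus nominal values, spectral
  CT, ...) is outside the package's scope.
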