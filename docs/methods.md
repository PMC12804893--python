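# Methods

## Incubation kinetics

Headspace H₂ in a closed incubation bottle with active soil is modelled as
pure first-order loss toward zero, C(t) = C₀·e^(−kt), with t in minutes and
C in ppb. The decay is toward zero rather than an asymptote: high-affinity
hydrogen-oxidizing bacteria draw H₂ well below ambient, and the analytical
detection limit is reached before any plateau would be observable. An
optional floor could be added behind the same interface but defaults to
absent.

Fitting is two-stage: ordinary least squares on ln C vs t provides a robust
seed, then nonlinear least squares on the original scale (k constrained
non-negative) gives the reported k, its standard error from the Jacobian
covariance, and R² on the retained points. The log-linear stage alone would
weight small concentrations too heavily under additive instrument noise; the
nonlinear stage restores the correct error model. If the log-linear slope is
non-negative (no drawdown), the constrained optimum k = 0 is returned
directly with C₀ = mean(C).

Censoring: points strictly below the concentration detection limit
(57 ppb default) are dropped, not imputed; a series whose first point is
censored, or with fewer than three retained points, is rejected. No rule for
partial information below the limit is attempted because the measurement
distribution near the limit is not characterized.

Detection uses a one-sided two-standard-error criterion (k − 2·SE(k) > 0),
and `compare_to_controls` additionally requires the sample k to exceed the
largest control k by twice the pooled SE. Ties are non-detections.

## Soil water

Conversions use water density 1 g/cm³: θ = w·ρ_b and s = θ/φ, with s clipped
to [0, 1] (a clip warns — it means more water was added than the pore volume
holds). Saturation is a fraction everywhere internally; percentages appear
only at I/O. SOC is estimated from loss on ignition as SOC(%) = 0.58·LOI(%).

The retention curve is the Campbell power law Ψ(s) = Ψₑ·s^(−b), chosen
because it has two parameters, closed-form inverse s = (Ψ/Ψₑ)^(−1/b), and
standard texture-class values; it is fitted by least squares on
ln(−Ψ) = ln(−Ψₑ) − b·ln(s). s = 0 is representable in a `MoistureState`
(air-dried soil still holds tightly bound water) but is singular in
Ψ(s) and therefore rejected by `saturation_to_psi`. Hysteresis and the
osmotic/matric split are out of scope.

The water-stress threshold Ψ_ws is not point-identified by
detection/non-detection data; `estimate_psi_ws` returns the bracketing
interval [max Ψ among non-detections, min Ψ among detections]. When
replicate scatter makes the ranges overlap, the degenerate interval at the
detected bound is returned with a warning rather than an error — overlap is
expected with triplicate incubations near the threshold, and the detected
bound is the conservative (wet) choice.

## Deposition-velocity model

v_d(H₂) combines a barrier conductance g_i (snow and canopy in series) and
the soil conductance g_s in series resistance. g_s = √(k_m·f·g·h·D_s) is the
analytic surface conductance of a semi-infinite homogeneous soil column with
first-order volumetric sink k_m·f·g·h and diffusivity D_s; no vertical
resolution is attempted.

- **f(s)** = (1/N)(s−s_ws)^β₁(s_opt−s)^β₂, clamped to 0 outside
  (s_ws, s_opt) where the power terms are undefined. N is evaluated at the
  analytic argmax s* = (β₁·s_opt + β₂·s_ws)/(β₁+β₂) so max f = 1 exactly
  (verified against a 10⁶-point grid to ≤1e-9). s_ws and s_opt are obtained
  from the two water potentials Ψ_ws (default −100 MPa; −3 MPa supported as
  the legacy configuration) and Ψ_opt (default −0.03 MPa) through each
  soil's retention curve, which is what makes a single threshold portable
  across textures. "Optimum" here names the upper zero of the formula; the
  response peaks at s* between the two zeros. β₁ = β₂ = 1 and Ψ_opt are
  model-lineage defaults, configurable, not measured values.
- **g(Tₛ)** defaults to a Gaussian normalized to 1 at T_opt = 27 °C with
  width 12 °C and a hard zero at/below −5 °C (frozen soil). The functional
  form is pluggable; these numbers are implementation defaults for a
  mesophilic community, not measurements.
- **h(SOC)**: absolute form a + b·SOC with a = 0.00387 min⁻¹ g⁻¹ and
  b = 0.0024 min⁻¹ g⁻¹ per %SOC (the empirical linear fit of maximum
  oxidation rate to soil organic carbon). Inside g_s the relative form
  (a + b·SOC)/(a + b·SOC_ref), SOC_ref = 2%, is the default so that
  calibrated k_m magnitudes are comparable across configurations; `off`
  disables the modulation. f is normalized to 1 independently of h.
- **D_s** is Millington–Quirk: D_air(T,P)·φ^(4/3)·(1−s)^(10/3), with
  D_air = 6.1e-5 m²/s for H₂ at 0 °C and 1 atm scaled by
  (T/273.15 K)^1.75·(P_ref/P). Both the reference value and the scaling are
  configurable.
- **Snow**: g_snow = D_air·φ_snow^(4/3)/depth with snow porosity 0.645;
  zero depth means no barrier. **Canopy** is a single configurable constant
  conductance (or none); no canopy scheme is implemented. Unbounded
  conductances are represented by `math.inf` (zero resistance), never a
  large magic number.

**Calibration.** The area-weighted, time-mean global v_d is strictly
increasing in k_m, so `calibrate_km` bisects on log₁₀ k_m within
[1e-8, 1e2] s⁻¹ until the mean matches the target (0.09 mm/s default) to
1e-6 relative. The biotic product and barrier resistances are precomputed
once, so each bisection step costs one square root over the grid.

## Gridded simulation

Cells are independent; v_d is evaluated per cell and hour, vectorized, and
is exactly reproducible and permutation-invariant (tested against a scalar
per-cell loop). Averaging order is fixed: time mean per cell first, then
area-weighted spatial mean — the orders agree for complete records, and
missing time steps are an error, never skipped. Zone labels (tropical,
desert, semi-arid, temperate, continental, polar) are inputs on the grid,
not computed from a climate classifier. Moisture inhibition is defined on
f(s) = 0 — the biotic factor — so snow cover does not count as moisture
inhibition; note the wet side (s ≥ s_opt) also counts as f = 0. Both an
area mode (fraction of zone area whose cells never activate over the
record) and an area-time mode (fraction of cell-hours with f = 0) are
provided and labelled in the output, since "fraction of a region inhibited"
is ambiguous between the two readings.

## Synthetic forcing

The generator emulates the *structure* of reanalysis-driven forcing, not its
statistics: per-zone mean saturation with lag-1 autocorrelated (AR(1))
hourly variability generated on the logit scale and back-transformed (so
[0,1] is respected without clipping artifacts), a seasonal cosine plus white
noise for soil temperature, snow only in continental/polar cells when the
soil is below 0 °C, static lognormal SOC per zone, cos-latitude area weights
from nominal per-zone latitude bands, and Clapp–Hornberger-style retention
parameters and porosities per zone's dominant texture. Per-cell
climatological offsets (larger in arid zones) create dry and wet sites
within a zone. One master seed expands into named substreams (layout,
moisture, temperature, SOC) so adding a generator never perturbs existing
outputs; the 'late' epoch subtracts a saturation offset (default 0.05) from
desert/semi-arid means while sharing every random draw with 'early', so
epoch differences isolate the prescribed drying.

What passing tests on this forcing do **not** show: agreement with
reanalysis-based global percentages. The synthetic grid has no spatial
correlation, no diurnal cycle, no precipitation events, and stylized zone
climatologies, so zone shares and inhibition fractions computed on it are
mechanism demonstrations (signs and orderings), not geographic estimates.

## Numerical choices and edge cases

- Default grid sizes (100 cells × 8760 hours for calibration runs; smaller
  for property sweeps) keep every analysis in seconds while leaving ≥88
  effectively independent moisture samples per cell-year at the default
  autocorrelation.
- Retention fits reject fewer than 3 pairs or zero spread in s; threshold
  estimation requires at least one detection and one non-detection.
- f's empty-window case (s_ws ≥ s_opt, possible for very wet Ψ_ws on
  coarse soils) is a configuration error, not a silent zero.
- `detected` at k exactly 0 is false by construction; r² is clipped to
  [0, 1] and defined as 1 for a perfect fit to a constant series.
- All generators, the replay pipeline and the grid runs are deterministic
  given (spec, seed); reports serialize with sorted keys so reruns are
  byte-identical.

## Known limitations

Single-layer (semi-infinite) soil column; no H₂ production term; no
diffusion-limited drawdown correction in the bottle model; canopy treated
as a constant; zone taxonomy fixed to six labels; retention defaults are
texture-class approximations, not fitted site curves.
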