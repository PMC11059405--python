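# Methods

## The model

`irmap` models the spread of insecticide resistance through an
*Anopheles gambiae* population with three compartments: susceptible
mosquitoes S, resistant mosquitoes R, and non-resistant offspring of
resistant mosquitoes M. Two variants are provided. Model 1 (imperfect
vertical transmission) is

    dS/dt = r − (μ + μ_i) S − (β/N) S R − γ S M + α M S
    dR/dt = (β/N) S R − μ R
    dM/dt = γ S M − α M S − μ M

with birth rate r, natural mortality μ, insecticide-induced mortality
μ_i, transmission probability β, non-resistant-offspring probability γ,
return rate α of non-resistant offspring to the susceptible pool, and
total population N. Model 2 (perfect transmission) is model 1 with
α = 0; the choice of model is always an explicit argument, never
inferred from the value of α.

Two structural quirks of this formulation are kept deliberately and
surfaced rather than "fixed":

- In dS/dt, susceptibles are consumed by mass-action contact with M
  (−γSM) and replenished by +αMS. A flow-based reading (offspring
  leaving M for S) would instead put +αM in dS/dt; we implement the
  mass-action form as the model is defined, and note that the two
  differ away from the resistance-free equilibrium.
- The closed-form reproduction number below is not what the standard
  next-generation construction yields for this system. Both are
  exposed; see "Reproduction number".

The resistance-free equilibrium (RFE) is (r/(μ+μ_i), 0, 0). Linearizing
at the RFE decouples R and M and gives two invasion ratios,
β·S\*/(N·μ) and (γ−α)·S\*/μ with S\* = r/(μ+μ_i); a ratio above one
means the corresponding compartment invades. The simulation tests
verify decay and growth of a small resistant perturbation on both sides
of this threshold — the stability statements are checked against the
Jacobian-derived ratios, not against the closed-form R0, because the
two do not coincide for this system.

## Reproduction number

The quantity used for all maps and sensitivity results is the closed
form

    R0 = 1/(μ + μ_i + α) · sqrt(β (r + γ) / N),

interpreted as the average number of resistant mosquitoes a single
resistant mosquito gives rise to over its lifetime. `ngm_standard`
additionally exposes the spectral radius of the standard F·V⁻¹
next-generation matrix on the infected block {R, M}, which equals the
maximum of the two invasion ratios. At the calibrated baseline the two
quantities differ by two orders of magnitude; `ngm_standard` exists as
a diagnostic of that discrepancy, never as the mapped quantity.

## Climate responses

Adult mortality follows the Martens-style lifespan quadratic
μ(T) = 1/(a T² + b T + c). Where the quadratic is not positive the rate
is undefined; this is returned as a NaN marker, not an exception, so
raster pipelines carry such cells as nodata. The shipped presets differ
in one coefficient:

- `parham2010` (default): a = −0.03 (°C² day)⁻¹, the standard value.
  The quadratic is positive roughly between 4 °C and 40 °C.
- `table1_as_printed`: a = −0.3. With that value the discriminant
  b² − 4ac = 1.31² − 5.28 is negative and the downward parabola never
  crosses zero, so the lifespan is negative at **every** temperature
  and every map pixel is nodata. The preset is kept for faithfulness to
  the calibrated table it reproduces, and the package treats it as a
  documented defect rather than silently correcting it; the acceptance
  suite asserts its total invalidity.

The birth rate is

    r(R, T) = B_E θ_E θ_L θ_P · (4R(R_L − R)/R_L²)³
              · (k1 T + k2) e^{−(k1 T + k2)} / (2(k1 T + k2) + 1)

with eggs per oviposition B_E = 200, immature daily survivals
θ_E = 0.9, θ_L = 0.25, θ_P = 0.75, rainfall limit R_L = 50 mm, and
development constants k1 = 0.00554 (°C day)⁻¹, k2 = −0.06737 day⁻¹. The
rainfall factor peaks (=1) at R_L/2 and is clamped to 0 above R_L
(flooding washout) where the cubed parabola would otherwise go
negative. The development term is floored at zero. One symbol in the
source formulation of the denominator ("c1") is undefined; it is read
as k1, which is the only reading that makes the expression well-formed.
All rates are per day; monthly climate means are treated as the
representative daily forcing for their month.

The climate-driven R0 substitutes μ(T) and r(R, T) into the closed
form. Two routes are implemented — composition of the two response
functions, and the single expanded expression — and tested for
agreement to 1e−12 over a dense (T, rain) grid.

## Risk classes

Pixels are classified low (R0 < 1), moderate (1 ≤ R0 ≤ 1.1), high
(R0 > 1.1). The moderate band is the closed interval, so exactly 1 and
exactly 1.1 are moderate: a deterministic, documented tie-break.

## Sensitivity analysis

Local: each parameter is multiplied by (1 ± 0.10) and the signed
percent change in the closed-form R0 reported. Because R0 is a pure
power law in β and N, those two changes are baseline-independent:
+10 % in β gives sqrt(1.1) − 1 = +4.88 %, +10 % in N gives
1/sqrt(1.1) − 1 = −4.65 %. At the calibrated baseline r = γ = 0.75, a
+10 % change in either r or γ scales the radicand by 1.05 and gives
+2.47 %. A formally perturbed probability (β = 1 → 1.1) is evaluated as
a sensitivity construct on the raw formula; it is not a biological
parameter set and does not pass type validation.

Global: Latin hypercube sampling (one draw per equal-probability
stratum per parameter, seeded) over uniform ranges, by default ±20 %
around the active preset — the sampling distributions behind published
PRCC magnitudes for this model are not stated anywhere we could follow,
so the default is chosen to robustly reproduce the *sign* structure and
exact magnitudes are explicitly out of scope. PRCC is computed by
rank-transforming all columns and the output, regressing each
parameter's ranks and the output's ranks on the other parameters'
ranks, and correlating the residuals; significance is a two-sided
t-test with n − 2 − k degrees of freedom (k covariates). The signs
recovered at n = 1000 match the analytic monotonicity of the closed
form: positive for β, r, γ; negative for N, μ, μ_i, α. Note μ is
negative — an increased death rate shortens the resistant lifetime and
lowers R0 — and the tests assert that sign.

## Raster pipeline

Rasters are plain-text ESRI ASCII grids (header ncols, nrows,
xllcorner, yllcorner, cellsize, NODATA_value; first data row is the
northernmost). In memory nodata is NaN; the sentinel (−9999 by default)
appears only in files. The pipeline evaluates R0 independently per
pixel from co-registered temperature (°C) and rainfall (mm/month)
grids, with nodata wherever an input is nodata or μ(T) is undefined.

The annual map is the pixel-wise mean of the 12 monthly R0 maps
(configurable to median). The source description of annual aggregation
("50 % annual contribution" of monthly values) is not interpretable as
a concrete weighting; the mean is the neutral reading and the choice is
recorded in each run's provenance block.

The 95 % CI layers are mean ± 1.96·SD across the 12 months, with the
sample (n−1) standard deviation; a pixel needs at least two valid
months. The width identity upper − lower = 2·1.96·SD holds raster-wide
by construction and is asserted in tests.

Validation overlays confirmed-resistant observation points on a class
map: the score is the fraction of scorable points whose containing
pixel has the target class. Cells are half-open
[x, x+cellsize) × [y, y+cellsize), so points exactly on the top or
right boundary fall off-grid. Only resistant-status points are scored;
susceptible points are not used as negatives because the published
accuracy figure does not state how (or whether) they entered it.

## Synthetic fixtures

`make_climate` generates 12 co-registered temperature and rainfall
grids: a latitudinal gradient plus sinusoidal seasonal cycle for
temperature (clipped to [0, 45] °C) and a cos² seasonal bump for
rainfall that peaks at `rain_peak` in the wet-season month at the
central latitude (floored at 0 mm). Defaults are a 40×40 grid of 0.5°
cells with lower-left corner (−20, −35) — an Africa-like extent at toy
resolution so full-pipeline tests run in seconds — with T_mean 25 °C,
seasonal amplitude 4 °C, rain peak 25 mm = R_L/2 (so the wettest
pixel-month saturates the rainfall factor exactly) and small Gaussian
noise (SD 0.5 °C, 2 mm), all behind one seeded generator.

`make_points` places round(n·frac_high) resistant points uniformly
inside randomly chosen high-class pixels and the remainder uniformly
over all valid pixels, so the constructed class membership of every
point is known and the overlay score can be checked exactly by
counting.

What passing these tests shows: every pipeline stage is numerically
correct and self-consistent end to end. What it does not show: the
generator carries no real climatology, no spatial autocorrelation
beyond the smooth gradients, and no resemblance to the geography of
observed resistance, so pipeline accuracy on synthetic points says
nothing about predictive accuracy on field data.

## Numerical choices

- ODE integration: adaptive RK45 with rtol 1e−8, atol 1e−10. The
  system is non-stiff at realistic parameter magnitudes. Compartment
  undershoot below −1e−9 raises; smaller undershoot is clipped to zero
  with a warning (compartments are counts).
- Invalidity (μ(T) undefined, development denominator ≤ 0) is a NaN
  value, never an exception, so maps degrade to nodata cell-wise.
- All stochastic entry points take an explicit seed and record it in
  their outputs; identical configuration + seed gives bit-identical
  CSV and value-identical rasters.

## Known limitations

- No genotype structure (e.g. kdr homo/heterozygotes), no human-host
  transmission, no humidity or land-use covariates.
- No spatial interpolation or smoothing: classification operates on
  the computed grid directly.
- GeoTIFF I/O is not provided; the canonical exchange format is the
  ESRI ASCII grid, plus CSV for points.
- The closed-form R0 and the standard next-generation construction
  disagree for this system; the package takes the closed form as the
  mapped quantity and exposes the disagreement rather than resolving
  it.
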