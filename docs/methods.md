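# Methods

This note documents the models, parameter choices, and numerical conventions
behind `cobenefits`, and what the synthetic data do and do not establish.

## Scenario structure

Three scenarios are compared on a common grid: a baseline year (2018), a
business-as-usual future (2030 BAU: warmer climate, ~6% more coal generation
from the city's plant), and a mitigation + adaptation future (2030 M&A: the
plant's emissions eliminated and its 2.10 TWh supply replaced by renewables;
cool roofs expanded by 20.60 km²). Scenario-level scalar inputs (monthly
PM2.5 city means and spatial SDs, populations by age band, baseline
mortality, temperatures, TWh figures) are bundled in
`cobenefits.ahmedabad` and used as-is; the package checks their internal
consistency rather than re-deriving them from energy or climate models.

## Synthetic gridded fields

The generator emulates the *statistical structure* of chemical-transport
model output, not its physics:

* **Background**: per representative month, white Gaussian noise smoothed by
  a separable Gaussian kernel (correlation length in cells), rescaled to the
  configured spatial SD, shifted to the configured monthly mean, clipped at
  zero. Clipping can shift the realized mean slightly when the SD is large
  relative to the mean; at the bundled settings the effect is negligible.
* **Plume**: an isotropic exponential kernel exp(−d/L) in Euclidean cell
  distance, amplitude = emission_scale × monthly contribution. Real plumes
  are anisotropic and meteorology-driven; the kernel is a configurable
  stand-in that preserves the properties the analysis needs (localized,
  additive, linear in the emission multiplier).
* **Population**: independent Gamma(2,1) cell weights, optionally multiplied
  by (1 + w·C_norm) against a reference surface so population co-locates
  with pollution — this reproduces the qualitative gap between
  population-weighted (71.04) and unweighted (63.40) exposure seen in the
  study inputs. Integer persons are allocated by largest-remainder rounding,
  so citywide totals are exact. Age structure is spatially uniform (no
  spatial age data exist at this resolution); a cell's band population is
  its total times the citywide band fraction.
* **Monitors**: observations are truth = field/(1 − b) plus Gaussian noise,
  where b is the per-season fractional model underestimate. The bias is
  multiplicative, matching the percent-difference diagnostic that recovers
  it.

Default problem sizes — a 32×32 grid for the demo pipeline, 8×8–10×10 grids
for oracle and closure tests — were chosen so a full run completes in well
under a second while leaving enough cells for spatial statistics to be
meaningful. Passing tests on these fields demonstrates the correctness of
the *computations* (weighting, aggregation, ERF evaluation, rounding,
propagation); it says nothing about the realism of any particular dispersion
pattern.

## Annual exposure

The year is represented by four months (Jan/winter, May/pre-monsoon,
Jul/monsoon, Oct/post-monsoon) with weights equal to the number of calendar
months each season spans: (3, 3, 4, 2)/12. Applied to the bundled monthly
means this weighting reproduces the published annual averages 63.40
(baseline) and 64.90 (M&A) to two decimals; the BAU year recomputes to 65.53
against a published 65.50, a discrepancy attributable to rounding of the
printed monthly inputs, so exposure checks carry a ±0.05 µg m⁻³ tolerance.
The "city mean" is the unweighted mean over all grid cells (no municipal
mask is applied). Percent changes are reported relative to the reference
(earlier) scenario's population-weighted mean. The seasonal bias sign
convention is positive = model underestimate.

## Exposure-response functions

* **Log-linear** (`LogLinearERF`): parameterised by RR per 10 µg m⁻³;
  β = ln(RR₁₀)/10. The Turner all-cause default is the cohort's published
  1.06 (1.04–1.08), ages 30–99. The Pope all-cause default, 1.072
  (1.056–1.089), is a *calibration*: it is back-solved from the bundled
  aggregate BAU estimates (1389 (1092, 1681) deaths over 7 116 333 people at
  ΔC = 4.14 with y₀ = 684.21) because the underlying coefficient is not part
  of the bundled inputs. Both are configuration values, overridable per run.
* **GEMM** (`GemmERF`): θ = 0.143 (SE 0.01807), α = 1.6, µ = 15.5, ν = 36.8,
  counterfactual c₀ = 2.4 µg m⁻³, non-accidental mortality, ages 25–99 —
  the adult parameter set of the GEMM publication. Below c₀, RR ≡ 1 by
  construction (z clamped at 0). No 25–99 baseline mortality rate is
  available, so the 30–99 all-cause rate is applied to the 25–99 band; GEMM
  results are therefore flagged approximate wherever they are compared with
  published figures (±15% in the acceptance check, which also reflects
  aggregate-vs-cellwise differences).

## Attributable mortality

Cellwise computation: each cell contributes
(y₀/10⁵)·P_cell,band·(1 − e^{−β·ΔC_cell}) (log-linear) or
(y₀/10⁵)·P_cell,band·(RR_s − RR_r)/RR_s (GEMM), summed over cells. On
uniform surfaces this equals the aggregate closed form exactly; on
heterogeneous surfaces it differs in the direction given by the response's
curvature (for the concave log-linear form, cellwise ≤ aggregate-at-mean
with equal cell populations — Jensen's inequality; tested on constructed
surfaces). ΔC is always scenario − reference, so a dirtier scenario yields
positive excess deaths and a cleaner one negative (avoided) deaths; the
convention is not antisymmetric under swapping the pair, with relative
discrepancy bounded by e^{βΔC} − 1.

**Confidence intervals** re-run the identical nonlinear cellwise computation
at the coefficient CI endpoints (RR lo/hi, or θ ± 1.96·SE) rather than
linearizing; for negative deltas the bounds invert naturally (larger risk →
larger avoided magnitude).

**Mortality rates**: scenario rate = y₀ + excess/P × 10⁵. Rates are always
derived from the package's own death counts. (The bundled published rate
rows are not arithmetically consistent with their own death counts and
populations — e.g. 1389 deaths over 7 116 333 people is +19.5 per 100 000,
not the +23.7 the printed 707.95 implies — so those rows are kept only as
reference data, never asserted.)

**Attainment rollback**: if a surface's population-weighted mean exceeds the
target goal (an absolute level, or a percent reduction applied to a supplied
baseline mean), all cells are scaled by goal/current — a uniform
proportional rollback whose resulting population-weighted mean equals the
goal to 1e-9. A cap-at-level alternative (`method="cap"`) is provided for
sensitivity only. Avoided deaths are the negated excess of the rolled-back
surface relative to BAU, reported per ERF together with the across-ERF
maximum ("up to" convention). Deeper goals always avoid more deaths; the
bundled published "up to" counts (6510/9047/17 369) depend on an unstated
ERF assignment and gridded inputs, so only the ordering is asserted.

## Energy accounting

Pure unit bookkeeping: TWh↔kWh and km²↔m² conversions are exact powers of
ten (1 km² at 14.2 kWh m⁻² yr⁻¹ = 0.0142 TWh yr⁻¹). Coal CO2 emission
factors (0.938–1.243 kg CO2/kWh for substituted generation; 0.9095 kg/kWh
for demand-side savings) are calibrations back-solved from the bundled Mt
figures and exposed as configuration. Note the deliberate non-reconciliation
carried from the inputs: 20.60 km² of cool roofs yields 0.2925 TWh gross
savings while the scenario demand gap is 0.21 TWh (the remainder offsets the
climate-driven demand increase); both numbers are reported, neither is
"corrected".

## Pipeline and reproducibility

`run_pipeline` validates the configuration (returning *all* violations),
then generates, exposes, accounts, and assesses in order. The top-level seed
is split via `numpy.random.SeedSequence.spawn` into independent stage seeds
(background, population, monitors); the background stream is shared across
scenarios so that scenario differences are signal, not noise. Identical
config + seed gives byte-identical CSV outputs; the manifest records the
config hash and stage seeds. In the bundled demo configuration the plume is
superimposed on backgrounds already set to the published scenario monthly
means, so demo city means sit ~5–10% above the published annual table — the
demo demonstrates pipeline structure (ordering, signs, determinism), while
quantitative comparisons against published aggregates are made directly from
the bundled scalar inputs.

## Known limitations

No atmospheric chemistry or meteorology; no temporal downscaling below
monthly representative fields; no spatial age structure; no morbidity,
cause-specific mortality, life-table/YLL, or monetary valuation endpoints;
single point source (other regional sources enter only through the
background means).
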