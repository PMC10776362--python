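# Methods

This note documents the model, the synthetic study conditions, the
numerical choices, and the limitations of the `airburden` package. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## 1. The risk-assessment chain

The burden model is the standard attributable-fraction chain used in
global burden-of-disease work. Per cell *s*, year *t*, subgroup *k*
(sex × 5-year adult age band × urban/rural residence) and cause:

- relative risk `RR = ERF(C)/ERF(TMREL)`, linearly interpolated on the
  curve's concentration knots, clipped to 1 at and below the TMREL and
  extrapolated flat beyond the last knot;
- attributable fraction `AF = 1 − 1/RR ∈ [0, 1)`;
- attributable deaths `D = AF · B · P` with baseline cause-specific
  mortality rate B and subgroup population P;
- `YLL = Σ_k D_k · LE_k` and per-capita `LLE = LE₀ · YLL / P`.

PM₂.₅ exposure is the annual mean; O₃ exposure is the peak-season value,
the maximum 6-month moving average of the 12 within-year monthly means.
Windows never wrap across calendar years (7 windows per year); whether a
Nov–Apr window should be allowed is genuinely ambiguous, and the
within-year convention is pinned here because each year's metric must be
computable from that year's data alone.

Fine-particle curves cover six causes (ischemic heart disease, stroke,
lung cancer, COPD, lower-respiratory infection, type-2 diabetes), with
age-band-specific curves for the two cardiovascular causes; ozone uses a
single all-adult COPD curve. The combined two-pollutant burden is additive
in YLL/LLE. A positive PM₂.₅×O₃ interaction (synergy) would make the
separate burdens non-additive; it is a documented caveat, not modelled.

### Clipping and conventions

- RR is clipped to 1 below the TMREL so attributable deaths are never
  negative (no protective effect is counted).
- Exceedance fractions use strict inequality: cells exactly at a standard
  count as compliant.
- Interpolation is linear in concentration (not log-concentration):
  simple, monotonicity-preserving, and bit-reproducible.
- Subgroups with zero population contribute zero deaths; per-capita LLE is
  undefined (NaN / error) for an unpopulated cell.

## 2. Benefit metric and equity

The benefit of a stage (y1 → y2) is `GLE_s = LLE_{s,y1} − LLE_{s,y2}`
(years per capita; negative where air quality worsened on balance), and
`YLG_s = GLE_s · P_{s,y2} / LE₀`. The printed algebra that motivates YLG
can also be written with the population ratio P_{y1}/P_{y2}, which is
inconsistent with the primary definition of GLE as an LLE difference;
this implementation keeps GLE = ΔLLE as the definition and derives YLG
from it, so the identity `GLE·P_{y2} = LE₀·YLG` holds exactly.

The Lorenz curve sorts cells by per-capita GLE ascending (stable
tie-break on cell id), plots cumulative population share (horizontal)
against cumulative benefit share, and is reported exactly at every cell
boundary (no binning). The Gini index is 1 − 2×(trapezoid area). For
non-negative benefits this equals the population-weighted
mean-absolute-difference form, which the test suite verifies to 1e-10 on
random instances. Axis orientation does not matter for the Gini index
(it is symmetric under exchanging the axes).

Negative-GLE cells are included by default: they sort first, the Gini
index may then exceed 1, and the result carries the count of negative
cells plus a logged warning. An option drops them with explicit logging.
Both behaviours are exposed because neither is canonically "the" Gini of
a signed distribution.

## 3. Monte Carlo uncertainty

Uncertainty in deaths, YLL, and GLE comes from the exposure–response
draws: the chain is recomputed once per draw and the 2.5/97.5 empirical
percentiles are reported, with linear interpolation between order
statistics (pinned so confidence intervals are bit-reproducible). The
central estimate uses the central curve and is not guaranteed to lie
inside the draw interval; a warning is emitted when it does not.
Optionally the TMREL is sampled per draw from a uniform interval
(off by default). Baseline-rate and population uncertainty are not
propagated. Lorenz/Gini uncertainty is not computed.

Empirical percentile intervals of this kind undercover slightly in small
draw ensembles; the coverage test in the acceptance suite (200 replicates,
100 draws, matched log-normal parameter noise) measures coverage near but
a little below the nominal 95%, within the binomial tolerance.

## 4. The synthetic scenario

No distributional description of the real 1-km national inputs is
available, so all generator choices are explicit stand-ins. The generator
reproduces the features the method is sensitive to — levels, stage
changes, spatial smoothness, age structure — not real geography.

**Spatial fields.** White noise smoothed with an isotropic Gaussian kernel
of bandwidth `spatial_corr_length` (default 5 cells), re-standardised,
then scaled/shifted. Negative concentrations from additive noise are
truncated at zero and counted in the log.

**Exposure trajectory.** Defaults are calibrated so the national
population-weighted series match, in expectation, PM₂.₅
68.98 → 47.13 → 35.77 µg/m³ (stage declines 21.85 and 11.36 µg/m³, 48%
overall) and peak-season O₃ 111.4 → 121.1 → 114.9 µg/m³. PM declines are
multiplicative per stage with smooth cell-level heterogeneity (larger in
stage 1, emulating region-targeted control and ozone-growth hotspots); O₃
shifts are additive and sign-free. Monthly O₃ follows a summer-peaking
sinusoid normalised so that the peak-season operator returns exactly the
annual level.

**Population.** A log-smooth density surface normalised to 1×10⁹ adults;
a mature pyramid over 5-year bands 25–95+ (shares ∝ exp(−0.02i−0.016i²));
aging moves a fraction `aging_rate` (default 0.01/year) of each band's
mass one band older per year; sexes split 51.2/48.8; urban fraction drawn
uniformly per cell within [0.2, 0.8].

**Mortality.** Gompertz all-cause rates `6·10⁻⁴·exp(0.078·(age−27.5))`
with male ×1.25 and urban ×0.92 multipliers, jointly calibrated with the
pyramid to a crude adult rate near 7.6 per 1000 in the baseline year
(rising with aging, since age-specific rates are held constant). Cause
rates are the all-cause rate times a fixed profile (six pollutant-linked
causes ≈ 56.5% of deaths, remainder "other"), so cause-specific rates
conserve the all-cause total exactly. Residual life expectancy
`58·exp(−0.022·(age−27.5))` years; LE₀ = 77.6 years (a free scaling
constant of the per-capita metric, recorded in every output header).

**Exposure–response curves.** The parametric family
`RR(C) = 1 + α(1 − exp(−β·(C−TMREL)₊^γ))` tabulated on a 1 µg/m³ knot
grid (TMREL included as a knot so the normalisation reference is exact).
PM₂.₅ causes use γ ≈ 0.52–0.58 with strong saturation: the marginal
benefit per µg/m³ is much larger at low baseline concentrations, which is
what makes the second stage's smaller concentration cut deliver the larger
health gain. The ozone curve is mildly convex (γ = 1.3), so the ozone
burden rises faster than exposure during stage 1 and falls in stage 2.
PM TMREL 4.15 µg/m³, O₃ TMREL 32.4 µg/m³. Draws perturb (α, β)
log-normally (default scale 0.1), which keeps every draw ≥ 1 and
non-decreasing by construction.

**What passing tests do and do not show.** The generator produces smooth,
well-behaved fields with exact subgroup cross-products; real inputs have
missing data, coastlines, extreme density contrasts, and correlated
exposure–population structure the generator does not emulate. Passing
tests demonstrate correctness of the computations and the qualitative
mechanism (stage contrast, equity ordering), not numerical agreement with
any real national assessment.

## 5. Numerical choices

- Problem sizes: the default scenario is a 50×50 grid (2 500 cells) with
  100 draws; the test suite uses 6×6 to 20×20 grids with 2–8 draws, and a
  100×100 grid for the decline-recovery check. These sizes make every
  result exactly reproducible on a laptop within minutes.
- Closed-form vs tabulated curves agree to ≤ 1e-3 away from the TMREL
  (C ≥ TMREL + 1 on a 0.25 µg/m³ grid). For γ < 1 the family has a power
  cusp at the TMREL where no piecewise-linear table can meet that bound;
  the knot at the TMREL keeps the error one-sided and the RR continuous.
- Vectorised-vs-loop oracle comparisons use relative tolerance 1e-9
  (absolute 1e-9 on a ~10⁷ quantity is below float64 reordering error).
- All result tables are written with `%.12g` floats; identical seed and
  configuration reproduce byte-identical tables.
- RNG streams are derived from `(seed, component-tag)` so each generator
  is individually reproducible regardless of call order.

## 6. Known limitations

- Additivity of the two pollutant burdens ignores possible synergy.
- Baseline age-specific mortality is constant over years; real secular
  declines in age-specific rates (decreasing vulnerability) are not
  modelled, so the crude-vs-standardised contrast here isolates aging
  only.
- Curves are inputs: no meta-regression or curve fitting is performed,
  and no claim is made that the default family matches any published
  curve set numerically.
- Geographic realism (provinces, terrain, emission sectors) and
  machine-learning exposure surfaces are out of scope.
- Stratified-vs-pooled aggregation: summing deaths over subgroups equals
  computing on pooled strata only when AF and B are subgroup-constant;
  no inequality direction is guaranteed otherwise.
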