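# Methods

This note documents the models implemented in `csmp_survey`, the defaults
chosen where the survey methodology left the choice open, and what the
synthetic-data tests do and do not demonstrate.

## Decay correction and isotope ratios

Activities are point measurements (value, 1σ, nuclide, calendar reference
date) or censored records carrying a detection limit. Correction between
dates multiplies value, σ, and any detection limit by
`exp(−ln2·Δt/T½)`, so relative uncertainty is preserved and the round
trip is exact to machine precision. Conventions:

- **Half-lives**: T½(¹³⁷Cs) = 30.08 y, T½(¹³⁴Cs) = 2.0652 y (evaluated
  nuclear data). These are not survey observables; they are validated by
  the reproduction sweep in the test suite, which forward-corrects every
  worn-date ¹³⁷Cs particle activity and lands on the published
  2011-03-11 value to the printed precision for ≥ 90% of rows.
- **Date arithmetic**: whole-day differences divided by 365.25. The survey
  records dates only, so no time-of-day resolution exists; printed 3-digit
  activities cannot distinguish 365 from 365.25 days/year.
- The decay factor is treated as exact — half-life uncertainty is orders
  of magnitude below counting σ for these measurements.
- The ¹³⁴Cs/¹³⁷Cs ratio at 2011-03-11 carries first-order quadrature
  uncertainty, `(σ_R/R)² = (σ₁₃₄/A₁₃₄)² + (σ₁₃₇/A₁₃₇)²`. Nine years of
  ¹³⁴Cs decay (factor ≈ 20) makes individual ratios noisy; attribution is
  meaningful in aggregate, not per particle.

## Counting model

One effective efficiency scalar (net cps/Bq) per counting geometry — mask
cylinder and particle-on-tape — since quantification is comparative
against standards in the same geometry; no energy-dependent efficiency
curve or coincidence-summing correction is modelled. Detection limits use
Currie's formula `L_D = 2.71 + 4.65√B` counts (5% error rates). The
derivation convention behind the published limits is unstated; here the
published values (0.070 Bq per nuclide for whole masks at 50,000 s;
0.00577/0.00537 Bq for isolated particles at 600,000 s) are used only to
calibrate the synthetic background rates by inverting Currie, never
reproduced as results. A value at or below the limit is censored (ties
censor, the conservative choice).

## Particle sizing

Type-A CsMPs from Unit 2 follow the empirical activity–volume power law
`A₁₃₇(2011-03-11) = p·V^k` with p = 2×10¹⁶ Bq·cm⁻³ᵏ and k = 1.40; both
are overridable in `SizeModel`. Sizing inverts the law and converts
volume to diameter. The diameter formula circulated with this law places
π in the numerator — `2·(3Vπ/4)^{1/3}·10⁴` — which is **not** the
geometric inversion of a sphere's volume; the true-sphere form is smaller
by exactly π^{2/3} ≈ 2.145. Because every published size-table entry was
computed with the π-in-numerator form, `as_printed` is the default and
reproduces the table; the `spherical` variant is provided for physical
diameter estimates. The discrepancy is surfaced in the module
documentation rather than silently "fixed", since downstream comparisons
(size-range statements, table reproduction) are all in the printed
convention. Optional first-order σ propagation uses
`σ_V/V = σ_A/(k·A)` and `σ_d = d·σ_V/(3V)`; the published tables carry no
size uncertainty, so it is off by default.

## Survey analytics

- **Collection efficiency** `(1 − inner/outer)·100 %` is reported exactly
  as defined, with `significant ⇔ efficiency > 0` (the published
  significance criterion beyond sign is unstated). The quantity
  overstates true filtration because the outer mask pre-filters the
  airstream reaching the inner one; no correction is attempted, matching
  the original analysis, and the bias is documented on the result type.
- **CsMP fraction** divides particle by host-mask ¹³⁷Cs activity at the
  shared worn-date reference; a censored numerator yields a flagged upper
  bound at the detection limit.
- **Distance regression** is OLS of log₁₀(activity) on log₁₀(distance);
  with `fixed_slope=-2` only the intercept is fitted and R² is reported
  for the constrained model. No aggregation is imposed on callers — the
  original figure's point definition is not fully specified — but the
  synthetic recovery report aggregates to per-residence geometric means
  (see below).

## Imaging-plate simulation

The forward model deposits, per source, a normalised intensity profile
scaled by activity × exposure × a single PSL-calibration scalar
(2 PSL·Bq⁻¹·min⁻¹ by default; no plate-fading model), over a uniform
background (0.05 PSL·px⁻¹·min⁻¹), then draws Poisson counts. Insoluble
particles are isotropic Gaussians (σ = 1.5 px); soluble patches are 3:1
anisotropic Gaussians with a configurable scale. Detection thresholds at
background mean + k·σ (k = 5 default) with sigma-clipped background
estimation (Poisson-floored), 8-connectivity labelling, intensity-weighted
centroids, and components smaller than 2 px dropped as noise excursions.
The symmetry score is the minor/major ratio of the component's
intensity-weighted second central moments (1 = circular; a single-pixel
component scores 1 by convention); it is rotation-invariant and cleanly
separates compact particles (≈ 0.9 at high contrast) from elongated
soluble smears (≈ 0.1). The isolation simulation re-images the excised
fragment after each sonication, multiplying remaining activity by
(1 − solubility) per round, and integrates counts in a window around the
source (4σ for particles, 3 patch scales for patches) so that late-round
signals are not swamped by whole-plate background noise. Whether a
vanishing spot was soluble aerosol or a disintegrating brittle particle is
not distinguishable by this assay; solubility is an input parameter, not
a mechanistic claim.

## Synthetic survey generator

`SurveyConfig` defaults encode the campaign's design: 59 residences at
1.6–16.1 km (uniform), construction mix ≈ 78/15/6 % wood / light steel /
reinforced concrete, 2–4 persons per residence of a pool of six, ~50% of
person-visits wearing stacked pairs, ~5% of single masks being N95, worn
dates spread over 2016-04 to 2019-01. Mask catches follow
`A = C/d²·10^ε` with C = 400 Bq·km² and ε ~ N(0, 1.0 dex); the 1-dex
scatter reproduces the weak observed distance association (R² ≈ 0.2).
Discrete CsMPs occur with expected count `0.5·max(0, log₁₀(A/10 Bq))` — a
minimal monotone form consistent with the observation that particles
appear only on masks above ~10 Bq, calibrated to the campaign's yield of
~50 particles per ~280 masks. Particle ¹³⁷Cs activities are drawn at the
2011 reference (lognormal, median 0.5 Bq, 0.5 dex), truncated so no
worn-date activity exceeds 25 Bq, and their true volumes/diameters derive
from the same power law the sizing module inverts — recovery tests
therefore have an exact internal truth. ¹³⁴Cs is generated from the
Unit-2 ratio 1.08 at 2011-03-11 and decayed to the worn date. Pair truth:
efficiency ~ U(0, 0.85) applied to the soluble airstream; mask totals are
soluble background + particle sum by construction, so particle activity
can never exceed its host mask. Observation adds Poisson counting noise
via the calibrated setups and Currie censoring; `noiseless=True` bypasses
both noise draws for exactness tests. One seed governs everything, with a
`default_rng([seed, residence_index])` substream per residence.

**Recovery scoring** runs the real downstream pipeline on the observable
tables. The distance slope is fitted on per-residence geometric-mean
activities: masks within a residence share a distance and correlated
catches (stacked pairs share one draw), so per-mask OLS understates the
slope standard error; aggregation restores honest ~95% CI coverage of the
−2 truth (≥ 90/100 replicates in the acceptance suite). Censoring of
sub-limit masks attenuates the fitted slope slightly (≈ −1.8 on average
at default conditions); the CI criterion, not a point equality, is
therefore the right check.

**What the generator does not emulate**: person-level behaviour (cleaning
vigour, wearing time — unrecorded), building-material effects, the
multi-plume deposition chronology, and the real joint distribution of
soluble vs particle-bound activity, which is unknown (the survey itself
flags it as future work). Passing recovery tests therefore demonstrates
the correctness and calibration of the analysis chain under the stated
statistical structure, not the fidelity of that structure to any
particular residence.

## Reference tables and reproduction tolerances

The published tables are packaged as plain CSVs transcribed as printed,
including the `LDL` censoring markers, a known exponent typo in one
volume cell, and conflicting particle IDs between the worn-date table and
the 2011/size tables (one mask renamed, two sibling series swapped).
`datasets.match_worn_to_2011` reconciles IDs exactly where possible and
by closest worn-date activity otherwise (with a 20% agreement guard so
the three non-spherical particles, which were never sized, cannot be
mis-paired); non-identity matches are flagged for audit.

Reproduction sweeps compare recomputed values against printed cells with
`datasets.matches_printed`: the recomputed value, rounded to the printed
precision, may differ by one unit in the last digit (|Δ| ≤ 1.5 ulp).
This is the natural tolerance when both chains round — the original
values were computed from unrounded measurements, ours from the rounded
printed ones — and a handful of rows (documented in the tests) differ in
exactly this way.

## Problem sizes

Test and acceptance runs use 64×64 IP grids, 100–200 seeded replicates
for detection/recovery rates, 1000 replicates for counting
self-consistency, and default-size synthetic campaigns (~280 masks);
these sizes give stable rates (binomial σ ≈ 1.5% at n = 200) while
keeping the whole suite in seconds.

## Known limitations

- Decay-chain ingrowth (¹³⁷ᵐBa) and other accident radionuclides are out
  of scope; calibrated Bq values absorb the former.
- No spectrum-level modelling (peak fitting, energy calibration, true
  coincidence summing, geometry transfer between the two detectors).
- The ¹³⁴Cs reproduction of the 2011 table is slightly worse than ¹³⁷Cs
  (≈ 93% vs 100% of rows at the sweep tolerance), consistent with small
  internal rounding differences in the original tables; the sweep
  criterion is therefore defined on ¹³⁷Cs.
- Efficiency "significance" is sign-based; no hypothesis test against
  counting σ is attempted because the published criterion is unstated.
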