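# Methods

## Tracer model and estimators

The pool-dilution stages rest on the two-pool constant-rate tracer model.
Let A(t) be the total NH₄⁺ (or NO₃⁻) pool in µg N g⁻¹ DW, H(t) the ¹⁵N
excess mass in that pool, m the gross production rate and c the gross
consumption rate (both µg N g⁻¹ DW h⁻¹, assumed constant over the assay):

    dA/dt = m − c
    dH/dt = −c·H/A

Production adds unlabelled N only, diluting the tracer; consumption is
assumed non-fractionating, removing ¹⁵N in proportion to the pool's
current enrichment. The closed form is

    A(t) = A₀ + (m−c)·t
    H(t) = H₀ · (A(t)/A₀)^(−c/(m−c))          (m ≠ c)
    H(t) = H₀ · exp(−c·t/A₀)                  (m = c)

Inverting these for m gives the classical estimator implemented in
`pool_dilution.gross_rates`:

    grossmin = (Aₜ−A₀)/t · ln(APE₀/APEₜ)/ln(Aₜ/A₀)

where APE is the atom-percent excess over the ¹⁵N background. For
numerical work the estimator is evaluated as
`(A₀/t)·ln(APE₀/APEₜ)·δ/log1p(δ)` with δ = (Aₜ−A₀)/A₀, which is
algebraically identical, continuous through the removable singularity at
Aₜ = A₀ (where it reduces to the analytic limit `A₀·ln(APE₀/APEₜ)/t`) and
accurate to machine precision for all admissible δ. Observations inside a
relative band |δ| ≤ 1e−6 are flagged `NEAR_ZERO_NET_LIMIT`; the band
removes the singularity without masking real pool dynamics.

Estimator conventions for pathological data: an APE *increase* over the
assay is impossible under dilution, so gross production is reported
missing with an `APE_INCREASE` flag rather than raising on a negative
logarithm; negative gross consumption (net exceeding gross) is reported
as-is with `NEGATIVE_CONSUMPTION`, because negative net rates are real in
these soils and downstream consumers need the raw estimate. The identity
`gross_consumption = gross_production − net_rate` holds exactly by
construction on every record.

Duplicate assay subsamples are averaged at the observation level (pool
size and atom % per timepoint) before estimation — the duplicates share
one homogenised soil and differ only in measurement error, so averaging
before the nonlinear inversion is the lower-variance choice. Per-duplicate
estimation can be had by filtering the `replicate` column upstream.

Key assay constants, all configurable: incubation interval t = 20 h (the
4 h extraction is timepoint 0 of the assay, the 24 h extraction is time
t); ¹⁵N background 0.3663 atom % (natural abundance — the IRMS background
actually subtracted in any given lab run may differ, hence the knob, and
the chosen default is recorded in output metadata); label pulse 500 µL of
0.13 mM solution at 99 atom % on 2 g fresh soil, which at 75% moisture is
≈1.8 µg N g⁻¹ DW. Whether net rates should come from the labelled assays
themselves or from unamended controls is a genuine methodological
ambiguity; the package computes net from the same observations, which is
what the printed equations do.

## Assay chemistry

Amino acids are quantified as OPAME-derivative fluorescence against a
leucine standard curve, with the NH₄⁺ contribution removed using the
NH₄⁺ standard-curve *slope* only: any NH₄⁺-curve intercept is reagent
background already captured by the buffer-amended blank, and subtracting
it again would double-count. Conversion from µM leucine equivalents to
µg N uses one N atom per leucine (14.0067 µg N µmol⁻¹). Extract
concentrations convert to the soil-DW basis through the 1:10 (w/w)
extraction, assuming extractant density 1.

Depolymerisation is the OLS slope of slurry amino-acid concentration
against time (default sampling at 0.25, 4 and 6 h), scaled by slurry
water volume (40 mL) over soil dry weight (4 g fresh soil). The 1:1
TCA-stop mixing of subsamples is a fixed ×2 dilution, undone by
`measured_to_slurry` before fitting; the 400 µL of toluene (1% of slurry
volume) is ignored. All three timepoints enter the fit by default; a
baseline-difference mode is available by passing only two points. Whether
the original analysis used all three timepoints or the 15-min point as a
baseline is not determinable; OLS over all points is the default because
it uses all information and is invariant to the baseline level. Negative
concentrations and rates are floored to zero only in *reported* pools,
never inside intermediate fits, and flooring always sets a QC flag.

## Derived metrics

Turnover time is pool size over mean throughput: the arithmetic mean of
gross production and gross consumption for NH₄⁺ and NO₃⁻, production
alone for amino acids (their consumption is not measured by the slurry
assay). When consumption is flagged negative the calculation falls back
to production only, with a flag. Hours are the native unit throughout;
the reporting layer converts to per-day on request.

Per-area fluxes assume the entire organic horizon cycles N at the rate
measured on the pooled core: flux (g N m⁻² day⁻¹) = rate (µg N g⁻¹ DW
day⁻¹) × 10⁻⁶ × bulk density (g cm⁻³) × horizon depth (cm) × 10⁴.
Seasonal-change summaries are computed on untransformed group means.

## Mixed-model inference

Each response is analysed as y = Xβ + Σₖ Zₖuₖ + ε with independent
random intercepts per block and per sampling location (nested in block —
the location term carries the repeated-measures covariance of resampling
each spot in both seasons). PFT-level models replace species with the
shrub/moss factor in the fixed part and add species as a third random
intercept. Fits are REML; boundary (zero) variance estimates are
retained, not refit, which is standard practice with only five blocks.

Fixed terms are tested with Type-III F-statistics (sum-to-zero coding)
and Satterthwaite denominator degrees of freedom: for a scalar contrast
l, ν = 2f²/(∇fᵀA∇f) with f(θ) = l(XᵀV⁻¹X)⁻¹lᵀ and A the inverse observed
REML information; multi-df terms are reduced through the eigenvectors of
LCLᵀ and combined by moment matching. Kenward–Roger is not implemented;
on the balanced designs here the two agree. Variance components estimated
at the zero boundary are held fixed in the uncertainty propagation (the
fit has collapsed to the submodel without them), which makes the
zero-variance limit agree exactly with classical fixed-effects ANOVA —
verified to 1e-6 in the tests — and keeps the type-I error of the season
term calibrated (0.05 ± 0.02 over 1000 null simulations).

Derivatives of the REML criterion are taken by central finite differences
(one-sided at the boundary) with steps of 1e−4–1e−5 relative to each
variance; the response is standardised internally so the optimiser works
on O(1) variances, and three starts guard against local optima. The
engine reproduces lmerTest's F, Satterthwaite df, p and variance
components to four-plus significant figures on nested designs (see
`tests/test_stats_inference.py`).

Explained variance follows the fixed/random variance partition: R²m =
σ²_fixed/(σ²_fixed + Σσ²_random + σ²_resid) and R²c includes the random
components, with σ²_fixed the sample variance of the fixed-effect
predictions. Post-hoc comparisons are Tukey-adjusted contrasts of
estimated marginal means, p = P(q ≥ |t|√2) under the studentized range
with the contrast's Satterthwaite df; when the season × species
interaction has p below the threshold (default 0.05), species contrasts
are estimated within each season and season contrasts within each
species. The compact letter display uses insert-and-absorb with
alphabetical tie-breaking, recomputed per conditioning stratum.

Transforms follow the response map used for the field data (log for
pools/depolymerisation/some turnovers, square root for nitrate and most
gross rates, none for the signed net rates); each model's transform is a
per-response setting and domain violations report the offending rows.

## What the simulator emulates — and what it does not

`synthetic_data.simulate_study` forward-simulates the full design: 5
blocks × 6 species × 2 seasons (60 samples, 30 locations), with per-pool
isotope assays in duplicate (480 IRMS rows), plate-reader fluorometry
with shared leucine/NH₄⁺ standard curves, extract concentration tables
and slurry time courses. Spatial heterogeneity enters as multiplicative
lognormal block (SD 0.15) and location (SD 0.25) effects applied jointly
to a sample's rates and pools — a shared "fertility" multiplier, the
simplest structure consistent with positive rates and with pools and
fluxes co-varying in space. Measurement error: multiplicative CV 5% on
pool/extract/slurry concentrations (flow injection behaves
proportionally), additive SD 0.01 atom % on IRMS atom fractions
(truncated at background), multiplicative CV 2% on fluorescence reads.
No instrument-error magnitudes are derivable from the study itself; these
defaults are fixed package conventions chosen at realistic instrument
precision.

The default truth table encodes the study's qualitative biology at
realistic magnitudes: depolymerisation (3–7.5 µg N g⁻¹ DW h⁻¹) one order
of magnitude above gross mineralisation (0.2–0.8) and nitrification;
moss-soil mineralisation and NH₄⁺ pools declining steeply from early to
late season (−75% and −60%), deciduous shrubs declining moderately, the
evergreen flat; consumption slightly exceeding production early (negative
net rates) and nearly balancing late; the evergreen's late-season NO₃⁻
pool at 10% of early. Figure-level numbers are not recoverable from the
source, so these are the generator's own defaults, not measured
constants.

Deliberately not modelled: microbial biomass dynamics, ¹⁵N-addition
stimulation of consumption, microdiffusion recovery efficiency,
plate-layout effects, leaching or denitrification budgets. Passing tests
therefore demonstrate correctness of the estimators and inference under
the stated model — not that field data satisfy the constant-rate or
lognormal-effect assumptions. The RK4 oracle's time-varying-rate mode
quantifies one such violation: with production declining linearly to half
its initial value over the assay, the constant-rate estimator recovers
the time-averaged rate within ~10%.

## Problem sizes and numerical choices

Monte-Carlo checks use 200 replicate studies for parameter recovery
(median relative bias of gross mineralisation within ±5% under the
default noise), a 3-point noise grid at 25 replicates for RMSE
monotonicity, and 1000 reduced-design (3 blocks × 3 species) null
simulations for type-I-error calibration — sizes chosen so the full
suite completes in a few minutes while keeping Monte-Carlo error well
below the tolerances tested. The RK4 oracle uses 4000 fixed steps over
the assay horizon, giving ≤1e−8 relative agreement with the closed form
across the randomized parameter grid (m, c ∈ [0, 2], A₀ ∈ [1, 50],
t ∈ [1, 48] h). All simulation randomness flows from a single
`numpy.random.default_rng` seed; identical seeds produce byte-identical
CSV bundles.

## Known limitations

* The constant-rate assumption is the method's, not the soil's; rates
  that vary within the assay bias the estimate toward a time average.
* Satterthwaite (not Kenward–Roger) denominator df; for the balanced
  designs targeted here the difference is negligible.
* The nitrate analogue inherits the same non-fractionating-consumption
  assumption, although denitrification can fractionate.
* Per-area scaling treats the organic horizon as vertically homogeneous.
* The simulator's site properties use the per-species means; block-level
  variation in bulk density and depth is not propagated into area fluxes.
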