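# soilncycle

Gross soil nitrogen transformation rates from ¹⁵N pool dilution and
amino-acid assays, with nested mixed-model inference and a forward
simulator of the whole study design.

## The problem

In organic tundra soils, nitrogen availability to plants is governed by
three microbial processes that concentrations alone cannot resolve:
protein depolymerisation (release of free amino acids from soil protein),
gross N mineralisation (NH₄⁺ production from organic N) and gross
nitrification (NO₃⁻ production from NH₄⁺) — each running simultaneously
with microbial consumption of the same pools. This package implements the
complete analysis chain for a seasonal field comparison of dwarf-shrub and
moss soils: 5 replicate blocks × 6 plant species (3 shrubs, 3 mosses) × 2
growing-season timepoints, with each sampling location resampled in both
seasons.

It is written for ecosystem scientists running (or simulating) ¹⁵N
pool-dilution campaigns who want the entire path from raw plate-reader
and IRMS exports to publishable rate estimates and mixed-model ANOVA
tables in one tested, scriptable pipeline.

## The estimators

A ¹⁵N pulse added to the NH₄⁺ (or NO₃⁻) pool is diluted by gross
production of unlabelled N, while consumption removes N at the pool's
current enrichment. With pool sizes A₀, Aₜ (µg N g⁻¹ DW) and atom percent
excess APE₀, APEₜ at two timepoints separated by t hours:

    netmin   = (Aₜ − A₀)/t
    grossmin = (Aₜ − A₀)/t · ln(APE₀/APEₜ) / ln(Aₜ/A₀)
    grossammcons = grossmin − netmin

with the analytic limit `grossmin = A₀·ln(APE₀/APEₜ)/t` at the removable
singularity Aₜ = A₀, and the identical formulas for the nitrate pool.
Protein depolymerisation is the OLS slope of amino-acid accumulation in a
toluene-inhibited soil slurry, scaled to µg N g⁻¹ DW h⁻¹. Turnover time
of each plant-available N pool is pool size over mean throughput
(production only, for amino acids). Per-area fluxes scale gravimetric
rates by bulk density × organic-horizon depth.

Responses are analysed by REML linear mixed models — season × species
fixed, block and sampling location nested in block random — with Type-III
F-tests and Satterthwaite denominator degrees of freedom, Nakagawa–
Schielzeth marginal/conditional R², and Tukey-adjusted contrasts of
estimated marginal means (conditioned on the interaction when it is
significant). The inference layer is validated in the test suite against
classical ANOVA in the zero-variance limit, statsmodels `MixedLM`, and
R's lmerTest/emmeans.

## Worked example

```python
from soilncycle.pool_dilution import (
    IsotopeAssayObservation, gross_rates, label_addition_per_g_dw,
)

# tracer pulse of the mineralisation assay protocol
label = label_addition_per_g_dw(volume_uL=500, conc_mM=0.13,
                                soil_fw_g=2.0, moisture_frac=0.75)
print(f"label added: {label:.2f} ug N / g DW")

obs = IsotopeAssayObservation(
    sample_id="B1-At-early", pool="ammonium",
    A0=9.8, At=7.9, atom_pct_0=18.7, atom_pct_t=9.6,
    background_atom_pct=0.3663, t=20.0,
)
res = gross_rates(obs)
print(f"gross mineralisation: {res.gross_production:.3f} ug N g-1 DW h-1")
print(f"net mineralisation:   {res.net_rate:.3f}")
print(f"NH4+ consumption:     {res.gross_consumption:.3f}")
```

prints

```
label added: 1.82 ug N / g DW
gross mineralisation: 0.302 ug N g-1 DW h-1
net mineralisation:   -0.095
NH4+ consumption:     0.397
```

— a 0.3 µg N g⁻¹ DW h⁻¹ gross NH₄⁺ production that is more than offset
by microbial consumption (net rate negative), the typical early-season
situation in these soils. A full simulated campaign runs the same way:

```python
from soilncycle.synthetic_data import SimulationConfig, simulate_study
from soilncycle.pipeline import run_study_analysis
from soilncycle.stats_inference import ModelSpec, fit_mixed_anova

bundle = simulate_study(SimulationConfig(seed=42))
results = run_study_analysis(bundle)
anova = fit_mixed_anova(results["responses"],
                        ModelSpec("gross_min", transform="sqrt"))
t = anova.terms["season"]
print(f"season: F(1, {t.df_den:.1f}) = {t.F:.2f}, p = {t.p:.2g}")
print(f"R2m = {anova.r2_marginal:.2f}, R2c = {anova.r2_conditional:.2f}")
```

```
season: F(1, 24.0) = 1583.24, p = 2e-23
R2m = 0.86, R2c = 0.98
```

(the default simulation truth encodes a strong early→late decline in
mineralisation, which the season term picks up). The same stages are
available from the shell:

```sh
soilncycle simulate --seed 1 --out study/
soilncycle rates    --data study --out study/results
soilncycle stats    --data study --out study/results
soilncycle report   --data study --out study/results
```

## Layout

| module | contents |
| --- | --- |
| `soilncycle.core_io` | domain types, CSV schemas, species→PFT map, config |
| `soilncycle.assay_chemistry` | standard curves, OPAME amino-acid quantification, slurry depolymerisation rates |
| `soilncycle.pool_dilution` | isotope pool-dilution estimators, APE, label arithmetic |
| `soilncycle.derived_metrics` | turnover times, per-area fluxes, seasonal changes |
| `soilncycle.stats_inference` | REML mixed ANOVA, Satterthwaite tests, Tukey EMM contrasts, R²m/R²c |
| `soilncycle.mixed` | the variance-components REML engine |
| `soilncycle.synthetic_data` | forward simulator (closed form + RK4 oracle), parameter-recovery harness |
| `soilncycle.pipeline` | raw tables → pools → rates → turnover orchestration |
| `soilncycle.cli` | `soilncycle` command-line verbs |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
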