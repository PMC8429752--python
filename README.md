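# coldrange

Winter cold load, pest overwintering range, and pesticide resistance.

Many destructive agricultural pests — the motivating case is the
diamondback moth (*Plutella xylostella*), the worldwide pest of
crucifer crops — cannot tolerate cold winters: they persist year-round
only where winters are mild (permanent sites) and reinvade colder
regions each season (transient sites). Where a population persists
locally, repeated exposure to the same pesticides lets resistance
accumulate across years; where it dies out each winter, local
adaptation is reset. `coldrange` implements the full inference chain
linking winter climate to overwintering range and resistance, for
researchers in pest ecology, climate-impact modelling and resistance
management:

1. **Thermal predictors** (`degree_days`) — low-temperature degree-days

       LTDD = Σ_j max(0, x₀ − T_j),  x₀ = 11.0 °C,

   accumulated over hemisphere-aware annual windows (Jul–Jun in the
   north, calendar year in the south), plus MinDTmean, DTmean +
   exposure days, and growing-season ETDD (7.4–33 °C band).
2. **Survival models** (`survival_models`) — the nine candidates
   (3 predictors × linear/exponential/sigmoid) fitted by multi-start
   nonlinear least squares, compared by AIC, and field-validated by
   regressing observed on predicted survival. The canonical winner for
   chill-killed pests is S = a·exp(b·LTDD).
3. **Range mapping** (`range_mapper`) — the selected model projected
   onto gridded daily temperatures; cells classified permanent (5-year
   mean survival ≥ 5%), marginal (1–5%), transient (< 1%) or masked
   (host-plant presence probability < 0.3); cos-latitude-weighted
   areas, expansion series versus a baseline year, +1…+6 °C warming
   scenarios, and the LTDD trend of the baseline marginal belt.
4. **Resistance meta-analysis** (`resistance_meta`) — log
   response-ratio effect sizes from LC50 bioassays (logRR = ln RR,
   SE = CI width / 3.92, pooled variance V, weight 1/√V), prognostic
   variance imputation, five resistance levels, weighted geometric mean
   RR per overwintering type, a mixed-model Wald chi-square test of the
   overwintering effect, a 0.85-quantile LTDD model of top-15%
   resistance, and a Kendall-tau funnel check for publication bias.
5. **Synthetic data** (`synthetic_data`) — seeded generators for every
   input with known ground truth: chamber temperature regimes, binomial
   survival experiments, a toy climate grid with warming trend, host
   masks and resistance records with injected effects.
6. **Pipeline + CLI** (`pipeline`, `cli`) — one `coldrange` command
   orchestrating simulate → degree-days → fit → map → meta with a
   config file, structured logging, and a run manifest.

## Worked example

```python
import coldrange as cr

# chamber experiment: 10 winter regimes, 11 sampling points, 220 observations
regimes = cr.make_regimes(10, seed=42)
obs = cr.simulate_survival_experiment(regimes, seed=42)

ranking = cr.compare_models(obs, seed=42)
for m in ranking[:3]:
    print(f"{m.spec.predictor:12s} {m.spec.form:12s} AIC={m.aic:9.1f}  R2={m.r2:.3f}")
best = ranking[0]
print("coefficients:", {k: round(v, 5) for k, v in best.coefficients.items()})

field = cr.simulate_field_experiment(cr.TruthParams(), seed=43)
val = cr.validate_field(best, field)
print(f"field validation: slope={val.slope:.3f}  R2={val.r2:.3f}  n={val.n}")

grid = cr.simulate_climate_grid(24, 6, 1990, 2010, seed=42)
host = cr.simulate_host_mask(grid, seed=42)
surv = cr.survival_grid([cr.annual_ltdd_grid(grid, y) for y in range(2006, 2011)], best)
ow = cr.classify_overwintering(surv, host, lats=grid.lats, lons=grid.lons)
n5, a5 = cr.overwinter_area(ow, 0.05)
print(f"overwintering >=5%: {n5} cells, {a5/1e6:.2f} Mkm2")
```

prints

```
LTDD         exponential  AIC=  -1371.9  R2=0.985
LTDD         sigmoid      AIC=  -1370.8  R2=0.985
DTmean_days  sigmoid      AIC=  -1230.0  R2=0.972
coefficients: {'a': 0.89357, 'b': -0.00491}
field validation: slope=0.993  R2=0.963  n=470
overwintering >=5%: 53 cells, 0.64 Mkm2
```

Reading the output: the exponential-LTDD model wins the AIC ranking and
recovers the generating law (truth a = 0.9, b = −0.005) — survival is
~89% with no cold load and halves every ~141 °C·day of accumulated
chill. Predictions on independent noisy field data fall on the 1:1 line
(slope 0.993) explaining 96% of variance, and projecting the model onto
the synthetic climate grid yields a 0.64 million-km² overwintering
range at the ≥5% survival cutoff. A +2 °C scenario
(`cr.warming_scenario(grid, 2.0)`) expands it to 0.67 million km².

The same flow from the shell:

```sh
coldrange run --seed 42 --out demo_run     # full pipeline + manifest
coldrange simulate --seed 1 --out fixtures # write input fixtures only
coldrange fit fixtures/lab_observations.csv
```

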