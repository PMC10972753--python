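# heatfootprint

Socioeconomic disaster footprints of extreme heat: from gridded daily
temperature and humidity to heatwave mortality, labour-capacity losses and
the indirect economic losses that cascade through global supply chains.

Heat stress hurts economies through three channels. People die in
heatwaves; workers slow down or stop when wet bulb globe temperature
(WBGT) rises; and both effects ripple outward, because a mine or farm that
cannot produce starves its downstream buyers of inputs and its upstream
suppliers of orders. `heatfootprint` implements this full chain as a
composable pipeline for scenario analysis on synthetic (or user-supplied)
inputs:

1. **Heat exposure** (`heatfootprint.exposure`) — simplified WBGT from air
   temperature T_a (°C) and relative humidity RH (%):

   ```
   WBGT_outdoor = 0.567·T_a + 3.94 + 0.393·E
   E            = RH/100 · 6.105 · exp(17.27·T_a / (237.7 + T_a))
   WBGT_indoor  = WBGT_outdoor − 4
   ```

   plus heatwave detection: ≥ 2 consecutive days with daily mean
   temperature strictly above a per-cell 95th-percentile baseline
   threshold (static, expanding-window dynamic, and a stricter
   97.5 % / ≥ 4-day sensitivity variant).

2. **Health losses** (`heatfootprint.health`) — excess deaths per cell-year
   `D_hw = POP · MR · (RR − 1) · HWN`, with climate-zone relative risks RR
   and heatwave-day counts HWN, monetized by a value of statistical life
   anchored at US$11 million and scaled across regions by income with unit
   elasticity (an equal-valuation mode is included).

3. **Labour losses** (`heatfootprint.labour`) — exposure–response curves per
   work-intensity class (200/300/400 W): the benchmark error-function curve
   `loss = ½(1 + erf((WBGT − Prod_mean)/(Prod_SD·√2)))` and the Hothaps
   logistic workability curve `0.1 + 0.9/(1 + (WBGT/α₁)^α₂)` as a
   sensitivity alternative; the 4+4+4 daily averaging over WBGT_max,
   WBGT_mean and their midpoint; air-conditioning protection rising with
   income; and population-weighted aggregation to daily unavailable labour
   shares γ^L(t) per region–sector, inside each hemisphere's warm season.

4. **Supply-chain propagation** (`heatfootprint.ario`) — an adaptive
   input–output simulator calibrated from a balanced multiregional
   input–output (MRIO) table: Leontief production constrained by labour,
   capital and input inventories; proportional rationing of scarce output;
   inventory-gap reordering with capacity-weighted supplier substitution.
   Losses are time-integrated value-added shortfalls:

   ```
   TEF = va̅·T − Σ_t va^a(t)      total economic footprint
   DEF = va̅·T − Σ_t va^max(t)    direct footprint (capacity limits)
   PEF = TEF − DEF                propagated (indirect) footprint
   ```

5. **Synthetic inputs** (`heatfootprint.synthetic`) — seasonal AR(1) climate
   with a secular warming trend, clustered population grids with region
   tables, and balanced MRIO tables (iterative proportional fitting), so the
   whole pipeline runs with no downloads and no licensed data.

## Worked example

```python
from heatfootprint import pipeline

report = pipeline.run_pipeline(
    pipeline.PipelineConfig(scenario="high", seed=1)
)
print(report.table[["health_pct_gdp", "direct_pct_gdp",
                    "indirect_pct_gdp", "total_pct_gdp"]].round(3))
```

```
        health_pct_gdp  direct_pct_gdp  indirect_pct_gdp  total_pct_gdp
region
R00              0.341          15.003             5.656         20.999
R01              0.196          10.391             6.336         16.923
R02              0.290           6.788             6.373         13.451
R03              2.107           8.869             6.566         17.542
WORLD            0.582           9.871             6.213         16.666
```

One synthetic world (four regions, four sectors, a hot climate under the
strongest warming scenario), one analysis year. Each row decomposes that
region's loss into monetized heatwave mortality (`health`), the value
added lost to heat-constrained labour capacity (`direct` = DEF) and the
loss propagated through supplier–client links (`indirect` = PEF), all as
percentages of the region's baseline GDP (annual value added of the
calibrated MRIO). The world row is the GDP-weighted aggregate; this run
also attributes about 363 heatwave deaths to the analysis year.

The headline mechanism — indirect losses gaining weight as heat stress
intensifies — can be reproduced on the packaged 5-region × 4-sector world:

```python
print(pipeline.demo_amplification(seed=0).round(4))
```

```
                TEF       DEF      PEF  indirect_share
magnitude
0.05        35.0883   27.6475   7.4408          0.2121
0.10        70.1949   55.2950  14.8999          0.2123
0.20       140.5054  110.5900  29.9154          0.2129
0.40       281.6262  221.1801  60.4461          0.2146
```

The indirect share PEF/TEF rises with the peak magnitude of the seasonal
labour shock.

## Command line

```bash
heatfootprint generate --kind climate --scenario high --seed 1 --out climate.nc
heatfootprint exposure --climate climate.nc --definition static --out hwn.nc
heatfootprint simulate --mrio mrio_dir/ --shocks shocks.csv --out results/
heatfootprint run --scenario mid --seed 0 --out run_out/
heatfootprint montecarlo --scenario mid --reps 5 --out mc_out/
```

`run` writes every intermediate artefact (climate and population grids,
MRIO CSVs, daily γ^L series, per-firm footprints, the loss report and a
manifest with seeds and a config hash), so any stage can be re-run from its
persisted inputs.

## Scope

Model parameters that are epidemiological or ergonomic estimates (zone
relative risks, exposure-curve means/SDs) ship as clearly labelled
illustrative defaults and are meant to be overridden from configuration
for real analyses. The package does not ingest CMIP/ERA5 archives or GTAP
databases, and has no price dynamics or capital-reconstruction module; see
`docs/methods.md` for the full model description, assumptions and
limitations.
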