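# Methods

`heatfootprint` couples four models — synthetic climate, heatwave
epidemiology, WBGT labour exposure, and an adaptive input–output (IO)
supply-chain simulator — into a single loss-accounting pipeline. This note
documents each model, its parameters and units, the numerical choices, and
what the synthetic data do and do not establish.

## Synthetic climate

Daily mean temperature in cell (i, j) on day t is

    T(t) = base_temp + A·cos(2π(doy − peak)/365) + a(t) + w·years/10

with seasonal amplitude `A` (°C, default 8), hemisphere-dependent phase
(peak at mid-July north of the equator, mid-January south of it), an AR(1)
anomaly `a(t) = ρ·a(t−1) + ε(t)` with innovation SD `noise_sd` (°C,
default 2) and persistence `ar1_rho` (default 0.7, a typical daily
temperature-anomaly decorrelation), and a linear warming trend `w` in °C
per decade. Daily maximum temperature is `tmean + diurnal_range` (default
6 °C). Relative humidity is `rh_mean + rh_temp_coupling·a(t)` clipped to
[0, 100]; the default coupling of −1.5 %/°C makes hot anomalies drier,
which is the common mid-latitude pattern. Nothing beyond this co-variation
structure is claimed: there is no bias correction, no spatial anomaly
correlation, no humidity seasonality.

The calendar is 365-day no-leap (Feb 29 dropped). This makes a noise-free,
trend-free climate repeat exactly year over year and keeps annual
aggregation shapes regular; at the scales involved the bias of dropping
leap days is negligible.

Scenario labels are deliberately neutral — `low`, `mid`, `high` map to
0.1, 0.3, 0.6 °C/decade, spanning roughly the range from strong mitigation
to unconstrained emissions over mid-century — rather than claiming
fidelity to any specific forcing pathway.

## Heat exposure

WBGT uses the two-parameter simplification from temperature and humidity
(solar radiation and wind dropped — their global-scale effect is small and
uncertain); indoor WBGT subtracts a fixed 4 °C radiation term. The daily
triplet (WBGT at `tmax`, at `tmean`, and their midpoint) reuses the same
daily RH for all three, since the generator produces one RH value per day.

Heatwaves: a cell-day is a heatwave day iff it belongs to a run of at
least `min_run` consecutive days with daily mean temperature **strictly**
above the cell's threshold (ties are not exceedances — the threshold must
be *exceeded*). The benchmark threshold is the empirical 95th percentile
of all baseline-window days, computed with linear interpolation between
order statistics (the numpy default, pinned for reproducibility). The
dynamic variant recomputes the percentile per target year over the
expanding window from the history start through the year before the
target year — a crude acclimatisation proxy — and never uses the target
year's own data. The sensitivity preset uses the 97.5th percentile with
≥ 4-day runs. Runs crossing year boundaries contribute each day to its own
calendar year, keeping annual heatwave-day counts (HWN) additive.

Note a structural property: an empirical percentile threshold leaves
~(100−q)% of baseline-distribution days above it in *any* stationary
climate, so HWN is never exactly zero even without warming; a stationary
run produces a small climatological health loss, not a zero one.

## Health losses

Excess deaths per cell-year: `D_hw = POP · MR · (RR − 1) · HWN`, with POP
the cell population, MR the baseline daily all-cause mortality rate
(deaths·person⁻¹·day⁻¹; default 2.2×10⁻⁵, consistent with a crude death
rate of ~8 per 1000 per year), RR the relative risk of death on heatwave
days for the cell's climate zone, and HWN the heatwave-day count. RR ≥ 1
is enforced (heatwaves are assumed non-protective). Regional totals are
plain sums over cells, so the result is invariant to how population is
split among cells sharing MR/RR/HWN.

Climate zones are a required input; the packaged helper assigns four zones
by quartiles of baseline warm-season mean temperature — a reproducible
stand-in, overridable by file. The packaged RR values (1.05/1.07/1.10/1.14
for zones 1–4) are **illustrative placeholders**, not estimates; real
analyses must supply epidemiologically estimated RRs.

Valuation uses a value of statistical life (VSL) anchored at US$11 million
(2019) at an anchor income of $65,000/yr, scaled by
`(income/anchor_income)^elasticity` with elasticity 1.0. The
`equal_world` mode instead applies the population-weighted mean of the
income-scaled VSLs to every region; with equal incomes the two modes
coincide. A single configurable deflator covers price-year conversion.

## Labour losses

Two exposure–response curves map WBGT to the lost share of work capacity
for a metabolic intensity class:

* benchmark (erf): `loss = ½(1 + erf((WBGT − Prod_mean)/(Prod_SD·√2)))` —
  the Gaussian CDF at (Prod_mean, Prod_SD);
* Hothaps (sensitivity): `workability = 0.1 + 0.9/(1 + (WBGT/α₁)^α₂)`,
  `loss = 1 − workability`, bounded in [0, 0.9).

Classes: 200 W (office/services, indoor), 300 W (industry, indoor), 400 W
(construction and agriculture, outdoor). The packaged Hothaps α values are
the published Hothaps-programme fits (α₁ = 34.64/32.93/30.94,
α₂ = 22.72/17.81/16.64); the erf Prod_mean/SD defaults (34/32/30 ± 2 °C)
are round placeholders of the right order, to be replaced with
population-appropriate estimates.

Daily impact uses the 4+4+4 rule: the unweighted mean of the loss at
WBGT_max, WBGT_mean and their midpoint, each standing for 4 h of a fixed
12 h workday (no latitude-dependent day length). Indoor classes evaluate
the indoor-shifted WBGT.

Air-conditioning protection applies only to indoor workers:
`effective_loss = (1 − penetration)·loss`. Penetration is
`saturation(climatology) · logistic(slope·(log income − log midpoint))`:
the income term is a logistic in log income (midpoint $15,000/yr, slope
1.5 — penetration roughly 18 %→82 % across one decade of income around the
midpoint), and the saturation term is a logistic in the indoor-WBGT
warm-season climatology (midpoint 18 °C-WBGT, slope 0.35/°C) rising toward
`max_penetration` in hot climates. The functional form is a stand-in —
nondecreasing in both arguments and bounded in [0, 1] — chosen because the
source form for a climate–income–AC-usage function on a WBGT basis is not
available; treat its parameters as scenario knobs.

Aggregation: γ^L_{r,s}(t) is the population-weighted mean over region r's
cells of the effective daily loss for sector s's intensity class, inside
the warm-season window — June 1 to September 30 north of the equator,
December 1 to March 30 south of it — and zero outside. Cells within 1° of
the equator follow the northern window (a documented convention;
configurable by latitude). Heatwave mortality is *not* fed back into γ^L:
the health and labour channels are deliberately separate.

## Supply-chain simulator

Firms are (region, sector) pairs; each region has one representative
household; product classes coincide with sectors, so a client can buy the
same product from suppliers in different regions. Calibration from a
balanced MRIO table (row balance x_i = ΣZ_ij + ΣF_ih, column balance
x_i = ΣZ_pi + va_i, residuals under 1e-6 required) yields input
coefficients a_i^p = z̄_i^p/x̄_i, value-added coefficients b_i = v̄a_i/x̄_i
(Σ_p a_i^p + b_i = 1 exactly), per-step baselines (annual flows divided by
`steps_per_year`, so v̄a·T over a one-year horizon equals annual value
added), and initial inventories S_i^p = n·a_i^p·x̄_i for an inventory
target of n steps of cover (default 15; scannable over [10, 90] in Monte
Carlo).

Each step runs produce → allocate → restore → order:

1. **Produce.** Capacity x^max = min(x^L, x^K, min_p S^p/a^p), with
   x^L = (1−γ^L)x̄ and x^K = (1−γ^K)x̄; products with a^p = 0 impose no
   constraint. Actual production x^a = min(x^max, total orders received
   last step). An overproduction factor ≥ 1 can scale x^max, but with
   exogenously fixed household demand values above 1 let the unshocked
   economy overproduce (value-added "gains" that make loss accounting
   ill-defined), so the default is 1.
2. **Allocate.** Proportional rationing: each supplier fills firm and
   household orders pro rata; allocations sum exactly to x^a; zero total
   orders yield zero allocations (no division by zero).
3. **Restore.** Inventories: S(t) = S(t−1) − a·x^a + receipts, receipts
   pooled by the supplier's product class. Deliveries arriving at step t
   are usable from step t+1 (production draws on end-of-previous-step
   stock).
4. **Order.** Target stock S* = n·a·x^max(t). The per-product order total
   is max(S* − S, 0) evaluated at the **post-production, pre-delivery**
   stock position, split across that product's suppliers in proportion to
   baseline flow × (supplier capacity utilisation x^a/x̄)^θ, renormalised;
   if all candidate suppliers are at zero capacity, baseline shares are
   used; suppliers with zero baseline flow never receive orders.
   Households split their exogenous demand (default: the calibrated
   baseline) the same way. θ is the substitution exponent: 0 freezes
   baseline shares (no substitution, the static-IO bound), 1 is the
   default capacity-weighted reallocation, larger values substitute more
   aggressively. Unfilled household demand is simply unmet; there is no
   backlog carry-over.

Two timing/normalisation choices matter and were made so that the
unshocked economy is an **exact fixed point** (drift ~1e-13 relative over
100 steps, verified in tests): (a) orders are placed against the
pre-delivery stock, which makes the order gap equal each step's own
consumption at equilibrium; (b) the substitution weight uses capacity
*utilisation* x^a/x̄ rather than absolute capacity, which reduces to
baseline shares when all suppliers are at baseline. With absolute-capacity
weights or post-delivery gaps the equilibrium degenerates (orders collapse
or shares drift), which no calibrated-benchmark simulation can tolerate.

Loss accounting: va^a(t) = b·x^a(t), va^max(t) = b·x^max(t);
TEF = v̄a·T − Σva^a, DEF = v̄a·T − Σva^max, PEF = TEF − DEF. With
overproduction 1 and shocks in [0, 1], x^a ≤ x^max ≤ x̄ for every firm and
step, hence TEF ≥ DEF ≥ 0 and PEF ≥ 0 identically. Defining va^max from
exogenous capacity only (b·min(x^L, x^K)) was considered and measured: in
every scenario run the two definitions coincide, because gap-driven
reordering and proportional rationing redistribute scarce products to
where they bind, so inventory constraints do not bite below labour/capital
capacity; the simpler definition via x^max is kept.

### Shock-shape sensitivity and the amplification property

The indirect share PEF/TEF behaves very differently under square-pulse and
seasonal shocks. A square pulse (γ jumping instantly to m) triggers a
destocking wave — S* = n·a·x^max drops abruptly, and the order gap clips
at zero once m ≥ 1/(n+1) — whose contribution to PEF *saturates* in m, so
the indirect share falls as the pulse grows. Heat-stress labour shocks are
not square pulses: γ^L waxes and wanes with the seasonal WBGT cycle. The
packaged demonstration scenario (`pipeline.demo_shock`) therefore applies
a smooth sin² envelope over a 90-step warm season, with regionally
heterogeneous intensity (weights 1.0 down to 0.2 from the hottest to the
coolest of five regions) and peak magnitude m. Under that shape the
destocking artifact vanishes and the indirect share is nondecreasing in m
(0.2121 → 0.2146 over m ∈ {0.05, 0.1, 0.2, 0.4} on the default seed),
reproducing the qualitative amplification of indirect losses with heat
severity. The effect is deliberately reported as qualitative: its
magnitude depends on network density, inventory cover and the substitution
exponent.

## Pipeline and Monte Carlo

`run_pipeline` generates one scenario's climate, population and MRIO (the
MRIO is rescaled so total value added equals the population's aggregate
income — the only way VSL-based health losses and value-added production
losses share a monetary scale), detects heatwaves in the analysis year
against the configured baseline, computes deaths, VSL values and γ^L
series, propagates the labour shocks over a 365-step horizon, and reports
the additive decomposition per region and world: total = health + DEF
+ PEF, with percentage shares against the same baseline GDP (annual value
added of the calibrated table). All stages are deterministic given the
config seeds; artefacts and a manifest (config hash, seeds) are persisted
when an output directory is given.

`monte_carlo` replicates the pipeline with the inventory target drawn from
[10, 90] steps, the substitution exponent from [0, 1], and optionally
reseeded climate, reporting mean and 1 s.d. per quantity. Degenerate
ranges with a fixed seed reproduce a single deterministic replicate.

Default problem sizes — 6×8 grid cells, 4 regions × 4 sectors, 13
simulated years, one analysis year at daily resolution — keep a full
scenario run around a second while exercising every code path;
all sizes scale via configuration.

## What the synthetic data do not show

The generators reproduce the *statistical structure* the method assumes
(seasonality, autocorrelated anomalies, warming trends, balanced IO
accounts, heterogeneous population and income), not any real geography,
climatology or trade network. Passing tests therefore establish the
correctness and internal consistency of the computations — formulas,
detection rules, conservation laws, equilibrium calibration, loss
decomposition — and the direction of scenario contrasts, but no
quantitative statement about real-world losses. Known limitations shared
with the modelling tradition: constant purchaser prices (no price
dynamics), no capital reconstruction, no labour–capital substitution, no
age- or humidity-stratified mortality risk, exogenous household demand,
and a static trade structure over the horizon.
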