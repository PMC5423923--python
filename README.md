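# democonv

Analysis pipeline for **regional convergence in population aging**.  Given
long-format regional panels of population counts by single year of age
(plus deaths and, optionally, net migration), the package

1. computes the **total support ratio** (TSR) — persons aged 15–64 per
   person below 15 or 65 and over, the inverse of the total dependency
   ratio;
2. decomposes the change in TSR over any interval into additive effects of
   the **non-working-age** (`nw`) and **working-age** (`w`) populations
   (symmetric two-factor decomposition of a ratio), and splits the
   working-age effect further into **cohort turnover** (`ct`),
   **migration at working ages** (`mg`) and **mortality at working ages**
   (`mt`) via the demographic balance `W2 = W1 + CT + M_W − D_W`, deriving
   either net migration (*observed* mode) or deaths (*projected* mode) as
   the balance residual;
3. estimates **beta convergence** — OLS of the TSR change on its initial
   level — and exploits OLS linearity to decompose the beta coefficient
   additively by demographic component and by time (yearly betas within a
   decade sum exactly to the decade's pooled beta; cumulative curves track
   the convergence process);
4. ships a **cohort-component simulator** that generates multi-region
   synthetic panels with the statistical structure the analysis assumes:
   labeled clusters (e.g. `east`/`west`/`south`/`north`), cluster-specific
   working-age mortality gaps, demographic waves (boom and bust cohorts),
   observed-period migration shocks and a projected regime with
   variance-shrinking convergent migration.

## Command-line usage

The console script `democonv` exposes the pipeline stages:

```bash
# full pipeline on the shipped default scenario
democonv run --config src/democonv/data/default_scenario.toml --seed 42 --out out/

# individual stages
democonv simulate  --config scenario.toml --seed 1 --out data/
democonv tsr       --population data/population.csv --bounds 15:65 --out tsr.csv
democonv decompose --population data/population.csv --deaths data/deaths.csv \
                   --mode observed --period 2003:2013 --out components.csv
democonv converge  --components components.csv --tsr tsr.csv \
                   --decades 2003:2013,2013:2023 --out conv/
democonv fixture   stationary --out fixtures/
```

`run` writes `population/deaths/migration.csv`, `tsr.csv`,
`components.csv`, `betas.csv`, `betas_cumulative.csv`, a stage log and a
`manifest.json` (config hash, seed, package version).  Reruns with the
same config and seed are byte-identical.

## File formats

All interchange is CSV with frozen schemas, validated on read:

| file | columns |
|---|---|
| population.csv | `region[,cluster],year,age,count` — January-1 stocks, completed age 0..open_age |
| deaths.csv | `region,year,age,deaths` — flows over `[year, year+1)` |
| migration.csv | `region,year,age,net_migration` |
| tsr.csv | `region,year,W,NW,tsr` |
| components.csv | `region[,cluster],period_start,period_end,mode,tsr1,tsr2,g,nw,w,ct,mg,mt,CT,M_W,D_W` |
| betas.csv | `component,period_start,period_end,regressor_year,alpha,beta,se_beta,r2,n_regions` |
| betas_cumulative.csv | `component,year,regressor_year,cumulative_beta` |

Flow panels record the age a cohort *attains* during the interval (the
cohort aged `a` on January 1 appears under age `a+1`; the open age group
pools its events).  Under this convention the demographic balance
`P(t+1, a) = P(t, a−1) − D(t, a) + M(t, a)` closes exactly on simulator
output, and flow sums over ages `[15, 65)` line up exactly with the change
in the working-age stock.

## Scenario configuration

Scenarios are declarative TOML (see
`src/democonv/data/default_scenario.toml`): a `[scenario]` block
(years, region count, open age, seed) plus one `[[cluster]]` block per
cluster with mortality/fertility/migration schedules — inline
piecewise-linear `points`, `constant`, `gompertz` or `gaussian` forms —
wave multipliers by birth-cohort window, a migration shock
(`shock_year`/`shock_delta`) and a projected-regime `convergence_rate`.

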