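# tcscea

A Markov cohort cost-utility model comparing transitional care services
(TCS) with usual care for older COPD inpatients, from the healthcare-system
perspective. The model tracks six post-discharge medical-use states
(stable management, no management, readmission for COPD / other
respiratory disease / other disease, and death) over a 10-year horizon in
3-month cycles, for cohorts starting at ages 60, 70 and 80. It produces
baseline incremental cost-utility results, one-way deterministic
sensitivity analysis with tornado ordering, and probabilistic sensitivity
analysis with cost-effectiveness acceptability curves.

The canonical input tables (transition-state counts, relative risks,
per-state costs, the itemized intervention cost, utilities, mortality
ratios and economic constants) ship with the package as plain CSV/JSON
under `src/tcscea/data/paper_params/`. The two external data sources the
original analysis relied on — a national complete life table and
patient-level claims — are replaced by a synthetic generator module, so
the whole pipeline runs offline.

## Layout

| module             | contents                                                            |
| ------------------ | ------------------------------------------------------------------- |
| `parameters`       | typed inputs, file I/O, cost arithmetic (sums, shares, conversion)  |
| `synthetic_data`   | Gompertz–Makeham life tables; categorical 90-day outcome simulator  |
| `transition_model` | relative-risk adjustment, period/cycle conversions, cycle matrices  |
| `cohort_engine`    | 40-cycle cohort trace; discounted, half-cycle-corrected accumulation|
| `economics`        | incremental cost/QALYs, ICUR with dominance label, net benefit      |
| `sensitivity`      | DSA/tornado, PSA distributions, Monte-Carlo propagation, CEAC, plots|
| `cli`              | `tcscea` command-line entry point                                   |

## CLI

```sh
tcscea baseline --out-dir out/                 # per-cohort incremental results
tcscea dsa --cohort 60s --out-dir out/         # tornado CSV + plot
tcscea psa --seed 1 --n-iter 2000 --out-dir out/   # scatter, CEAC CSVs + plots
tcscea make-lifetable --out lt.csv             # synthetic life table
tcscea simulate-claims --cohort 80s --n 1000 --seed 1 --out claims.csv
```

All commands accept `--params <dir>` to swap the bundled parameter tables
for your own and `--life-table <csv>` to supply a real mortality schedule;
stochastic commands require `--seed`. Outputs are CSV/JSON plus PNG plots,
with a `manifest.json` (seed, parameter hash, version) per run. Exit
codes: 0 success, 2 configuration error, 3 validation error.

## Notes

- Monetary unit is USD throughout (1 USD = 1,301.50 KRW for the two
  conversions the tables require); presentation rounding is half-up.
- The bundled default life table is synthetic. Baseline deltas therefore
  differ from any specific national setting; the structural findings
  (intervention dominance, effect gain increasing with age) are stable
  across valid life tables and are what the acceptance tests assert.
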