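# fluxseason

Analysis toolkit for collar-based soil respiration campaigns in seasonal
(dry/wet monsoon) forests. It covers the full chain from raw collar tables to
an annual carbon budget:

* **Synthetic campaigns** — a seeded generator for daily climate, soil
  microclimate, collar-level flux measurements, and per-season soil
  chemistry, with a four-stand default truth set, so every downstream stage
  is testable without field data.
* **Response models** — linear moisture (`rs = m + nW`), exponential
  temperature (`rs = a·e^{bT}`), and bivariate (`rs = a·e^{bT}·W^c`) fits by
  nonlinear least squares (log-linear initialized) or log-linear OLS, with
  temperature sensitivity `Q10 = e^{10b}`.
* **Annual upscaling** — monthly soil↔air temperature calibration, daily
  soil temperature prediction, integration to gC m⁻² a⁻¹
  (`a·e^{bT}·86400·12·10⁻⁶` per day), and a collar-resampling bootstrap CI.
* **Environmental statistics** — dry/wet seasonal summaries, wet:dry ratios,
  Pearson screens of respiration against ten environmental factors, one-way
  ANOVA with LSD compact-letter displays, and random-forest permutation
  importance with a response-permutation (max-statistic) significance test.

## CLI

A single entry point with chained subcommands:

```sh
fluxseason simulate --seed 7 --out data/            # CSVs + truth.json
fluxseason fit --in data/measurements.csv --out fits.json
fluxseason upscale --measurements data/measurements.csv \
    --climate data/climate_daily.csv --boot 1000 --out flux.json
fluxseason seasonal --in data/measurements.csv --out seasonal.json
fluxseason correlate --measurements data/measurements.csv \
    --chemistry data/chemistry.csv --climate data/climate_daily.csv --out corr.json
fluxseason importance --measurements data/measurements.csv \
    --chemistry data/chemistry.csv --climate data/climate_daily.csv --out imp.json
fluxseason run --simulate --seed 7 --out results/   # full pipeline + report.md
fluxseason reproduce-table4 --measurements data/measurements.csv \
    --climate data/climate_daily.csv --out table.md
```

`run` writes `fits.json`, `flux.json`, `seasonal.json`, `correlations.json`,
`importance.json`, and a Markdown report; every JSON embeds the seed and a
hash of the run configuration. Reruns with the same configuration are
byte-identical. Seasons are fixed at dry = November–April,
wet = May–October.

## Library example

```python
from fluxseason import generate_study, fit_temperature_exponential

bundle = generate_study(seed=7)
ca = bundle.measurements.query("stand_id == 'CA'")
fit = fit_temperature_exponential(ca)
print(fit.b, fit.q10, fit.r2)
```
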