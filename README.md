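# vpdgrowth

A tested pipeline linking boreal tree growth to atmospheric vapour
pressure deficit (VPD): from daily site weather and ring-width series to
site-level VPD-sensitivity t-values, random-forest driver attribution,
and autocorrelation-corrected growth-change and trend statistics.
Everything runs end-to-end on synthetic data with known ground truth —
no external datasets are required.

## What's inside

| module | role |
| --- | --- |
| `vpdgrowth.synthgen` | coupled daily-weather + tree-ring simulator with known generative parameters (log-BAI recursion with prior-BA elasticity, age curve, current/prior summer VPD effects, tree random intercepts, AR1 noise); writes text fixture bundles (rwl + CSV + JSON) |
| `vpdgrowth.climate` | daily VPD (Tetens saturation pressure, RH- or Kimball-dewpoint actual pressure), simplified Penman-Monteith PET, quadratic-plus-linear soil-moisture index (300/400 mm), JJA summaries, 1°x1° grid assignment, MAT/MAP climatologies |
| `vpdgrowth.rings` | Tucson/rwl reader-writer (0.01 and 0.001 mm dialects), long-CSV alternative, width→basal-area-increment conversion, juvenile-ring filter, site structure summaries |
| `vpdgrowth.growth_model` | the site-species growth model: log-BAI on log prior BA + penalized cubic-spline age smooth + summer VPD terms, tree random intercepts, AR1 residuals; REML (default) or GCV smoothness selection; Wald t-tests, response classification, partial-SMI variant |
| `vpdgrowth.drivers` | 500-tree bagged regression forest over seven site predictors with unscaled OOB permutation importance, average minimal depth, root-node counts and partial dependence |
| `vpdgrowth.trends` | species-level age/size detrending, percent growth change with Moran's-I effective sample sizes, effective-n trend tests, stationary-block-bootstrap correlation CIs, IDW interpolation |
| `vpdgrowth.pipeline` | orchestration + manifest (seeds, timings, attrition and significance counts) behind a `click` CLI |

## CLI

```bash
vpdgrowth run-all --seed 1 --out run1          # synthetic end-to-end run
vpdgrowth report run1                          # machine+human readable summary
vpdgrowth simulate --seed 2 --out fixtures     # write a fixture bundle
vpdgrowth climate weather.csv sites.csv        # site-year VPD/SMI summaries
vpdgrowth rings rings.rwl --out bai.csv        # filtered BAI table
```

Configuration is YAML (see `vpdgrowth.pipeline.PipelineConfig` for keys);
every module default — SMI capacities, summer months, spline basis size,
forest settings, bootstrap sizes, the full simulation block — is
overridable there and nowhere else.

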