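# infoseason

Cosinor-based seasonality analysis for monthly search-interest time series.

Public interest in a disease, tracked through relative search volume (the
0–100 index that Google Trends exports per query and region), often follows
the disease's clinical seasonality. `infoseason` turns panels of such
monthly series into quantitative seasonality calls: it fits harmonic
regression (cosinor) models to multi-year monthly data, tests whether the
seasonal amplitude is real, decides between one and two seasonal peaks per
year, controls for the multiplicity of testing dozens of locations at once,
and asks whether seasonal amplitude strengthens with latitude. A seeded
synthetic-panel generator reproduces the statistical structure of real
exports (0–100 max-anchored scaling, integer rounding, autocorrelated
noise, hemisphere-opposed peaks), so the entire pipeline is testable and
demonstrable without live data.

Intended users: epidemiologists and infodemiology researchers analyzing
search-interest seasonality, and anyone needing a tested cosinor /
harmonic-selection / FDR stack for monthly climatology data.

## The model

Each location's multi-year series is averaged by calendar month into a
12-point climatology and fitted with the cosinor model

    y(t) = M + A·sin(2πt/12 + θ),   t = 0 (January) … 11 (December)

by exact linearization: OLS on the sine/cosine basis gives `M`,
`β₁, β₂`, and `A = √(β₁²+β₂²)`. The **mesor** `M` is the midline level, the
**amplitude** `A` is half the seasonal peak-to-trough swing, and the
**acrophase** φ (reported as `2π·t_peak/12`, so φ = π/2 ⇔ an April peak)
locates the peak within the year. Significance comes from a two-tailed
t-test on the amplitude (delta-method SE) and from the exact
F-test of both harmonic coefficients, the default flag.

A nested bimodal model adds a 6-month harmonic (two peaks per year).
Preference is summarized by

    ΔBIC = BIC_uni − BIC_bi,  BIC = k·ln n + 2·ln SSE   (k = 3 / 5)
    ΔAIC = AIC_uni − AIC_bi,  AIC = 2k + 2·ln SSE

with ΔBIC ≥ 6 moderate / ≥ 10 strong evidence for bimodality (ΔAIC > 4 /
> 10); comparisons where neither model is significant carry the sentinel
−999. Grouped p-values get three corrections side by side: within-group
Benjamini–Hochberg FDR, pooled FDR across all tests, and Bonferroni capped
at 1. The latitude–amplitude gradient is quantified by an OLS slope with
95% CI, Pearson r (Fisher-z CI) and Spearman ρ.

## Worked example

```bash
python examples/bimodal_model_selection.py
```

```
unimodal term: dBIC =   -3.92 (negligible)  dAIC =   -2.95 (negligible)  6-month term p = 1.59e-01
bimodal term : dBIC =    8.90 (moderate  )  dAIC =    9.87 (moderate  )  6-month term p = 2.87e-11
```

The unimodal term's negative ΔBIC says the extra 6-month harmonic is pure
parameter cost; the planted-bimodal term clears the ΔBIC ≥ 6 moderate
threshold and its semiannual coefficients are individually significant.

```bash
python examples/multiple_testing_summary.py
```

```
             group  n  sig_raw  sig_within_fdr  sig_pooled_fdr  sig_bonferroni
 countries_english 70       37              37              37              36
countries_language 20       10              10              10              10
         na_cities 36       33              33              33              33
          symptoms 21       17              17              17              17
         us_states 50       46              46              46              46

pooled tests: 197
```

Five subgroups (70+20+50+36+21 = 197 tests); counts can only shrink from
raw to Bonferroni, and here one borderline country drops out under the
strictest correction. The other examples (`fit_single_series.py`,
`latitude_gradient.py`, `full_pipeline.py`) demonstrate single-series
fitting, the latitude gradient, and the full CSV-emitting pipeline; a thin
CLI (`infoseason simulate|fit|compare|correct|geo|run-all`) wraps the same
functions for shell use.

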