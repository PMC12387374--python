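# Methods

## Data model

The unit of analysis is one location's (or query's) monthly relative search
volume: an integer series on a 0–100 scale in which 100 marks that series'
own maximum over the window, so levels are comparable within a series but
not across separately normalized series. Exports may contain the literal
`"<1"` for months with too little traffic; the parser maps these to 0.5 —
the midpoint of the censoring interval — and flags them, since mapping to 0
would erase "present but low". The censoring constant is configurable
because the correct substitute is not knowable from the export. Missing
months are hard errors rather than imputed: the analysis presumes a
complete 132-month record, and a gap usually indicates a failed download
rather than true missingness.

Fitting operates by default on the 12-point climatology (the calendar-month
means over all years), which is the natural target when the question is
"what does the average year look like"; a config switch (`fit_on: full`)
fits the raw monthly series instead. Month indices are 0-based with
January = 0 internally; every user-facing peak month is a 1-based calendar
month.

## Cosinor model and phase conventions

The unimodal model `y = M + A·sin(2πt/12 + θ)` is linear in the sin/cos
basis and is fitted by exact OLS — no iterative optimization, identical
optimum, fully reproducible. Two phase conventions are stored. The internal
regression phase θ is the argument shift of the fitted sinusoid. The
reported acrophase is calendar-anchored: φ = 2π·t\*/12, where
t\* = (3 − 6θ/π) mod 12 is the month at which the fitted curve peaks, so
φ = π/2 means an April peak. This anchoring was chosen because the naive
reading of the model equation (φ = π/2 peaking at t = 0, January, when t
counts months from January) contradicts the standard worked interpretation
that π/2 corresponds to April; the calendar-anchored convention makes that
interpretation exact, and the raw θ remains available. The peak month is
`floor(t*) + 1` after snapping t\* to a 1e-9 grid, so a peak at an exact
month boundary is not pushed into the previous month by floating-point
error. A zero-amplitude fit has no defined peak and reports it as missing.

Two significance numbers are always computed:

* the **amplitude t-test** — delta-method SE of `A = √(β₁²+β₂²)` from the
  OLS coefficient covariance, two-tailed t with n−3 df;
* the **seasonality F-test** — exact F of β₁ = β₂ = 0 with (2, n−3) df.

The F-test is the default significance flag throughout the pipeline because
the amplitude's sampling distribution is folded at the A = 0 boundary,
making the t-test anti-conservative under the null (the suite verifies this
empirically); the t-test remains selectable (`significance: amplitude_t`).
A zero-residual fit (possible with noiseless synthetic input) is flagged
`perfect_fit` and reported as p = 0.

## Bimodal extension and model selection

The bimodal model adds `sin(2πt/6)`, `cos(2πt/6)` (k = 5). The semiannual
term is tested with the exact nested F-test (2, n−5 df); across many terms
those p-values are Benjamini–Hochberg adjusted. Model preference uses

    BIC = k·ln n + 2·ln SSE,   AIC = 2k + 2·ln SSE,
    ΔBIC = BIC_uni − BIC_bi,   ΔAIC = AIC_uni − AIC_bi,

with ΔBIC ≥ 6 moderate and ≥ 10 strong (inclusive), ΔAIC > 4 moderate and
> 10 strong (exclusive, per the stated wording of those thresholds). These
criterion forms penalize ln SSE directly; they are not the Gaussian
log-likelihood forms (`n·ln(SSE/n) + …`), whose fit term scales with n. The
sign of the `2·ln SSE` term is the one under which a better-fitting model
has the lower criterion — the only orientation under which the published
interpretive thresholds (positive deltas favoring the richer model) are
attainable at all, since for nested fits SSE_bi ≤ SSE_uni. The conventional
Gaussian forms are available via `criterion_formula: gaussian`. Under the
default forms the identity `ΔAIC − ΔBIC = 2·ln n − 4` holds exactly for
every non-excluded comparison and is used as an internal consistency check.

Comparisons where neither model's seasonal component is significant
(each model's joint harmonic F-test at α) are excluded from interpretation
and marked with the sentinel −999. The joint F-test was chosen as the
exclusion gate because it is well defined for both models; whether the
semiannual term itself passed its nested test is recorded separately
(`gated`). `n` in the criterion formulas follows the fitting mode (12 for
climatologies, the full series length otherwise). Zero-residual fits cannot
be compared (ln SSE undefined); the pipeline records such comparisons as
excluded with NaN deltas.

## Multiplicity

Three corrections are applied over the pooled panel of per-location
seasonality p-values: within-group BH-FDR, pooled BH-FDR, and Bonferroni
with the multiplier equal to the pooled test count (197 when the subgroups
are 70/20/50/36/21), capped at 1. A per-group Bonferroni multiplier is
available (`bonferroni_scope: per_group`) because published analyses are
sometimes ambiguous about the family; note that one published description
of this design refers both to 197 total tests and to "156 parallel tests"
in the Bonferroni context — this package uses the pooled count of the
records it is given and surfaces that count in the run manifest.
Significance is strict `p < α` with α = 0.05 by default. BH adjustment
delegates to `statsmodels.stats.multitest` (`fdr_bh`); the test suite
checks it against a from-scratch step-up implementation.

## Latitude gradient

Amplitude is regressed on latitude by OLS (slope ± t-based 95% CI, R²);
Pearson r carries a t-test p (n−2 df) and a Fisher-z CI with variance
1/(n−3); Spearman ρ (average ranks) carries the t-approximation p and a
Fisher-z CI with variance 1.06/(n−3) — the standard approximation for the
rank correlation, used here because a ρ CI needs *some* variance model and
this is the common default. By default only locations whose fit passed the
raw significance threshold enter the scatter (`geo_only_significant`),
configurable to all locations; published figures of this kind do not always
state which choice was made. R² is exactly the square of Pearson r since
both come from the same centered cross-products.

## Synthetic generator

The generator emulates what the analysis assumes about real exports:

* latent signal `mesor + A12·sin(…12-month…) + amp6·sin(…6-month…) +
  trend·t + AR(1) noise`, with `A12 = amp12 + amp_lat_slope·|latitude|` and
  a 6-month peak shift in the southern hemisphere;
* max-anchored rescaling (series maximum → exactly 100, clipped at 0),
  matching the export's normalization rather than z-scoring, and half-up
  integer rounding reproducing the integer noise floor;
* defaults: 11 years from 2014-01, mesor 50, annual amplitude 20 (a clear
  but not extreme rhythm on the 0–100 scale), April peak, innovation sd 5,
  ar1 = 0, rescale and rounding on. ar1 defaults to 0 so the calibration
  tests run under the exact independence assumptions of the OLS inference,
  which is also what the analysis itself implicitly assumes.

Peak months are specified in calendar terms; "peaks in April" places the
latent peak at month index 3 — exactly acrophase π/2 — so noiseless series
recover their peak month exactly. With noise, an estimated peak near a
month boundary can fall on either side of it; peak-time error, not
peak-month agreement, is the meaningful recovery metric.

What the generator does **not** model: media-spike events, holidays,
between-download resampling variability of real exports, weekly/daily
granularity, or cross-query cannibalization. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative assumptions, not robustness to every artifact of real search
data.

### Scenario sizes used by tests and the acceptance script

Chosen once as realistic study conditions: null calibration uses 2,000
pure-noise climatologies (rescaling/rounding off, so the latent process is
exactly the Gaussian null of the F-test); parameter recovery uses 500
replicates at amplitude 8 vs innovation sd 2 (4× ratio); harmonic selection
uses 500 replicates with both planted amplitudes 12 vs innovation sd 1.5 —
an 8× ratio emulating strongly bimodal terms, the regime the moderate/strong
ΔBIC thresholds are meant to flag (a back-of-envelope power calculation
shows E[ΔBIC] ≈ 2·ln(SSE_uni/SSE_bi) − 2·ln 12 ≈ 5 at a 4× ratio, i.e.
genuinely below the moderate threshold: weak bimodality is *supposed* to be
classified negligible). The acceptance panel mirrors the five-subgroup
layout (70/20/50/36/21 = 197 tests) with roughly half of the country units
null and >90% of states/cities seasonal, and a city panel whose amplitude
rises 0.3 units per degree latitude.

## Numerical choices

* Rank-deficient designs (fewer than 3, resp. 5, distinct phases mod the
  period) raise errors rather than returning pseudo-inverse fits.
* SSE below 1e-10 × max(SST, 1) counts as a perfect fit.
* BH ties share an adjusted value; adjustment is order-equivariant.
* Pipeline CSVs are written with a fixed float format and sorted rows, so a
  config + seed pair reproduces outputs byte for byte; the run manifest
  records the seed and a config hash (output path excluded).
* Heatmap and polar tables min-max scale each location against its own
  range (cross-location levels are not comparable under per-series
  normalization); a flat climatology maps to 0.5 everywhere and is flagged.

## Known limitations

* OLS inference assumes independent homoscedastic errors; with ar1 > 0 the
  generator produces serial correlation that the F/t tests do not model
  (mirroring the common practice this package reproduces).
* The amplitude t-test is anti-conservative near A = 0 and is provided for
  comparability, not as the default.
* The Spearman CI variance 1.06/(n−3) is an approximation, poor below
  n ≈ 10.
* No harmonics beyond the second, no AICc, no spatial autocorrelation in
  the latitude analysis, and no modelling of Trends' between-download
  sampling noise.
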