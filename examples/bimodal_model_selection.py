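"""Decide between unimodal and bimodal seasonal shapes with dBIC / dAIC.

Two synthetic terms are analyzed: one with a single annual peak and one with
an added 6-month harmonic (two peaks per year, like weight-loss-related
queries that surge in spring and autumn).  Positive deltas favor the bimodal
model; dBIC >= 6 is moderate and >= 10 strong evidence.  A comparison where
neither model shows significant seasonality would be excluded (delta -999).
"""

from infoseason import (
    SyntheticSpec,
    compare_models,
    fit_bimodal,
    fit_cosinor,
    generate_series,
    monthly_climatology,
)

for label, amp6 in [("unimodal term", 0.0), ("bimodal term ", 12.0)]:
    spec = SyntheticSpec(amp12=12, amp6=amp6, peak_month_6=2, noise_sd=1.5,
                         rescale_0_100=False, integer_round=False, seed=3)
    clim = monthly_climatology(generate_series(spec))
    uni = fit_cosinor(clim.monthly_mean, clim.t)
    bi = fit_bimodal(clim.monthly_mean, clim.t)
    cmp_ = compare_models(uni, bi)
    print(
        f"{label}: dBIC = {cmp_.delta_bic:7.2f} ({cmp_.evidence_bic.value:10s})  "
        f"dAIC = {cmp_.delta_aic:7.2f} ({cmp_.evidence_aic.value:10s})  "
        f"6-month term p = {cmp_.p_second_harmonic:.2e}"
    )
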