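"""Grouped multiplicity corrections over a 197-test panel.

Builds a synthetic panel shaped like the analyzed study (five subgroups of
70, 20, 50, 36 and 21 units, roughly half of the country units null) and
counts significant seasonal patterns under four readings: unadjusted p,
within-group Benjamini-Hochberg FDR, pooled FDR over all 197 tests, and
Bonferroni (p x 197, capped at 1).  Counts can only shrink left to right
from raw to Bonferroni.
"""

from infoseason import PipelineConfig, run_pipeline

scenario = {
    "panels": [
        {"n_locations": 70, "group": "countries_english", "id_prefix": "ce",
         "frac_null": 0.5, "seed": 11},
        {"n_locations": 20, "group": "countries_language", "id_prefix": "cl",
         "frac_null": 0.5, "seed": 12},
        {"n_locations": 50, "group": "us_states", "id_prefix": "st",
         "frac_null": 0.08, "seed": 13},
        {"n_locations": 36, "group": "na_cities", "id_prefix": "ci",
         "frac_null": 0.08, "seed": 14},
        {"n_locations": 21, "group": "symptoms", "id_prefix": "sy",
         "frac_null": 0.2, "seed": 15},
    ]
}
result = run_pipeline(PipelineConfig(synthetic=scenario, seed=0))
print(result.group_summary.to_string(index=False))
print(f"\npooled tests: {result.manifest['n_tests']}")
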