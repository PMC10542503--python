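"""Classify hybrid expression phenotypes from the six pairwise DE calls.

Each locus's six DE indicators are matched against the class table:
DE between parents (A), novel expression in one/both hybrids (B),
parent-like expression (C), DE between the hybrids (D).  Novel loci are
annotated transgressive (outside the parental range) or intermediate,
and parent-like counts are combined into a parental-bias ratio.
"""

import pandas as pd

from orthoexpress import (
    SimulationConfig,
    classify_all,
    compute_tmm_factors,
    cpm_matrix,
    de_all_pairs,
    estimate_common_dispersion,
    novel_total,
    parent_bias_summary,
    simulate_counts,
)
from orthoexpress.phenotype import COMPARISONS

fractions = {
    "novel_sun": 0.01, "novel_lem": 0.01, "novel_both": 0.005,
    "sun_bro_like": 0.03, "sun_fru_like": 0.02,
    "lem_bro_like": 0.04, "lem_fru_like": 0.02,
    "both_bro_like": 0.02, "both_fru_like": 0.015,
}
config = SimulationConfig(n_loci=2000, seed=5, effect_size=3.0,
                          phenotype_fractions=fractions)
counts, truth = simulate_counts(config)
factors = compute_tmm_factors(counts)
dispersion = estimate_common_dispersion(counts, factors)
tables = de_all_pairs(counts, pairs=list(COMPARISONS), factors=factors,
                      dispersion=dispersion)
cpm = cpm_matrix(counts, factors)
means = pd.DataFrame({t: cpm[counts.samples_of(t)].mean(axis=1) for t in counts.taxa})
calls, class_counts = classify_all(tables, means)

print(class_counts.to_string())
print(f"novel loci in one or both hybrids: {novel_total(class_counts)}")
for hybrid in ("sun", "lem"):
    n_bro, n_fru, ratio = parent_bias_summary(class_counts, hybrid)
    print(f"{hybrid}: {n_bro} bro-like vs {n_fru} fru-like ({ratio})")
novel_modes = calls.loc[calls["primary"].isin(["novel_sun", "novel_both"]),
                        "novel_mode_sun"].value_counts()
print("novel-mode (sun):", dict(novel_modes))
# Class counts should track the configured fractions, and novel loci
# are expected to be overwhelmingly transgressive.
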