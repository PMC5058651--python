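"""Summarize SLC-family alteration, per-sample overexpression and IHC.

A family gene counts as altered when its adjusted p-value is below 0.05;
41 up + 95 down of a 300-gene family is 45.3% altered. The per-sample
fraction and the IHC high fraction use the same half-up one-decimal
rounding as the cohort tabulations.
"""

from cdc_lossmap import (
    SimConfig,
    family_alteration_summary,
    ihc_cohort_fraction,
    per_sample_up_fraction,
    simulate_de_table,
    simulate_ihc,
)

config = SimConfig(seed=3)  # 41 up / 95 down of 300 family genes
records, _ = simulate_de_table(config)
family = [f"SLCX{i + 1:03d}" for i in range(config.family_size)]
summary = family_alteration_summary(records, family)
print(f"{summary.family_name} family: {summary.n_altered} of {summary.n_family} altered "
      f"({summary.pct_altered}%), {summary.n_up} up / {summary.n_down} down")
print(f"  top up-regulated: {', '.join(summary.top_up)}")

# cystine-transporter style per-sample check: positive log2FC in 4 of 5 tumors
per_sample = {"T1": 2.1, "T2": 1.4, "T3": 3.0, "T4": 0.8, "T5": -0.5}
n_up, n_total, pct_up = per_sample_up_fraction(per_sample)
print(f"per-sample overexpression: {n_up} of {n_total} tumors ({pct_up}%)")

scores, _ = simulate_ihc(config, n_cases=15)
print(f"IHC high-expression fraction: {ihc_cohort_fraction(scores)}% of {len(scores)} cases")
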