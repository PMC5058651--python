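"""Generate a synthetic tumor/normal cohort with known ground truth.

The generator emulates the assays a collecting-duct-carcinoma study rests
on: candidate SNVs with stranded read counts, copy-number segments over
CDKN2A, per-cell FISH probe counts, a family expression table and IHC
scores — each with a truth sidecar for benchmarking.
"""

from collections import Counter

from cdc_lossmap import SimConfig, simulate_cohort

config = SimConfig(seed=42)
cohort = simulate_cohort(config)

print(f"samples: {len(config.sample_ids())}")
print(f"variant candidates: {len(cohort.variants)}")
print("  truth labels:", dict(Counter(cohort.variant_truth.variant_labels)))
print(f"segments: {len(cohort.segments)} across {len(config.cn_truth)} samples")
states = Counter(cohort.segment_truth.cn_states.values())
print("  CDKN2A truth states:", dict(states))
print(f"FISH cases: {len(cohort.fish_cases)} x {config.fish_cells} cells")
print(f"DE table: {len(cohort.de_table)} genes "
      f"({config.de_family_up} family up, {config.de_family_down} family down)")

# Every record carries exactly one truth label, so downstream stages can be
# scored for sensitivity and specificity without any external data.
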