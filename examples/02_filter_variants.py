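"""Run the somatic filter chain on simulated candidates and score it.

The chain keeps a candidate only if the alternative allele is absent in
the paired normal, significantly enriched in tumor reads (one-sided
Fisher exact), present on both strands, outside homopolymer context, and
(for indels) supported after realignment against the mutant template.
"""

from cdc_lossmap import SimConfig, simulate_variants, summarize_calls
from cdc_lossmap.somatic import filter_candidates

config = SimConfig(seed=1)  # 200 somatic at VAF 0.3, 200 germline, 100 artifacts
candidates, truth = simulate_variants(config)
verdicts = filter_candidates(candidates)

by_label = {}
for verdict, label in zip(verdicts, truth.variant_labels):
    by_label.setdefault(label, []).append(verdict.is_somatic)

for label, flags in sorted(by_label.items()):
    kept = sum(flags)
    print(f"{label:>22}: kept {kept:3d} of {len(flags):3d}")

somatic = by_label["somatic"]
print(f"\nsensitivity on somatic sites: {sum(somatic) / len(somatic):.3f}")
print(f"germline pass-throughs: {sum(by_label['germline'])}")
print("\nconsequence summary of passing calls:", summarize_calls(verdicts))

# Expected: ~all somatic sites kept; germline sites removed by the
# normal-absence + Fisher criteria; artifacts removed by the strand and
# homopolymer criteria.
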