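"""Merge array, FISH and sequence evidence into final CDKN2A calls.

The deeper loss wins across assays, and a truncating mutation under LOH
counts as biallelic inactivation. The 16-case evidence pattern below
tabulates to 8 homozygous (50.0%), 2 heterozygous (12.5%), 62.5% any loss.
"""

from cdc_lossmap import cohort_frequencies, integrate_cohort


def rec(sid, arr, fish, snv=False, loh=False):
    return {"sample_id": sid, "array_status": arr, "fish_status": fish,
            "truncating_snv": snv, "loh_at_locus": loh}


evidence = [
    rec("CDC1", "homo_loss", "homo_loss"),
    rec("CDC2", "homo_loss", "homo_loss"),
    rec("CDC4", "homo_loss", "homo_loss"),
    rec("CDC6", "no_loss", "homo_loss"),       # biallelic seen by FISH only
    rec("CDC3", "no_loss", "het_loss"),
    rec("CDC5", "not_assayed", "no_loss", snv=True, loh=True),  # nonsense + LOH
    rec("CDC7", "no_loss", "no_loss"),
]
ffpe = ["homo_loss"] * 3 + ["het_loss"] + ["no_loss"] * 5
evidence += [rec(f"CDC{8 + i}", "not_assayed", s) for i, s in enumerate(ffpe)]

statuses = integrate_cohort(evidence)
for s in statuses[:7]:
    print(f"{s.sample_id}: {s.final_status:>9}   [{s.evidence_note}]")

summary = cohort_frequencies(statuses)
print(f"\n{summary.n_homo}/{summary.n_samples} homozygous ({summary.pct_homo}%), "
      f"{summary.n_het}/{summary.n_samples} heterozygous ({summary.pct_het}%), "
      f"any loss {summary.pct_any_loss}%")
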