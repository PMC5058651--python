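# cdc-lossmap

Somatic-alteration analysis for collecting duct carcinoma (CDC), a rare and
aggressive renal cell carcinoma subtype arising from the distal collecting
ducts. The package implements the downstream analysis stack such a study
needs once reads are aligned and candidates are called: tumor/normal
somatic variant filtering, gene-level copy-number loss calling from logR
segments, FISH probe-ratio classification of *CDKN2A* status, integration
of the three assays into per-sample calls and cohort frequencies, and
solute-carrier (SLC) family expression profiling — together with a seeded
synthetic cohort generator so every stage can be benchmarked against known
ground truth.

## What it computes

**Somatic filter chain.** A putative SNV/indel with stranded read counts
(t<sub>alt</sub>, t<sub>ref</sub>) in tumor and (n<sub>alt</sub>,
n<sub>ref</sub>) in normal is kept iff

1. the alternative allele is absent in the paired normal
   (n<sub>alt</sub> ≤ 0 by default);
2. the one-sided Fisher exact test on
   [[t<sub>alt</sub>, t<sub>ref</sub>], [n<sub>alt</sub>, n<sub>ref</sub>]]
   shows tumor enrichment, p = P(X ≥ t<sub>alt</sub>) with
   X ~ Hypergeom(N, K, n<sub>t</sub>), below α = 0.05;
3. the mutant allele appears on both strands (≥ 1 read each);
4. no homopolymer run of ≥ 5 bases touches (±1 bp) the variant position;
5. for indels, realignment of all tumor and normal reads against a mutant
   template (alternate allele substituted into the reference window)
   leaves ≥ 2 supporting tumor reads and 0 supporting normal reads.

**Copy-number loss.** A gene is lost in a sample when an overlapping
segment has logR < −0.4; below −1.0 the loss is called homozygous. Multiple
overlapping segments aggregate by minimum logR, so a focal deletion inside
a broad neutral segment is not averaged away.

**FISH classification.** Per case, ratio = mean(*CDKN2A* probes/cell) /
mean(CEP9 probes/cell) over 200 nuclei; ratio > 0.75 → no loss,
0.5 ≤ ratio ≤ 0.75 → heterozygous loss, ratio < 0.5 → biallelic loss.

**Integration.** Final status per sample is the maximum severity across
assays (no_loss < het_loss < homo_loss); a truncating SNV under LOH counts
as biallelic inactivation. Cohort percentages round half-up to one decimal.

**Expression.** Family alteration = share of family genes with adjusted
p < 0.05 (up if log2FC > 0, down if < 0); per-sample overexpression and
IHC percent-positive bins (< 2 negative, 2–20 low, 20–80 intermediate,
≥ 80 high) use the same rounding.

## Worked example

```python
from cdc_lossmap import cohort_frequencies, integrate_cohort

def rec(sid, arr, fish, snv=False, loh=False):
    return {"sample_id": sid, "array_status": arr, "fish_status": fish,
            "truncating_snv": snv, "loh_at_locus": loh}

evidence = [
    rec("CDC1", "homo_loss", "homo_loss"),
    rec("CDC2", "homo_loss", "homo_loss"),
    rec("CDC4", "homo_loss", "homo_loss"),
    rec("CDC6", "no_loss", "homo_loss"),                        # FISH-only biallelic
    rec("CDC3", "no_loss", "het_loss"),
    rec("CDC5", "not_assayed", "no_loss", snv=True, loh=True),  # nonsense + LOH
    rec("CDC7", "no_loss", "no_loss"),
] + [rec(f"CDC{8+i}", "not_assayed", s)
     for i, s in enumerate(["homo_loss"]*3 + ["het_loss"] + ["no_loss"]*5)]

s = cohort_frequencies(integrate_cohort(evidence))
print(s.n_homo, s.pct_homo, s.n_het, s.pct_het, s.pct_any_loss)
```

prints

```
8 50.0 2 12.5 62.5
```

i.e. 8 of 16 cases carry biallelic *CDKN2A* inactivation (50.0%) — the
FISH-only deletion and the nonsense mutation under LOH both count — plus 2
heterozygous losses (12.5%), for 62.5% of the cohort with any loss.

The `examples/` directory holds one short script per capability
(simulation, filtering, copy number + FISH, integration, expression); each
prints the numbers it computes and what they mean. `cdc-lossmap run
--outdir out --seed 1` runs the whole pipeline on a synthetic cohort and
writes every stage's table plus a manifest; with noise-free generator
settings the integrated frequencies reproduce the configured 8/2/6 truth
exactly.

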