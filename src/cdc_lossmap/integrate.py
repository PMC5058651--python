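"""Cross-assay integration of gene-loss evidence and cohort frequencies.

Array (SNP-array segment) calls, FISH calls and sequence evidence
(truncating SNV plus LOH at the locus) are merged into one final status per
sample. The rule is a maximum over an ordered severity scale
no_loss < het_loss < homo_loss: whichever assay reports the deeper loss
wins, and a truncating mutation on an LOH background counts as biallelic
inactivation. This reproduces the two published discordance patterns — a
FISH-only homozygous loss missed by the array, and a nonsense mutation
under LOH tallied with the homozygous losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from ._util import pct

SEVERITY = {"no_loss": 0, "het_loss": 1, "homo_loss": 2}
NOT_ASSAYED = "not_assayed"


@dataclass(frozen=True)
class SampleGeneStatus:
    """Per-assay and integrated loss call for one gene in one sample."""

    sample_id: str
    gene: str
    array_status: str          # no_loss | het_loss | homo_loss | not_assayed
    fish_status: str
    truncating_snv: bool
    loh_at_locus: bool
    final_status: str
    evidence_note: str


@dataclass(frozen=True)
class CohortSummary:
    n_samples: int
    n_homo: int
    n_het: int
    n_no_loss: int
    pct_homo: float
    pct_het: float
    pct_any_loss: float


def _check_status(name: str, value: str) -> None:
    if value not in SEVERITY and value != NOT_ASSAYED:
        raise ValueError(f"invalid {name} {value!r}")


def integrate_sample(
    array_status: str,
    fish_status: str,
    truncating_snv: bool,
    loh_at_locus: bool,
) -> tuple[str, str]:
    """Merge evidence for one sample into (final_status, evidence_note).

    Raises if every source is absent (both assays not_assayed and no
    sequence evidence).
    """
    _check_status("array_status", array_status)
    _check_status("fish_status", fish_status)
    has_assay = array_status != NOT_ASSAYED or fish_status != NOT_ASSAYED
    if not has_assay and not truncating_snv:
        raise ValueError("no evidence source present for this sample")

    contributions: list[tuple[str, int]] = []
    if array_status != NOT_ASSAYED:
        contributions.append((f"array:{array_status}", SEVERITY[array_status]))
    if fish_status != NOT_ASSAYED:
        contributions.append((f"fish:{fish_status}", SEVERITY[fish_status]))
    if truncating_snv and loh_at_locus:
        contributions.append(("truncating_snv+LOH:biallelic", SEVERITY["homo_loss"]))
    elif truncating_snv:
        # one allele hit; without LOH this alone does not deepen copy loss
        contributions.append(("truncating_snv:monoallelic", SEVERITY["het_loss"]))

    final_sev = max(sev for _, sev in contributions)
    final = next(s for s, sev in SEVERITY.items() if sev == final_sev)
    drivers = [tag for tag, sev in contributions if sev == final_sev]
    note = "; ".join(drivers)
    assay_sevs = {
        sev for tag, sev in contributions if tag.startswith(("array", "fish"))
    }
    if len(assay_sevs) > 1:
        note += " [discordant assays]"
    return final, note


def integrate_cohort(
    records: Sequence[dict],
    gene: str = "CDKN2A",
) -> list[SampleGeneStatus]:
    """Integrate a list of per-sample evidence dicts for one gene.

    Each record needs keys sample_id, array_status, fish_status,
    truncating_snv, loh_at_locus.
    """
    out = []
    for rec in records:
        final, note = integrate_sample(
            rec["array_status"],
            rec["fish_status"],
            bool(rec["truncating_snv"]),
            bool(rec["loh_at_locus"]),
        )
        out.append(
            SampleGeneStatus(
                sample_id=rec["sample_id"],
                gene=rec.get("gene", gene),
                array_status=rec["array_status"],
                fish_status=rec["fish_status"],
                truncating_snv=bool(rec["truncating_snv"]),
                loh_at_locus=bool(rec["loh_at_locus"]),
                final_status=final,
                evidence_note=note,
            )
        )
    return out


def cohort_frequencies(statuses: Sequence[SampleGeneStatus]) -> CohortSummary:
    """Tabulate final statuses across the cohort, one entry per sample.

    Percentages are rounded half-up to one decimal; ``pct_any_loss`` counts
    both heterozygous and homozygous losses.
    """
    if not statuses:
        raise ValueError("empty cohort")
    ids = [s.sample_id for s in statuses]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in cohort")
    n = len(statuses)
    n_homo = sum(s.final_status == "homo_loss" for s in statuses)
    n_het = sum(s.final_status == "het_loss" for s in statuses)
    n_no = n - n_homo - n_het
    return CohortSummary(
        n_samples=n,
        n_homo=n_homo,
        n_het=n_het,
        n_no_loss=n_no,
        pct_homo=pct(n_homo, n),
        pct_het=pct(n_het, n),
        pct_any_loss=pct(n_homo + n_het, n),
    )


def snv_evidence_for_gene(
    snv_records: Sequence[dict], sample_id: str, gene: str
) -> tuple[bool, bool]:
    """Look up (truncating_snv, loh) for one sample/gene in an SNV-evidence
    table; absent entries mean no sequence evidence."""
    for rec in snv_records:
        if rec["sample_id"] == sample_id and rec["gene"] == gene:
            return bool(rec["truncating_snv"]), bool(rec["loh"])
    return False, False
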