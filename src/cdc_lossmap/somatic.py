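"""Tumor/normal somatic variant filtering.

Post-caller filters applied to putative SNVs and indels from a matched
tumor/normal pair:

1. *normal absence* — the alternative allele must be (essentially) absent in
   the paired non-tumor sample;
2. *tumor enrichment* — a one-sided Fisher exact test must show the
   non-reference allele significantly more frequent in tumor reads than in
   normal reads;
3. *both orientations* — the mutant allele must be observed on both the
   forward and reverse strand (single-strand support is the signature of a
   sequencing/mapping artifact);
4. *homopolymer context* — candidates sitting in or immediately next to a
   homopolymer run are rejected (slippage artifacts);
5. *indel realignment* — for indels, all reads from both samples are
   re-scored against a mutant template built by substituting the alternate
   allele into the reference window; the call must retain tumor support and
   gain no normal support.

A candidate is somatic iff every applicable filter passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
CONSEQUENCES = ("missense", "nonsense", "frameshift", "protein_deletion", "other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrandedAlleleCounts:
    """Read counts for one sample at one site, split by allele and strand."""

    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def ref(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def alt(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def depth(self) -> int:
        return self.ref + self.alt


@dataclass(frozen=True)
class VariantCandidate:
    """One putative SNV/indel with stranded tumor and normal evidence.

    ``pos`` is 1-based; ``context`` is the reference sequence of odd length
    centred on the variant position.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_class: str  # snv | ins | del
    tumor: StrandedAlleleCounts
    normal: StrandedAlleleCounts
    context: str
    consequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in ("snv", "ins", "del"):
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref/alt alleles must be non-empty")
        if self.variant_class == "snv" and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise ValueError("snv alleles must have length 1")
        if len(self.context) % 2 != 1:
            raise ValueError("context length must be odd")


@dataclass(frozen=True)
class FilterParams:
    """Tunable thresholds for the somatic filter chain."""

    fisher_alpha: float = 0.05
    max_normal_alt_reads: int = 0
    min_alt_per_strand: int = 1
    homopolymer_min_run: int = 5
    indel_min_tumor_support: int = 2
    indel_max_normal_support: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fisher_alpha < 1.0:
            raise ValueError("fisher_alpha must be in (0, 1)")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        for name in (
            "max_normal_alt_reads",
            "min_alt_per_strand",
            "indel_min_tumor_support",
            "indel_max_normal_support",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class AlignedRead:
    """A read overlapping an indel site: its sequence and the 0-based offset
    of its first base relative to the reference window start."""

    sequence: str
    offset: int


@dataclass(frozen=True)
class IndelReadSet:
    """Reads from tumor and normal overlapping one indel site.

    ``window`` is the reference subsequence around the site and
    ``indel_offset`` the 0-based position within the window where the
    reference allele starts.
    """

    tumor_reads: tuple[AlignedRead, ...]
    normal_reads: tuple[AlignedRead, ...]
    window: str
    indel_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.indel_offset < len(self.window):
            raise ValueError("indel_offset must fall inside the window")


@dataclass
class FilterVerdict:
    """Per-candidate outcome of the filter chain.

    ``pass_realignment`` is vacuously true for SNVs. ``is_somatic`` is the
    conjunction of all applicable flags.
    """

    candidate: VariantCandidate
    pass_normal_absence: bool
    pass_fisher: bool
    pass_orientation: bool
    pass_homopolymer: bool
    pass_realignment: bool
    fisher_p: float
    is_somatic: bool = field(init=False)

    def __post_init__(self) -> None:
        self.is_somatic = (
            self.pass_normal_absence
            and self.pass_fisher
            and self.pass_orientation
            and self.pass_homopolymer
            and self.pass_realignment
        )


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def fisher_enrichment_pvalue(t_alt, t_depth, n_alt, n_depth):
    """One-sided Fisher exact p-value for alt-allele enrichment in tumor.

    Conditions on the 2x2 table [[t_alt, t_ref], [n_alt, n_ref]] with fixed
    margins; the p-value is the upper hypergeometric tail
    ``P(X >= t_alt)`` with ``X ~ Hypergeom(N=t_depth+n_depth,
    K=t_alt+n_alt, n=t_depth)``. Accepts scalars or numpy arrays
    (broadcast together).
    """
    t_alt = np.asarray(t_alt)
    t_depth = np.asarray(t_depth)
    n_alt = np.asarray(n_alt)
    n_depth = np.asarray(n_depth)
    if np.any(t_depth < 1) or np.any(n_depth < 1):
        raise ValueError("tumor and normal depth must each be >= 1")
    if np.any(t_alt > t_depth) or np.any(n_alt > n_depth):
        raise ValueError("alt count cannot exceed depth")
    p = hypergeom.sf(t_alt - 1, t_depth + n_depth, t_alt + n_alt, t_depth)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def fisher_tumor_enrichment(
    tumor: StrandedAlleleCounts, normal: StrandedAlleleCounts
) -> float:
    """One-sided Fisher exact p-value that the non-reference allele is more
    frequent in tumor than in paired normal (strand-collapsed counts)."""
    return fisher_enrichment_pvalue(tumor.alt, tumor.depth, normal.alt, normal.depth)


def check_normal_absence(
    normal: StrandedAlleleCounts, params: FilterParams = FilterParams()
) -> bool:
    """True iff the normal sample carries at most ``max_normal_alt_reads``
    alternative-allele reads (default 0: strictly absent)."""
    return normal.alt <= params.max_normal_alt_reads


def check_orientation(
    tumor: StrandedAlleleCounts, params: FilterParams = FilterParams()
) -> bool:
    """True iff the mutant allele is seen on both strands, with at least
    ``min_alt_per_strand`` reads each."""
    return (
        tumor.alt_fwd >= params.min_alt_per_strand
        and tumor.alt_rev >= params.min_alt_per_strand
    )


def _runs(seq: str) -> Iterable[tuple[int, int]]:
    """Yield (start, end) inclusive indices of maximal single-base runs."""
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[start]:
            yield start, i - 1
            start = i


def detect_homopolymer(context: str, params: FilterParams = FilterParams()) -> bool:
    """True iff a homopolymer run of length >= ``homopolymer_min_run``
    includes, or lies within 1 bp of, the centre (variant) position.

    A True return means the candidate FAILS the homopolymer criterion.
    """
    if len(context) % 2 != 1:
        raise ValueError("context length must be odd")
    bad = set(context.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"context contains non-ACGTN characters: {sorted(bad)}")
    seq = context.upper()
    centre = len(seq) // 2
    for start, end in _runs(seq):
        if end - start + 1 >= params.homopolymer_min_run:
            if start - 1 <= centre <= end + 1:
                return True
    return False


def _mismatches(read: str, template: str, offset: int) -> int:
    """Ungapped mismatch count of ``read`` placed at ``offset`` on
    ``template``; bases falling outside the template count as mismatches."""
    n_mm = 0
    for i, base in enumerate(read):
        j = offset + i
        if j < 0 or j >= len(template):
            n_mm += 1
        elif template[j] != base:
            n_mm += 1
    return n_mm


def realign_indel_support(
    reads: IndelReadSet, ref_allele: str, alt_allele: str
) -> tuple[int, int]:
    """Count reads supporting the mutant allele after realignment.

    The mutant template substitutes ``alt_allele`` for ``ref_allele`` in the
    reference window. Each read is scored ungapped against both templates;
    on the mutant template a read starting right of the edited site is also
    tried at its indel-shifted offset and the better placement is kept. A
    read supports the mutant iff its mutant mismatch count is strictly lower
    than its reference mismatch count (ties are conservative: no support).

    Returns ``(tumor_support, normal_support)``.
    """
    window = reads.window
    i = reads.indel_offset
    if window[i : i + len(ref_allele)] != ref_allele:
        raise ValueError("reference allele does not match the window at indel_offset")
    mutant = window[:i] + alt_allele + window[i + len(ref_allele):]
    shift = len(alt_allele) - len(ref_allele)

    def supports(read: AlignedRead) -> bool:
        site_end = i + len(ref_allele)
        if read.offset >= len(window) or read.offset + len(read.sequence) <= i:
            log.warning("read at offset %d does not overlap the indel site", read.offset)
            return False
        mm_ref = _mismatches(read.sequence, window, read.offset)
        mm_mut = _mismatches(read.sequence, mutant, read.offset)
        if shift != 0 and read.offset >= site_end:
            mm_mut = min(mm_mut, _mismatches(read.sequence, mutant, read.offset + shift))
        return mm_mut < mm_ref

    tumor_support = sum(supports(r) for r in reads.tumor_reads)
    normal_support = sum(supports(r) for r in reads.normal_reads)
    return tumor_support, normal_support


# ---------------------------------------------------------------------------
# filter chain
# ---------------------------------------------------------------------------

def apply_somatic_filters(
    candidate: VariantCandidate,
    params: FilterParams = FilterParams(),
    indel_reads: Optional[IndelReadSet] = None,
) -> FilterVerdict:
    """Run all applicable filters on one candidate and return the verdict.

    SNVs skip the realignment filter (vacuously true); indels require
    ``indel_reads``.
    """
    if candidate.variant_class != "snv" and indel_reads is None:
        raise ValueError("indel candidates require an IndelReadSet for realignment")

    fisher_p = fisher_tumor_enrichment(candidate.tumor, candidate.normal)
    pass_realignment = True
    if candidate.variant_class != "snv":
        t_sup, n_sup = realign_indel_support(
            indel_reads, candidate.ref_allele, candidate.alt_allele
        )
        pass_realignment = (
            t_sup >= params.indel_min_tumor_support
            and n_sup <= params.indel_max_normal_support
        )

    return FilterVerdict(
        candidate=candidate,
        pass_normal_absence=check_normal_absence(candidate.normal, params),
        pass_fisher=fisher_p < params.fisher_alpha,
        pass_orientation=check_orientation(candidate.tumor, params),
        pass_homopolymer=not detect_homopolymer(candidate.context, params),
        pass_realignment=pass_realignment,
        fisher_p=fisher_p,
    )


def filter_candidates(
    candidates: Sequence[VariantCandidate],
    params: FilterParams = FilterParams(),
    indel_reads: Optional[Mapping[tuple[str, str, int], IndelReadSet]] = None,
) -> list[FilterVerdict]:
    """Apply the filter chain to a list of candidates.

    ``indel_reads`` maps ``(sample_id, chrom, pos)`` to the read set for
    indel candidates.
    """
    verdicts = []
    for cand in candidates:
        reads = None
        if cand.variant_class != "snv" and indel_reads is not None:
            reads = indel_reads.get((cand.sample_id, cand.chrom, cand.pos))
        verdicts.append(apply_somatic_filters(cand, params, reads))
    return verdicts


def summarize_calls(verdicts: Iterable[FilterVerdict]) -> dict[str, int]:
    """Count somatic-passing candidates per consequence label.

    Candidates with no / unknown consequence fall under ``other``; the
    returned mapping also carries a ``total`` key.
    """
    counts = {label: 0 for label in CONSEQUENCES}
    for v in verdicts:
        if not v.is_somatic:
            continue
        label = v.candidate.consequence
        counts[label if label in CONSEQUENCES else "other"] += 1
    counts["total"] = sum(counts[label] for label in CONSEQUENCES)
    return counts
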