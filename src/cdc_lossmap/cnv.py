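"""Gene-level copy-number loss calling from logR segments.

A gene is called lost in a sample when an overlapping copy-number segment
has logR below the loss threshold (default -0.4, the standard cut-off for
array-based single-copy loss). A second, deeper threshold (default -1.0,
the expected logR of a single-copy loss in a pure diploid tumor) separates
heterozygous from homozygous (biallelic) loss. Multiple overlapping
segments are aggregated by minimum logR so a focal deletion inside a broad
neutral segment is not averaged away.

All intervals are 1-based inclusive (SEG-style); BED input is converted on
read by the I/O layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

log = logging.getLogger(__name__)

CN_STATES = ("no_loss", "het_loss", "homo_loss")


@dataclass(frozen=True)
class Segment:
    """One copy-number segment with mean logR and an LOH flag."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    logr: float
    loh: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if not (self.logr == self.logr and abs(self.logr) != float("inf")):
            raise ValueError("logR must be finite")


@dataclass(frozen=True)
class GeneInterval:
    """A gene locus, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")


@dataclass(frozen=True)
class CnThresholds:
    loss_logr: float = -0.4
    homo_logr: float = -1.0

    def __post_init__(self) -> None:
        if not self.homo_logr < self.loss_logr:
            raise ValueError("homo_logr must be below loss_logr")


@dataclass(frozen=True)
class GeneCNStatus:
    """Copy-number call for one gene in one sample."""

    sample_id: str
    gene: str
    status: str  # no_loss | het_loss | homo_loss
    min_overlapping_logr: Optional[float]
    loh: bool


def overlaps(segment: Segment, gene: GeneInterval) -> bool:
    """True iff segment and gene share at least one base (same chromosome,
    1-based inclusive coordinates)."""
    return (
        segment.chrom == gene.chrom
        and segment.start <= gene.end
        and gene.start <= segment.end
    )


def call_gene_loss(
    segments: Sequence[Segment],
    gene: GeneInterval,
    thresholds: CnThresholds = CnThresholds(),
) -> GeneCNStatus:
    """Call loss status of one gene from one sample's segments.

    Uses the minimum logR among overlapping segments: ``homo_loss`` if
    min < homo_logr, ``het_loss`` if homo_logr <= min < loss_logr (strict
    "less than" at the loss threshold), else ``no_loss``. A locus with no
    overlapping segment is reported ``no_loss`` with logR ``None`` and
    logged as uncovered.
    """
    samples = {s.sample_id for s in segments}
    if len(samples) > 1:
        raise ValueError(f"segments span multiple samples: {sorted(samples)}")
    sample_id = segments[0].sample_id if segments else "NA"

    over = [s for s in segments if overlaps(s, gene)]
    if not over:
        log.warning("locus %s uncovered for sample %s", gene.gene, sample_id)
        return GeneCNStatus(sample_id, gene.gene, "no_loss", None, False)

    min_logr = min(s.logr for s in over)
    loh = any(s.loh for s in over)
    if min_logr < thresholds.homo_logr:
        status = "homo_loss"
    elif min_logr < thresholds.loss_logr:
        status = "het_loss"
    else:
        status = "no_loss"
    return GeneCNStatus(sample_id, gene.gene, status, min_logr, loh)


def genome_loss_profile(
    segments: Sequence[Segment],
    genes: Sequence[GeneInterval],
    thresholds: CnThresholds = CnThresholds(),
) -> list[GeneCNStatus]:
    """Call every gene in every sample present in ``segments``.

    Output is ordered by (sample_id, gene symbol).
    """
    by_sample: dict[str, list[Segment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    profile = []
    for sample_id in sorted(by_sample):
        for gene in sorted(genes, key=lambda g: g.gene):
            profile.append(call_gene_loss(by_sample[sample_id], gene, thresholds))
    return profile
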