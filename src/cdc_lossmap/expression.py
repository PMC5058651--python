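"""Gene-family expression profiling and IHC scoring.

Summarises how much of a gene family (here the ~300-member solute carrier,
SLC, transporter family) is differentially expressed in tumor versus
matched normal, computes per-sample overexpression fractions for a single
gene of interest (e.g. the cystine transporter SLC7A11/xCT), and bins
immunohistochemistry percent-positive scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ._util import pct

IHC_BINS = ("negative", "low", "intermediate", "high")


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression table (tumor vs normal)."""

    gene: str
    log2fc: float
    padj: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.padj <= 1.0:
            raise ValueError("padj must be in [0, 1]")
        if self.log2fc != self.log2fc or abs(self.log2fc) == float("inf"):
            raise ValueError("log2fc must be finite")


@dataclass(frozen=True)
class FamilyAlterationSummary:
    family_name: str
    n_family: int
    n_up: int
    n_down: int
    n_altered: int
    pct_altered: float
    top_up: tuple[str, ...]
    top_down: tuple[str, ...]


@dataclass(frozen=True)
class IhcScore:
    sample_id: str
    pct_positive_cells: float
    bin: str


def family_alteration_summary(
    de: Sequence[DERecord],
    family_genes: Sequence[str],
    padj_cutoff: float = 0.05,
    family_name: str = "SLC",
    n_top: int = 5,
) -> FamilyAlterationSummary:
    """Count significantly up-/down-regulated family members.

    A family gene is up if ``padj < padj_cutoff`` and ``log2fc > 0``, down
    if significant with ``log2fc < 0``. Family genes absent from the DE
    table (or significant with log2fc exactly 0) count as unaltered; genes
    outside the family are ignored. ``top_up``/``top_down`` rank altered
    family genes by |log2fc|.
    """
    if not family_genes:
        raise ValueError("family_genes must be non-empty")
    if len(set(family_genes)) != len(family_genes):
        raise ValueError("family_genes contains duplicate symbols")
    seen: set[str] = set()
    for rec in de:
        if rec.gene in seen:
            raise ValueError(f"duplicate gene {rec.gene!r} in DE table")
        seen.add(rec.gene)

    family = set(family_genes)
    up = [r for r in de if r.gene in family and r.padj < padj_cutoff and r.log2fc > 0]
    down = [r for r in de if r.gene in family and r.padj < padj_cutoff and r.log2fc < 0]
    up.sort(key=lambda r: (-abs(r.log2fc), r.gene))
    down.sort(key=lambda r: (-abs(r.log2fc), r.gene))

    n_altered = len(up) + len(down)
    return FamilyAlterationSummary(
        family_name=family_name,
        n_family=len(family_genes),
        n_up=len(up),
        n_down=len(down),
        n_altered=n_altered,
        pct_altered=pct(n_altered, len(family_genes)),
        top_up=tuple(r.gene for r in up[:n_top]),
        top_down=tuple(r.gene for r in down[:n_top]),
    )


def per_sample_up_fraction(
    per_sample_log2fc: Mapping[str, float], min_log2fc: float = 0.0
) -> tuple[int, int, float]:
    """Fraction of samples where a gene is up-regulated.

    Returns ``(n_up, n_total, percentage)`` with the percentage rounded
    half-up to one decimal; a sample counts as up if its log2 fold change
    exceeds ``min_log2fc`` (default 0: any up-regulation).
    """
    if not per_sample_log2fc:
        raise ValueError("at least one sample is required")
    n_total = len(per_sample_log2fc)
    n_up = sum(v > min_log2fc for v in per_sample_log2fc.values())
    return n_up, n_total, pct(n_up, n_total)


def classify_ihc(pct_positive_cells: float) -> str:
    """Bin an IHC percent-positive score.

    Scoring bins: < 2% negative, 2-20% low, 20-80% (exclusive)
    intermediate, >= 80% high. The published scheme names only the low and
    high bins; the other two make the partition exhaustive.
    """
    if not 0.0 <= pct_positive_cells <= 100.0:
        raise ValueError("percent positive cells must be in [0, 100]")
    if pct_positive_cells < 2:
        return "negative"
    if pct_positive_cells <= 20:
        return "low"
    if pct_positive_cells < 80:
        return "intermediate"
    return "high"


def make_ihc_score(sample_id: str, pct_positive_cells: float) -> IhcScore:
    return IhcScore(sample_id, pct_positive_cells, classify_ihc(pct_positive_cells))


def ihc_cohort_fraction(scores: Sequence[IhcScore]) -> float:
    """Percentage of cases scored high, rounded half-up to one decimal."""
    if not scores:
        raise ValueError("empty score list")
    return pct(sum(s.bin == "high" for s in scores), len(scores))
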