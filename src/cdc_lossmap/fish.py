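"""FISH probe-ratio computation and CDKN2A loss classification.

For each case, target (CDKN2A) and reference (CEP9, chromosome-9
centromere) probe signals are counted in interphase nuclei — 200 neoplastic
cells per case in the standard protocol. The case ratio is the average
number of target probes per cell divided by the average number of reference
probes per cell, and is binned as:

* ratio > 0.75          -> no loss
* 0.5 <= ratio <= 0.75  -> heterozygous (single-copy) loss
* ratio < 0.5           -> biallelic (homozygous) loss

The published bins leave the two boundary values doubly described; this
implementation assigns both 0.5 and 0.75 to the heterozygous bin (the
thresholds are parameters). No rounding is applied before binning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

log = logging.getLogger(__name__)

FISH_CALLS = ("no_loss", "het_loss", "homo_loss")
DEFAULT_MIN_CELLS = 200


class FishCell(NamedTuple):
    """Probe counts in one nucleus: target (CDKN2A) and reference (CEP9)."""

    n_target: int
    n_reference: int


@dataclass(frozen=True)
class FishCase:
    """Per-cell probe counts for one sample."""

    sample_id: str
    cells: tuple[FishCell, ...]


@dataclass(frozen=True)
class FishResult:
    sample_id: str
    n_cells: int
    ratio: float
    call: str
    sub_threshold: bool  # fewer cells than the protocol minimum


class AssayFailureError(ValueError):
    """Raised when the reference probe yields no signal at all."""


def fish_ratio(cells: Sequence[FishCell]) -> float:
    """Mean target count divided by mean reference count.

    Equivalent to total target probes / total reference probes; invariant
    to cell order and to duplicating the cell list.
    """
    if not cells:
        raise ValueError("at least one cell is required")
    if any(c.n_target < 0 or c.n_reference < 0 for c in cells):
        raise ValueError("probe counts must be non-negative")
    total_ref = sum(c.n_reference for c in cells)
    if total_ref == 0:
        raise AssayFailureError("all reference probe counts are zero")
    mean_target = sum(c.n_target for c in cells) / len(cells)
    mean_reference = total_ref / len(cells)
    return mean_target / mean_reference


def classify_fish(
    ratio: float, het_upper: float = 0.75, homo_upper: float = 0.5
) -> str:
    """Bin a probe ratio into no_loss / het_loss / homo_loss.

    Boundary convention: exactly ``het_upper`` (0.75) and exactly
    ``homo_upper`` (0.5) both classify as het_loss.
    """
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if not homo_upper < het_upper:
        raise ValueError("homo_upper must be below het_upper")
    if ratio > het_upper:
        return "no_loss"
    if ratio >= homo_upper:
        return "het_loss"
    return "homo_loss"


def evaluate_case(
    sample_id: str,
    cells: Sequence[FishCell],
    min_cells: int = DEFAULT_MIN_CELLS,
    het_upper: float = 0.75,
    homo_upper: float = 0.5,
) -> FishResult:
    """Compute the ratio and call for one case.

    Cases with fewer than ``min_cells`` cells are still evaluated but
    flagged sub-threshold (and a warning is logged) rather than rejected.
    """
    ratio = fish_ratio(cells)
    sub = len(cells) < min_cells
    if sub:
        log.warning(
            "sample %s: only %d cells evaluated (< %d)", sample_id, len(cells), min_cells
        )
    return FishResult(
        sample_id=sample_id,
        n_cells=len(cells),
        ratio=ratio,
        call=classify_fish(ratio, het_upper, homo_upper),
        sub_threshold=sub,
    )
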