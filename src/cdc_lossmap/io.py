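"""Readers and writers for the pipeline's tab-separated exchange formats.

All tables are plain TSV handled through pandas. Internal coordinates are
1-based inclusive (the SEG convention used here); BED input/output is
converted at the boundary (BED is 0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .cnv import GeneCNStatus, GeneInterval, Segment
from .expression import DERecord, IhcScore, make_ihc_score
from .fish import FishCase, FishCell, FishResult
from .integrate import CohortSummary, SampleGeneStatus
from .somatic import FilterVerdict, StrandedAlleleCounts, VariantCandidate

VARIANT_COLUMNS = [
    "SAMPLE", "CHROM", "POS", "REF", "ALT", "CLASS", "CONTEXT",
    "T_REF_FWD", "T_REF_REV", "T_ALT_FWD", "T_ALT_REV",
    "N_REF_FWD", "N_REF_REV", "N_ALT_FWD", "N_ALT_REV", "CONSEQUENCE",
]


def _write(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def write_variants(candidates: Sequence[VariantCandidate], path: str | Path) -> None:
    rows = [
        {
            "SAMPLE": c.sample_id, "CHROM": c.chrom, "POS": c.pos,
            "REF": c.ref_allele, "ALT": c.alt_allele, "CLASS": c.variant_class,
            "CONTEXT": c.context,
            "T_REF_FWD": c.tumor.ref_fwd, "T_REF_REV": c.tumor.ref_rev,
            "T_ALT_FWD": c.tumor.alt_fwd, "T_ALT_REV": c.tumor.alt_rev,
            "N_REF_FWD": c.normal.ref_fwd, "N_REF_REV": c.normal.ref_rev,
            "N_ALT_FWD": c.normal.alt_fwd, "N_ALT_REV": c.normal.alt_rev,
            "CONSEQUENCE": c.consequence or "other",
        }
        for c in candidates
    ]
    _write(pd.DataFrame(rows, columns=VARIANT_COLUMNS), path)


def read_variants(path: str | Path) -> list[VariantCandidate]:
    df = pd.read_csv(path, sep="\t", dtype={"SAMPLE": str, "CHROM": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantCandidate(
                sample_id=row.SAMPLE,
                chrom=row.CHROM,
                pos=int(row.POS),
                ref_allele=row.REF,
                alt_allele=row.ALT,
                variant_class=row.CLASS,
                tumor=StrandedAlleleCounts(
                    int(row.T_REF_FWD), int(row.T_REF_REV),
                    int(row.T_ALT_FWD), int(row.T_ALT_REV),
                ),
                normal=StrandedAlleleCounts(
                    int(row.N_REF_FWD), int(row.N_REF_REV),
                    int(row.N_ALT_FWD), int(row.N_ALT_REV),
                ),
                context=row.CONTEXT,
                consequence=row.CONSEQUENCE,
            )
        )
    return out


def write_verdicts(verdicts: Sequence[FilterVerdict], path: str | Path) -> None:
    rows = [
        {
            "SAMPLE": v.candidate.sample_id,
            "CHROM": v.candidate.chrom,
            "POS": v.candidate.pos,
            "PASS_NORMAL_ABSENCE": v.pass_normal_absence,
            "PASS_FISHER": v.pass_fisher,
            "PASS_ORIENTATION": v.pass_orientation,
            "PASS_HOMOPOLYMER": v.pass_homopolymer,
            "PASS_REALIGNMENT": v.pass_realignment,
            "FISHER_P": f"{v.fisher_p:.6g}",
            "IS_SOMATIC": v.is_somatic,
        }
        for v in verdicts
    ]
    _write(pd.DataFrame(rows), path)


# ---------------------------------------------------------------------------
# segments / genes
# ---------------------------------------------------------------------------

def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    """SEG-style table (1-based inclusive) with an extra LOH column."""
    rows = [
        {
            "sample": s.sample_id, "chrom": s.chrom, "start": s.start,
            "end": s.end, "logR": f"{s.logr:.6f}", "LOH": int(s.loh),
        }
        for s in segments
    ]
    _write(pd.DataFrame(rows), path)


def read_segments(path: str | Path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return [
        Segment(
            sample_id=r.sample, chrom=r.chrom, start=int(r.start),
            end=int(r.end), logr=float(r.logR), loh=bool(int(r.LOH)),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_bed(genes: Sequence[GeneInterval], path: str | Path) -> None:
    """Write gene intervals as BED (0-based half-open)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene}\n")


def read_gene_bed(path: str | Path) -> list[GeneInterval]:
    """Read BED gene intervals, converting to 1-based inclusive."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            genes.append(GeneInterval(name, chrom, int(start) + 1, int(end)))
    return genes


def write_gene_status(statuses: Sequence[GeneCNStatus], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id, "gene": s.gene, "status": s.status,
            "min_logR": "NA" if s.min_overlapping_logr is None else f"{s.min_overlapping_logr:.6f}",
            "LOH": int(s.loh),
        }
        for s in statuses
    ]
    _write(pd.DataFrame(rows), path)


def read_gene_status(path: str | Path) -> list[GeneCNStatus]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "min_logR": str})
    return [
        GeneCNStatus(
            sample_id=r.sample, gene=r.gene, status=r.status,
            min_overlapping_logr=None if r.min_logR == "NA" else float(r.min_logR),
            loh=bool(int(r.LOH)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# FISH
# ---------------------------------------------------------------------------

def write_fish_cells(cases: Sequence[FishCase], path: str | Path) -> None:
    rows = [
        {
            "sample": case.sample_id, "cell_index": i,
            "n_target": cell.n_target, "n_reference": cell.n_reference,
        }
        for case in cases
        for i, cell in enumerate(case.cells)
    ]
    _write(pd.DataFrame(rows), path)


def read_fish_cells(path: str | Path) -> list[FishCase]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    cases = []
    for sample, grp in df.groupby("sample", sort=True):
        grp = grp.sort_values("cell_index")
        cells = tuple(
            FishCell(int(r.n_target), int(r.n_reference))
            for r in grp.itertuples(index=False)
        )
        cases.append(FishCase(sample_id=sample, cells=cells))
    return cases


def write_fish_results(results: Sequence[FishResult], path: str | Path) -> None:
    rows = [
        {
            "sample": r.sample_id, "n_cells": r.n_cells,
            "ratio": f"{r.ratio:.6f}", "call": r.call,
            "sub_threshold": int(r.sub_threshold),
        }
        for r in results
    ]
    _write(pd.DataFrame(rows), path)


def read_fish_results(path: str | Path) -> list[FishResult]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return [
        FishResult(
            sample_id=r.sample, n_cells=int(r.n_cells), ratio=float(r.ratio),
            call=r.call, sub_threshold=bool(int(r.sub_threshold)),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# expression / IHC / integration
# ---------------------------------------------------------------------------

def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    rows = [
        {"gene": r.gene, "log2fc": f"{r.log2fc:.6f}", "padj": f"{r.padj:.6g}"}
        for r in records
    ]
    _write(pd.DataFrame(rows), path)


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return [DERecord(r.gene, float(r.log2fc), float(r.padj)) for r in df.itertuples(index=False)]


def write_family_genes(genes: Sequence[str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def read_family_genes(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_ihc_scores(scores: Sequence[IhcScore], path: str | Path) -> None:
    rows = [
        {"sample": s.sample_id, "pct_positive_cells": f"{s.pct_positive_cells:.2f}", "bin": s.bin}
        for s in scores
    ]
    _write(pd.DataFrame(rows), path)


def read_ihc_scores(path: str | Path) -> list[IhcScore]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return [make_ihc_score(r.sample, float(r.pct_positive_cells)) for r in df.itertuples(index=False)]


def write_snv_evidence(records: Sequence[dict], path: str | Path) -> None:
    rows = [
        {
            "sample": r["sample_id"], "gene": r["gene"],
            "truncating_snv": int(bool(r["truncating_snv"])), "loh": int(bool(r["loh"])),
        }
        for r in records
    ]
    _write(pd.DataFrame(rows, columns=["sample", "gene", "truncating_snv", "loh"]), path)


def read_snv_evidence(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    return [
        {
            "sample_id": r.sample, "gene": r.gene,
            "truncating_snv": bool(int(r.truncating_snv)), "loh": bool(int(r.loh)),
        }
        for r in df.itertuples(index=False)
    ]


def write_integrated(statuses: Sequence[SampleGeneStatus], path: str | Path) -> None:
    rows = [
        {
            "sample": s.sample_id, "gene": s.gene,
            "array_status": s.array_status, "fish_status": s.fish_status,
            "truncating_snv": int(s.truncating_snv), "loh": int(s.loh_at_locus),
            "final_status": s.final_status, "evidence": s.evidence_note,
        }
        for s in statuses
    ]
    _write(pd.DataFrame(rows), path)


def write_cohort_summary(summary: CohortSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "n_samples": summary.n_samples, "n_homo": summary.n_homo,
                "n_het": summary.n_het, "n_no_loss": summary.n_no_loss,
                "pct_homo": summary.pct_homo, "pct_het": summary.pct_het,
                "pct_any_loss": summary.pct_any_loss,
            }
        ]
    )
    _write(df, path)


def write_variant_truth(labels: Sequence[str], path: str | Path) -> None:
    _write(pd.DataFrame({"record_index": range(len(labels)), "label": list(labels)}), path)


def read_variant_truth(path: str | Path) -> list[str]:
    return pd.read_csv(path, sep="\t")["label"].tolist()


def write_cn_truth(states: dict, path: str | Path) -> None:
    rows = [
        {"sample": sample, "gene": gene, "state": state}
        for (sample, gene), state in sorted(states.items())
    ]
    _write(pd.DataFrame(rows), path)


def read_cn_truth(path: str | Path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    return {(r.sample, r.gene): r.state for r in df.itertuples(index=False)}
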