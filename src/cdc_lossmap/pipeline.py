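"""End-to-end pipeline: simulate (optional) -> filter variants -> call
copy-number loss -> FISH -> integrate -> expression/IHC summaries.

A run writes every stage's table plus a manifest (seed, parameter values,
SHA-256 checksums of inputs and outputs) and a human-readable report. The
manifest deliberately contains no wall-clock information, so two runs with
the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io
from ._util import round_half_up
from .cnv import CnThresholds, genome_loss_profile
from .cohort import SimConfig, simulate_cohort
from .expression import family_alteration_summary, ihc_cohort_fraction
from .fish import DEFAULT_MIN_CELLS, evaluate_case
from .integrate import (
    cohort_frequencies,
    integrate_cohort,
    snv_evidence_for_gene,
)
from .somatic import FilterParams, filter_candidates, summarize_calls

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    With ``simulate=True`` all inputs are generated into ``outdir/inputs``
    from ``sim`` and the path fields are ignored.
    """

    outdir: str = "cdc_lossmap_run"
    simulate: bool = True
    seed: int = 0
    gene: str = "CDKN2A"
    # external inputs (used when simulate=False)
    variants_path: Optional[str] = None
    segments_path: Optional[str] = None
    genes_bed_path: Optional[str] = None
    fish_cells_path: Optional[str] = None
    de_table_path: Optional[str] = None
    family_genes_path: Optional[str] = None
    ihc_path: Optional[str] = None
    snv_evidence_path: Optional[str] = None
    # stage parameters
    filter_params: FilterParams = field(default_factory=FilterParams)
    cn_thresholds: CnThresholds = field(default_factory=CnThresholds)
    fish_min_cells: int = DEFAULT_MIN_CELLS
    de_padj_cutoff: float = 0.05
    sim: SimConfig = field(default_factory=SimConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "filter_params" in kwargs:
            kwargs["filter_params"] = FilterParams(**kwargs["filter_params"])
        if "cn_thresholds" in kwargs:
            kwargs["cn_thresholds"] = CnThresholds(**kwargs["cn_thresholds"])
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        cfg = cls(**kwargs)
        if "sim" not in raw:
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    d.pop("gene_intervals", None)
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a result dict and writes all outputs.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs_dir = outdir / "inputs"
    report: dict = {"gene": config.gene, "seed": config.seed}

    # -- stage: simulate / load inputs --------------------------------------
    try:
        if config.simulate:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            cohort = simulate_cohort(sim)
            io.write_variants(cohort.variants, inputs_dir / "variants.tsv")
            io.write_variant_truth(
                cohort.variant_truth.variant_labels, inputs_dir / "variant_truth.tsv"
            )
            io.write_segments(cohort.segments, inputs_dir / "segments.seg")
            io.write_cn_truth(cohort.segment_truth.cn_states, inputs_dir / "cn_truth.tsv")
            io.write_gene_bed(sim.gene_intervals, inputs_dir / "genes.bed")
            io.write_fish_cells(cohort.fish_cases, inputs_dir / "fish_cells.tsv")
            io.write_de_table(cohort.de_table, inputs_dir / "de_table.tsv")
            io.write_family_genes(cohort.family_genes, inputs_dir / "family_genes.txt")
            io.write_ihc_scores(cohort.ihc_scores, inputs_dir / "ihc.tsv")
            snv_records = [
                {"sample_id": s, "gene": config.gene, "truncating_snv": False, "loh": False}
                for s in sim.sample_ids()
            ]
            io.write_snv_evidence(snv_records, inputs_dir / "snv_evidence.tsv")
            paths = {
                "variants": inputs_dir / "variants.tsv",
                "segments": inputs_dir / "segments.seg",
                "genes_bed": inputs_dir / "genes.bed",
                "fish_cells": inputs_dir / "fish_cells.tsv",
                "de_table": inputs_dir / "de_table.tsv",
                "family_genes": inputs_dir / "family_genes.txt",
                "ihc": inputs_dir / "ihc.tsv",
                "snv_evidence": inputs_dir / "snv_evidence.tsv",
            }
        else:
            paths = {
                "variants": Path(config.variants_path),
                "segments": Path(config.segments_path),
                "genes_bed": Path(config.genes_bed_path),
                "fish_cells": Path(config.fish_cells_path),
                "de_table": Path(config.de_table_path),
                "family_genes": Path(config.family_genes_path),
                "ihc": Path(config.ihc_path),
                "snv_evidence": Path(config.snv_evidence_path),
            }
            for name, p in paths.items():
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input {name}: {p}")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate" if config.simulate else "load-inputs", exc) from exc

    # -- stage: filter-variants ---------------------------------------------
    try:
        candidates = io.read_variants(paths["variants"])
        verdicts = filter_candidates(candidates, config.filter_params)
        io.write_verdicts(verdicts, outdir / "verdicts.tsv")
        call_summary = summarize_calls(verdicts)
        report["somatic_calls"] = call_summary
        log.info("filter-variants: %d/%d candidates somatic",
                 call_summary["total"], len(candidates))
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter-variants", exc) from exc

    # -- stage: call-loss ----------------------------------------------------
    try:
        segments = io.read_segments(paths["segments"])
        genes = io.read_gene_bed(paths["genes_bed"])
        profile = genome_loss_profile(segments, genes, config.cn_thresholds)
        io.write_gene_status(profile, outdir / "gene_status.tsv")
        report["cn_calls"] = {
            s: sum(1 for p in profile if p.status == s)
            for s in ("no_loss", "het_loss", "homo_loss")
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("call-loss", exc) from exc

    # -- stage: fish ---------------------------------------------------------
    try:
        fish_cases = io.read_fish_cells(paths["fish_cells"])
        fish_results = [
            evaluate_case(c.sample_id, c.cells, config.fish_min_cells)
            for c in fish_cases
        ]
        io.write_fish_results(fish_results, outdir / "fish_results.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("fish", exc) from exc

    # -- stage: integrate ----------------------------------------------------
    try:
        snv_records = io.read_snv_evidence(paths["snv_evidence"])
        array_by_sample = {
            p.sample_id: p.status for p in profile if p.gene == config.gene
        }
        fish_by_sample = {r.sample_id: r.call for r in fish_results}
        sample_ids = sorted(set(array_by_sample) | set(fish_by_sample))
        evidence = []
        for sid in sample_ids:
            trunc, loh = snv_evidence_for_gene(snv_records, sid, config.gene)
            evidence.append(
                {
                    "sample_id": sid,
                    "gene": config.gene,
                    "array_status": array_by_sample.get(sid, "not_assayed"),
                    "fish_status": fish_by_sample.get(sid, "not_assayed"),
                    "truncating_snv": trunc,
                    "loh_at_locus": loh,
                }
            )
        integrated = integrate_cohort(evidence, config.gene)
        summary = cohort_frequencies(integrated)
        io.write_integrated(integrated, outdir / "integrated.tsv")
        io.write_cohort_summary(summary, outdir / "cohort_summary.tsv")
        report["cohort"] = dataclasses.asdict(summary)
    except Exception as exc:  # noqa: BLE001
        raise StageError("integrate", exc) from exc

    # -- stage: slc-profile / ihc -------------------------------------------
    try:
        de_table = io.read_de_table(paths["de_table"])
        family = io.read_family_genes(paths["family_genes"])
        fam = family_alteration_summary(de_table, family, config.de_padj_cutoff)
        with open(outdir / "family_summary.tsv", "w") as fh:
            fh.write("family\tn_family\tn_up\tn_down\tn_altered\tpct_altered\n")
            fh.write(
                f"{fam.family_name}\t{fam.n_family}\t{fam.n_up}\t{fam.n_down}\t"
                f"{fam.n_altered}\t{fam.pct_altered}\n"
            )
        ihc_scores = io.read_ihc_scores(paths["ihc"])
        ihc_pct_high = ihc_cohort_fraction(ihc_scores)
        report["family"] = dataclasses.asdict(fam)
        report["ihc_pct_high"] = ihc_pct_high
    except Exception as exc:  # noqa: BLE001
        raise StageError("slc-profile", exc) from exc

    # -- manifest + report ---------------------------------------------------
    output_files = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name not in ("manifest.json", "report.txt")
    )
    manifest = {
        "seed": config.seed,
        "gene": config.gene,
        "parameters": {
            "filter_params": _params_dict(config.filter_params),
            "cn_thresholds": _params_dict(config.cn_thresholds),
            "fish_min_cells": config.fish_min_cells,
            "de_padj_cutoff": config.de_padj_cutoff,
            "simulate": config.simulate,
            "sim": _params_dict(config.sim) if config.simulate else None,
        },
        "inputs": {name: _sha256(Path(p)) for name, p in sorted(paths.items())},
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in output_files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    lines = [
        f"gene: {config.gene}   seed: {config.seed}",
        f"somatic calls: {report['somatic_calls']['total']} "
        f"(missense {report['somatic_calls']['missense']}, "
        f"nonsense {report['somatic_calls']['nonsense']}, "
        f"frameshift {report['somatic_calls']['frameshift']}, "
        f"protein_deletion {report['somatic_calls']['protein_deletion']}, "
        f"other {report['somatic_calls']['other']})",
        f"copy-number calls: {report['cn_calls']}",
        f"cohort {config.gene}: {report['cohort']['n_homo']} homozygous "
        f"({report['cohort']['pct_homo']}%), {report['cohort']['n_het']} heterozygous "
        f"({report['cohort']['pct_het']}%), any loss {report['cohort']['pct_any_loss']}% "
        f"of {report['cohort']['n_samples']} samples",
        f"family {report['family']['family_name']}: {report['family']['n_altered']} of "
        f"{report['family']['n_family']} altered ({report['family']['pct_altered']}%), "
        f"{report['family']['n_up']} up / {report['family']['n_down']} down",
        f"IHC high: {report['ihc_pct_high']}% of cases",
    ]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    report["outdir"] = str(outdir)
    return report


def recovery_against_truth(outdir: str | Path) -> dict:
    """Compare a simulated run's somatic verdicts with the truth sidecar.

    Returns sensitivity over somatic sites and the pass-through count per
    non-somatic label.
    """
    outdir = Path(outdir)
    import pandas as pd

    verdicts = pd.read_csv(outdir / "verdicts.tsv", sep="\t")
    labels = io.read_variant_truth(outdir / "inputs" / "variant_truth.tsv")
    verdicts["label"] = labels
    somatic = verdicts[verdicts["label"] == "somatic"]
    out = {
        "sensitivity": round_half_up(
            float(somatic["IS_SOMATIC"].mean()) if len(somatic) else 0.0, 4
        ),
        "n_somatic": int(len(somatic)),
    }
    for label in ("germline", "artifact_strand", "artifact_homopolymer"):
        sub = verdicts[verdicts["label"] == label]
        out[f"passthrough_{label}"] = int(sub["IS_SOMATIC"].sum())
    return out
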