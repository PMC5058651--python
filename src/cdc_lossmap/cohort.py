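"""Synthetic tumor/normal cohort generator with known ground truth.

Every downstream stage (somatic filtering, copy-number loss calling, FISH
classification, integration, expression profiling) is exercised against
data produced here, so each generator emits a truth sidecar alongside its
records:

* ``simulate_variants`` — candidate SNVs with stranded tumor/normal read
  counts drawn from binomial sampling: somatic sites at a configured VAF
  with a clean paired normal, germline heterozygous sites at ~50% in both
  samples, and artifact sites that are either single-strand or sit next to
  a homopolymer run.
* ``simulate_segments`` — per-sample logR segments with a focal segment
  over each gene whose centre reflects the configured copy state
  (0.0 / -0.7 / -2.0 for no loss / single-copy / biallelic loss) plus
  neutral flanks; LOH flags accompany loss states.
* ``simulate_fish`` — per-cell probe counts with base (target, reference)
  of (2,2), (1,2) or (0,2) by state and independent +/-1 count perturbation
  with probability ``fish_noise`` (floored at 0).
* ``simulate_de_table`` — a differential-expression table with an exact
  configured number of significantly up- and down-regulated family genes.
* ``simulate_ihc`` / ``simulate_indel_reads`` — IHC percent-positive scores
  with configured bin membership, and indel read sets with per-read
  provenance for the realignment filter.

Each generator draws from its own child stream of the master seed, so
enlarging one table never shifts another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cnv import CN_STATES, GeneInterval, Segment
from .expression import DERecord, IhcScore, make_ihc_score
from .fish import FishCase, FishCell
from .somatic import AlignedRead, IndelReadSet, StrandedAlleleCounts, VariantCandidate

BASES = "ACGT"
VARIANT_LABELS = ("somatic", "germline", "artifact_strand", "artifact_homopolymer")

# streams of the master seed, one per generator
_STREAMS = {"variants": 0, "segments": 1, "fish": 2, "de": 3, "ihc": 4, "reads": 5}

# hg19 locus of CDKN2A, the headline deletion target
DEFAULT_GENES = (GeneInterval("CDKN2A", "chr9", 21_967_752, 21_995_043),)

# weights for somatic consequence labels, proportional to the published
# 325 missense / 24 nonsense / 17 frameshift / 2 protein-deletion split
_CONSEQ = ("missense", "nonsense", "frameshift", "protein_deletion")
_CONSEQ_W = (325.0 / 368, 24.0 / 368, 17.0 / 368, 2.0 / 368)


def default_cn_truth(
    n_samples: int = 16, n_homo: int = 8, n_het: int = 2, gene: str = "CDKN2A"
) -> dict[str, dict[str, str]]:
    """Per-sample copy-state truth for the default cohort: 8 biallelic,
    2 single-copy and 6 intact CDKN2A loci among 16 cases."""
    if n_homo + n_het > n_samples:
        raise ValueError("n_homo + n_het cannot exceed n_samples")
    truth = {}
    for i in range(n_samples):
        state = "homo_loss" if i < n_homo else "het_loss" if i < n_homo + n_het else "no_loss"
        truth[f"CDC{i + 1:02d}"] = {gene: state}
    return truth


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the scenario the pipeline is benchmarked on: a
    16-sample cohort with 8/2/6 biallelic/single-copy/intact CDKN2A states,
    200 somatic sites at VAF 0.3 and depth 100 with 200 germline and 100
    artifact sites, 200 FISH cells per case at 5% count noise, and an SLC
    family of 300 genes with 41 up- and 95 down-regulated members.
    """

    n_samples: int = 16
    # variant sites
    n_somatic_sites: int = 200
    n_germline_sites: int = 200
    n_artifact_sites: int = 100
    tumor_depth: int = 100
    normal_depth: int = 100
    somatic_vaf: float = 0.3
    sequencing_error_rate: float = 0.0
    strand_bias_prob: float = 0.5
    homopolymer_artifact_prob: float = 0.5
    context_k: int = 10
    homopolymer_len: int = 6
    # copy number
    cn_truth: dict[str, dict[str, str]] = field(default_factory=default_cn_truth)
    gene_intervals: tuple[GeneInterval, ...] = DEFAULT_GENES
    logr_centers: dict[str, float] = field(
        default_factory=lambda: {"no_loss": 0.0, "het_loss": -0.7, "homo_loss": -2.0}
    )
    logr_sd: float = 0.1
    # FISH
    fish_noise: float = 0.05
    fish_cells: int = 200
    # expression
    de_family_up: int = 41
    de_family_down: int = 95
    family_size: int = 300
    n_filler_genes: int = 200
    family_genes: Optional[tuple[str, ...]] = None
    # IHC
    ihc_n_high: int = 12
    ihc_n_low: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_samples,
            self.n_somatic_sites,
            self.n_germline_sites,
            self.n_artifact_sites,
            self.de_family_up,
            self.de_family_down,
            self.family_size,
            self.n_filler_genes,
            self.ihc_n_high,
            self.ihc_n_low,
            self.fish_cells,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if self.tumor_depth <= 0 or self.normal_depth <= 0:
            raise ValueError("read depths must be positive")
        if not 0.0 < self.somatic_vaf <= 1.0:
            raise ValueError("somatic_vaf must be in (0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        if not 0.0 <= self.fish_noise < 0.5:
            raise ValueError("fish_noise must be in [0, 0.5)")
        for name in ("strand_bias_prob", "homopolymer_artifact_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.strand_bias_prob + self.homopolymer_artifact_prob > 1.0 + 1e-12:
            raise ValueError("artifact type probabilities must sum to <= 1")
        if self.de_family_up + self.de_family_down > self.family_size:
            raise ValueError("de_family_up + de_family_down cannot exceed family_size")
        if self.context_k < 1:
            raise ValueError("context_k must be >= 1")
        if self.homopolymer_len < 2:
            raise ValueError("homopolymer_len must be >= 2")
        for sample, genes in self.cn_truth.items():
            for gene, state in genes.items():
                if state not in CN_STATES:
                    raise ValueError(f"invalid copy state {state!r} for {sample}/{gene}")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one named stream of the master seed."""
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def sample_ids(self) -> list[str]:
        if self.cn_truth:
            return sorted(self.cn_truth)
        return [f"CDC{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class SimTruth:
    """Ground-truth sidecar; each generator fills its own field."""

    variant_labels: Optional[list[str]] = None
    cn_states: Optional[dict[tuple[str, str], str]] = None
    de_direction: Optional[dict[str, str]] = None
    fish_state: Optional[str] = None
    ihc_bins: Optional[dict[str, str]] = None
    read_provenance: Optional[dict[str, list[str]]] = None


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _random_context(rng: np.random.Generator, k: int, max_run: int = 3) -> str:
    """Random 2k+1-mer with no single-base run longer than ``max_run``, so
    clean sites never trip the homopolymer filter."""
    out: list[str] = []
    for _ in range(2 * k + 1):
        choices = BASES
        if len(out) >= max_run and all(b == out[-1] for b in out[-max_run:]):
            choices = choices.replace(out[-1], "")
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _homopolymer_context(rng: np.random.Generator, k: int, run_len: int) -> str:
    """Context whose centre base is immediately followed by a homopolymer
    run of exactly ``run_len`` bases (slippage-prone site)."""
    ctx = list(_random_context(rng, k))
    centre = k
    run_base = BASES[rng.integers(4)]
    while run_base == ctx[centre]:
        run_base = BASES[rng.integers(4)]
    end = min(centre + run_len, 2 * k)
    for j in range(centre + 1, end + 1):
        ctx[j] = run_base
    if end + 1 <= 2 * k and ctx[end + 1] == run_base:
        ctx[end + 1] = BASES[(BASES.index(run_base) + 1) % 4]
    return "".join(ctx)


def _split_strands(rng: np.random.Generator, total: int) -> tuple[int, int]:
    fwd = int(rng.binomial(total, 0.5)) if total > 0 else 0
    return fwd, total - fwd


def _counts(
    rng: np.random.Generator, mean_depth: int, alt_fraction: float
) -> StrandedAlleleCounts:
    depth = max(int(rng.poisson(mean_depth)), 1)
    alt = int(rng.binomial(depth, alt_fraction)) if alt_fraction > 0 else 0
    ref = depth - alt
    alt_fwd, alt_rev = _split_strands(rng, alt)
    ref_fwd, ref_rev = _split_strands(rng, ref)
    return StrandedAlleleCounts(ref_fwd, ref_rev, alt_fwd, alt_rev)


def simulate_variants(config: SimConfig) -> tuple[list[VariantCandidate], SimTruth]:
    """Emit candidate SNVs with truth labels.

    One record per configured site; somatic sites draw tumor alt reads
    binomially at ``somatic_vaf`` (normal alt only via the sequencing-error
    rate, default 0), germline sites sit at ~50% VAF in both samples,
    single-strand artifacts put every alt read on one strand, and
    homopolymer artifacts carry a run of ``homopolymer_len`` adjacent to
    the variant base.
    """
    rng = config.rng("variants")
    samples = config.sample_ids() or ["CDC01"]
    k = config.context_k
    err = config.sequencing_error_rate

    plan: list[str] = (
        ["somatic"] * config.n_somatic_sites
        + ["germline"] * config.n_germline_sites
        + ["artifact"] * config.n_artifact_sites
    )
    candidates: list[VariantCandidate] = []
    labels: list[str] = []
    for idx, kind in enumerate(plan):
        sample = samples[idx % len(samples)]
        pos = 10_000 + idx * 100

        label = kind
        if kind == "artifact":
            u = rng.random()
            label = (
                "artifact_strand"
                if u < config.strand_bias_prob
                or u >= config.strand_bias_prob + config.homopolymer_artifact_prob
                else "artifact_homopolymer"
            )

        if label == "artifact_homopolymer":
            context = _homopolymer_context(rng, k, config.homopolymer_len)
        else:
            context = _random_context(rng, k)
        ref = context[k]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]

        if label == "somatic":
            tumor = _counts(rng, config.tumor_depth, config.somatic_vaf)
            normal = _counts(rng, config.normal_depth, err)
            consequence = str(rng.choice(_CONSEQ, p=_CONSEQ_W))
        elif label == "germline":
            tumor = _counts(rng, config.tumor_depth, 0.5)
            normal = _counts(rng, config.normal_depth, 0.5)
            consequence = "other"
        else:  # artifacts: clean normal, tumor alt at the somatic VAF
            tumor = _counts(rng, config.tumor_depth, config.somatic_vaf)
            normal = _counts(rng, config.normal_depth, err)
            consequence = "other"
            if label == "artifact_strand":
                alt_total = tumor.alt
                if rng.random() < 0.5:
                    tumor = StrandedAlleleCounts(
                        tumor.ref_fwd, tumor.ref_rev, alt_total, 0
                    )
                else:
                    tumor = StrandedAlleleCounts(
                        tumor.ref_fwd, tumor.ref_rev, 0, alt_total
                    )

        candidates.append(
            VariantCandidate(
                sample_id=sample,
                chrom="chr1",
                pos=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_class="snv",
                tumor=tumor,
                normal=normal,
                context=context,
                consequence=consequence,
            )
        )
        labels.append(label)
    return candidates, SimTruth(variant_labels=labels)


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def simulate_segments(config: SimConfig) -> tuple[list[Segment], SimTruth]:
    """Emit per-sample logR segments reflecting ``cn_truth``.

    Each gene gets a focal segment (gene span padded by 50 kb) whose logR is
    drawn from a normal around the state's centre (sd ``logr_sd``; 0 gives
    noise-free segments) plus two neutral flanking segments. LOH is flagged
    on loss-state focal segments.
    """
    rng = config.rng("segments")
    intervals = {g.gene: g for g in config.gene_intervals}
    pad, flank = 50_000, 1_000_000
    segments: list[Segment] = []
    cn_states: dict[tuple[str, str], str] = {}

    for sample in sorted(config.cn_truth):
        for gene in sorted(config.cn_truth[sample]):
            state = config.cn_truth[sample][gene]
            cn_states[(sample, gene)] = state
            if gene not in intervals:
                raise ValueError(f"no interval known for gene {gene!r}")
            locus = intervals[gene]

            def draw(centre: float) -> float:
                if config.logr_sd == 0:
                    return centre
                return float(rng.normal(centre, config.logr_sd))

            focal_start = max(locus.start - pad, 1)
            focal_end = locus.end + pad
            segments.append(
                Segment(
                    sample_id=sample,
                    chrom=locus.chrom,
                    start=focal_start,
                    end=focal_end,
                    logr=draw(config.logr_centers[state]),
                    loh=state != "no_loss",
                )
            )
            if focal_start > 1:
                segments.append(
                    Segment(
                        sample_id=sample,
                        chrom=locus.chrom,
                        start=max(focal_start - flank, 1),
                        end=focal_start - 1,
                        logr=draw(0.0),
                        loh=False,
                    )
                )
            segments.append(
                Segment(
                    sample_id=sample,
                    chrom=locus.chrom,
                    start=focal_end + 1,
                    end=focal_end + flank,
                    logr=draw(0.0),
                    loh=False,
                )
            )
    return segments, SimTruth(cn_states=cn_states)


# ---------------------------------------------------------------------------
# FISH
# ---------------------------------------------------------------------------

_FISH_BASE = {"no_loss": (2, 2), "het_loss": (1, 2), "homo_loss": (0, 2)}


def simulate_fish(
    config: SimConfig,
    true_state: str,
    n_cells: Optional[int] = None,
    sample_id: str = "CDC01",
    rng: Optional[np.random.Generator] = None,
) -> tuple[FishCase, SimTruth]:
    """Emit per-cell probe counts for one case in a known copy state.

    Base counts per cell are (2,2) / (1,2) / (0,2); each count is
    independently perturbed by +/-1 with probability ``fish_noise`` and
    floored at zero.
    """
    if true_state not in _FISH_BASE:
        raise ValueError(f"unknown state {true_state!r}")
    n = config.fish_cells if n_cells is None else n_cells
    if n < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = config.rng("fish")

    base_t, base_r = _FISH_BASE[true_state]
    target = np.full(n, base_t, dtype=np.int64)
    reference = np.full(n, base_r, dtype=np.int64)
    for arr in (target, reference):
        perturb = rng.random(n) < config.fish_noise
        sign = rng.choice([-1, 1], size=n)
        arr += np.where(perturb, sign, 0)
        np.maximum(arr, 0, out=arr)

    cells = tuple(FishCell(int(t), int(r)) for t, r in zip(target, reference))
    return FishCase(sample_id=sample_id, cells=cells), SimTruth(fish_state=true_state)


def simulate_fish_cohort(config: SimConfig, gene: str = "CDKN2A") -> tuple[list[FishCase], SimTruth]:
    """One FISH case per sample, states taken from ``cn_truth``."""
    rng = config.rng("fish")
    cases = []
    states: dict[tuple[str, str], str] = {}
    for sample in sorted(config.cn_truth):
        state = config.cn_truth[sample][gene]
        case, _ = simulate_fish(config, state, sample_id=sample, rng=rng)
        cases.append(case)
        states[(sample, gene)] = state
    return cases, SimTruth(cn_states=states)


# ---------------------------------------------------------------------------
# differential expression / IHC
# ---------------------------------------------------------------------------

def simulate_de_table(config: SimConfig) -> tuple[list[DERecord], SimTruth]:
    """Emit a DE table with exactly ``de_family_up`` significant up- and
    ``de_family_down`` significant down-regulated family genes; the rest of
    the family is non-significant, plus non-family filler genes."""
    rng = config.rng("de")
    if config.family_genes is not None:
        family = list(config.family_genes)
        if len(family) != config.family_size:
            raise ValueError("family_genes length must equal family_size")
    else:
        family = [f"SLCX{i + 1:03d}" for i in range(config.family_size)]

    order = rng.permutation(config.family_size)
    up_idx = set(order[: config.de_family_up].tolist())
    down_idx = set(
        order[config.de_family_up : config.de_family_up + config.de_family_down].tolist()
    )

    records: list[DERecord] = []
    direction: dict[str, str] = {}
    for i, gene in enumerate(family):
        if i in up_idx:
            rec = DERecord(gene, float(rng.uniform(0.5, 8.5)), float(rng.uniform(0, 0.05) * 0.999))
            direction[gene] = "up"
        elif i in down_idx:
            rec = DERecord(gene, float(-rng.uniform(0.5, 8.5)), float(rng.uniform(0, 0.05) * 0.999))
            direction[gene] = "down"
        else:
            rec = DERecord(gene, float(rng.normal(0, 0.3)), float(rng.uniform(0.05, 1.0)))
            direction[gene] = "none"
        records.append(rec)

    for j in range(config.n_filler_genes):
        sig = rng.random() < 0.5
        lfc = float(rng.normal(0, 2.0))
        padj = float(rng.uniform(0, 0.05) * 0.999) if sig else float(rng.uniform(0.05, 1.0))
        records.append(DERecord(f"FILLER{j + 1:04d}", lfc, padj))
    return records, SimTruth(de_direction=direction)


def simulate_ihc(config: SimConfig, n_cases: int = 15) -> tuple[list[IhcScore], SimTruth]:
    """IHC percent-positive scores: ``ihc_n_high`` cases in the high bin
    (80-100%), ``ihc_n_low`` in the low bin (2-20%), any remainder
    intermediate."""
    if config.ihc_n_high + config.ihc_n_low > n_cases:
        raise ValueError("ihc_n_high + ihc_n_low cannot exceed n_cases")
    rng = config.rng("ihc")
    scores: list[IhcScore] = []
    bins: dict[str, str] = {}
    for i in range(n_cases):
        sid = f"CDC{i + 1:02d}"
        if i < config.ihc_n_high:
            val = float(rng.uniform(80, 100))
        elif i < config.ihc_n_high + config.ihc_n_low:
            val = float(rng.uniform(2, 20))
        else:
            val = float(rng.uniform(25, 75))
        score = make_ihc_score(sid, val)
        scores.append(score)
        bins[sid] = score.bin
    return scores, SimTruth(ihc_bins=bins)


# ---------------------------------------------------------------------------
# indel read sets
# ---------------------------------------------------------------------------

def simulate_indel_reads(
    config: SimConfig,
    ref_allele: str,
    alt_allele: str,
    n_tumor_mutant: int = 10,
    n_tumor_reference: int = 10,
    n_normal_reference: int = 20,
    window_half: int = 30,
    read_length: int = 25,
    rng: Optional[np.random.Generator] = None,
) -> tuple[IndelReadSet, SimTruth]:
    """Build an indel read set with per-read provenance labels.

    Mutant reads are copied from the mutant template (reference window with
    ``alt_allele`` substituted for ``ref_allele``), reference reads from the
    window itself; offsets are reported in reference-window coordinates as
    the realignment filter expects.
    """
    if rng is None:
        rng = config.rng("reads")
    window = _random_context(rng, window_half)
    i = window_half  # indel at the window centre
    window = window[:i] + ref_allele + window[i + len(ref_allele):]
    window = window[: 2 * window_half + 1]
    i = min(i, len(window) - len(ref_allele))
    mutant = window[:i] + alt_allele + window[i + len(ref_allele):]
    shift = len(alt_allele) - len(ref_allele)

    def sample_read(template: str, from_mutant: bool) -> AlignedRead:
        lo = max(i - read_length + 1, 0)
        hi = min(i, len(template) - read_length)
        start = int(rng.integers(lo, max(hi, lo) + 1))
        seq = template[start : start + read_length]
        offset = start
        if from_mutant and start > i:
            offset = start - shift
        return AlignedRead(seq, offset)

    tumor: list[AlignedRead] = []
    provenance: dict[str, list[str]] = {"tumor": [], "normal": []}
    for _ in range(n_tumor_mutant):
        tumor.append(sample_read(mutant, True))
        provenance["tumor"].append("mutant")
    for _ in range(n_tumor_reference):
        tumor.append(sample_read(window, False))
        provenance["tumor"].append("reference")
    normal = []
    for _ in range(n_normal_reference):
        normal.append(sample_read(window, False))
        provenance["normal"].append("reference")

    reads = IndelReadSet(
        tumor_reads=tuple(tumor),
        normal_reads=tuple(normal),
        window=window,
        indel_offset=i,
    )
    return reads, SimTruth(read_provenance=provenance)


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """Everything one pipeline run consumes, with truth sidecars."""

    config: SimConfig
    variants: list[VariantCandidate]
    variant_truth: SimTruth
    segments: list[Segment]
    segment_truth: SimTruth
    fish_cases: list[FishCase]
    fish_truth: SimTruth
    de_table: list[DERecord]
    de_truth: SimTruth
    ihc_scores: list[IhcScore]
    ihc_truth: SimTruth
    family_genes: list[str]


def simulate_cohort(config: SimConfig) -> CohortData:
    """Run all generators under one master seed."""
    variants, v_truth = simulate_variants(config)
    segments, s_truth = simulate_segments(config)
    fish_cases, f_truth = simulate_fish_cohort(config)
    de_table, d_truth = simulate_de_table(config)
    ihc_scores, i_truth = simulate_ihc(
        config, n_cases=max(config.ihc_n_high + config.ihc_n_low, 15)
    )
    family = (
        list(config.family_genes)
        if config.family_genes is not None
        else [f"SLCX{i + 1:03d}" for i in range(config.family_size)]
    )
    return CohortData(
        config=config,
        variants=variants,
        variant_truth=v_truth,
        segments=segments,
        segment_truth=s_truth,
        fish_cases=fish_cases,
        fish_truth=f_truth,
        de_table=de_table,
        de_truth=d_truth,
        ihc_scores=ihc_scores,
        ihc_truth=i_truth,
        family_genes=family,
    )
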