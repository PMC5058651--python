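"""Gene-level copy-number loss calling from logR segments."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdc_lossmap import (
    CnThresholds,
    GeneInterval,
    Segment,
    SimConfig,
    call_gene_loss,
    genome_loss_profile,
    overlaps,
    simulate_segments,
)

GENE = GeneInterval("CDKN2A", "chr9", 21_967_752, 21_995_043)


def seg(start, end, logr, chrom="chr9", sample="S1", loh=False):
    return Segment(sample, chrom, start, end, logr, loh)


class TestOverlap:
    @pytest.mark.parametrize(
        "s_start,s_end,g_start,g_end,expected",
        [
            (100, 200, 200, 300, True),   # single shared base
            (100, 199, 200, 300, False),  # abutting, 1-based inclusive
            (150, 250, 100, 300, True),   # nested
            (301, 400, 100, 300, False),
        ],
    )
    def test_inclusive_interval_overlap(self, s_start, s_end, g_start, g_end, expected):
        gene = GeneInterval("G", "chr9", g_start, g_end)
        assert overlaps(seg(s_start, s_end, 0.0), gene) is expected

    def test_different_chromosomes_never_overlap(self):
        gene = GeneInterval("G", "chr9", 150, 250)
        assert overlaps(seg(100, 300, 0.0, chrom="chr8"), gene) is False

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    def test_overlap_is_symmetric_in_intervals(self, a, b, c, d):
        s1, e1 = min(a, b), max(a, b)
        s2, e2 = min(c, d), max(c, d)
        fwd = overlaps(seg(s1, e1, 0.0), GeneInterval("G", "chr9", s2, e2))
        rev = overlaps(seg(s2, e2, 0.0), GeneInterval("G", "chr9", s1, e1))
        assert fwd is rev


class TestCallGeneLoss:
    @pytest.mark.parametrize(
        "logr,expected",
        [(-0.6, "het_loss"), (-0.3, "no_loss"), (-2.1, "homo_loss"),
         (-0.4, "no_loss"), (-1.0, "het_loss"), (0.3, "no_loss")],
    )
    def test_threshold_bins_with_strict_less_than(self, logr, expected):
        status = call_gene_loss([seg(GENE.start, GENE.end, logr)], GENE)
        assert status.status == expected

    def test_minimum_logr_wins_over_broad_neutral_segment(self):
        """A focal deletion inside a broad neutral segment must not be
        averaged away."""
        segments = [
            seg(1, 40_000_000, 0.01),
            seg(GENE.start + 1000, GENE.start + 5000, -2.3),
        ]
        status = call_gene_loss(segments, GENE)
        assert status.status == "homo_loss"
        assert status.min_overlapping_logr == -2.3

    def test_uncovered_locus_reports_no_loss_with_none(self):
        status = call_gene_loss([seg(1, 100, -3.0, chrom="chr8")], GENE)
        assert status.status == "no_loss"
        assert status.min_overlapping_logr is None

    def test_loh_flag_from_any_overlapping_segment(self):
        segments = [
            seg(GENE.start, GENE.end, -0.7, loh=True),
            seg(GENE.end + 1, GENE.end + 100, 0.0, loh=False),
        ]
        assert call_gene_loss(segments, GENE).loh is True

    def test_mixed_sample_segments_rejected(self):
        with pytest.raises(ValueError):
            call_gene_loss(
                [seg(1, 10, 0.0, sample="A"), seg(1, 10, 0.0, sample="B")], GENE
            )

    @given(delta=st.floats(0.0, 3.0))
    def test_status_monotone_in_logr(self, delta):
        """Lowering an overlapping segment's logR never moves the call
        toward no_loss."""
        order = {"no_loss": 0, "het_loss": 1, "homo_loss": 2}
        hi = call_gene_loss([seg(GENE.start, GENE.end, -0.2)], GENE)
        lo = call_gene_loss([seg(GENE.start, GENE.end, -0.2 - delta)], GENE)
        assert order[lo.status] >= order[hi.status]


class TestGenomeProfile:
    def test_empty_gene_list_gives_empty_profile(self):
        assert genome_loss_profile([seg(1, 10, 0.0)], []) == []

    def test_one_called_one_uncovered(self):
        genes = [
            GeneInterval("A", "chr9", 100, 200),
            GeneInterval("B", "chr10", 100, 200),
        ]
        profile = genome_loss_profile([seg(50, 500, -0.7)], genes)
        by_gene = {p.gene: p for p in profile}
        assert by_gene["A"].status == "het_loss"
        assert by_gene["B"].status == "no_loss"
        assert by_gene["B"].min_overlapping_logr is None

    def test_order_deterministic_by_sample_then_gene(self):
        segments = [seg(1, 10, 0.0, sample="S2"), seg(1, 10, 0.0, sample="S1")]
        genes = [GeneInterval("B", "chr9", 1, 5), GeneInterval("A", "chr9", 1, 5)]
        profile = genome_loss_profile(segments, genes)
        assert [(p.sample_id, p.gene) for p in profile] == [
            ("S1", "A"), ("S1", "B"), ("S2", "A"), ("S2", "B"),
        ]

    def test_invariant_to_segment_list_order(self):
        segments = [
            seg(GENE.start, GENE.end, -2.0),
            seg(1, GENE.start - 1, 0.0),
        ]
        fwd = genome_loss_profile(segments, [GENE])
        rev = genome_loss_profile(segments[::-1], [GENE])
        assert fwd == rev


class TestSimulatedRecovery:
    def test_noise_free_segments_recover_truth_exactly(self):
        """Criterion check at module level: with logR sd 0, every
        sample x gene call equals the configured copy state."""
        config = SimConfig(seed=11, logr_sd=0.0)
        segments, truth = simulate_segments(config)
        profile = genome_loss_profile(segments, list(config.gene_intervals))
        assert len(profile) == len(truth.cn_states)
        for status in profile:
            assert status.status == truth.cn_states[(status.sample_id, status.gene)]

    def test_noisy_homozygous_segment_stays_deep(self):
        config = SimConfig(seed=2)  # logr_sd 0.1, homo centre -2.0
        segments, truth = simulate_segments(config)
        homo_samples = {s for (s, g), st_ in truth.cn_states.items() if st_ == "homo_loss"}
        gene = config.gene_intervals[0]
        for sample in homo_samples:
            focal = [
                s for s in segments
                if s.sample_id == sample and overlaps(s, gene)
            ]
            assert min(s.logr for s in focal) < -1.0

    def test_all_no_loss_truth_emits_nothing_below_loss_threshold(self):
        truth = {f"S{i}": {"CDKN2A": "no_loss"} for i in range(4)}
        config = SimConfig(seed=3, cn_truth=truth)
        segments, _ = simulate_segments(config)
        gene = config.gene_intervals[0]
        assert all(s.logr > -0.4 for s in segments if overlaps(s, gene))

    def test_thresholds_validate(self):
        with pytest.raises(ValueError):
            CnThresholds(loss_logr=-1.0, homo_logr=-0.4)
        cfg = dataclasses.replace(SimConfig(seed=1), logr_sd=0.0)
        assert cfg.logr_sd == 0.0
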