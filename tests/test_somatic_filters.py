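"""Unit and property tests for the tumor/normal somatic filter chain."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdc_lossmap import (
    AlignedRead,
    FilterParams,
    IndelReadSet,
    StrandedAlleleCounts,
    VariantCandidate,
    apply_somatic_filters,
    check_normal_absence,
    check_orientation,
    detect_homopolymer,
    fisher_enrichment_pvalue,
    fisher_tumor_enrichment,
    realign_indel_support,
    summarize_calls,
)
from cdc_lossmap.somatic import FilterVerdict

from .oracles import fisher_one_sided_exact


def sac(ref_fwd=0, ref_rev=0, alt_fwd=0, alt_rev=0):
    return StrandedAlleleCounts(ref_fwd, ref_rev, alt_fwd, alt_rev)


def make_candidate(
    tumor, normal, context="ACGTACGTACGTACGTACGTA", variant_class="snv",
    consequence="missense",
):
    return VariantCandidate(
        sample_id="S1", chrom="chr1", pos=1000, ref_allele="A", alt_allele="C",
        variant_class=variant_class, tumor=tumor, normal=normal,
        context=context, consequence=consequence,
    )


class TestFisher:
    def test_no_alt_anywhere_gives_p_one(self):
        assert fisher_tumor_enrichment(sac(5, 5), sac(5, 5)) == 1.0

    def test_identical_proportions_not_enriched(self):
        p = fisher_tumor_enrichment(sac(3, 2, 3, 2), sac(3, 2, 3, 2))
        assert p > 0.5

    @pytest.mark.parametrize(
        "t_alt,t_depth,n_alt,n_depth",
        [(10, 20, 0, 20), (5, 10, 1, 12), (0, 7, 3, 9), (15, 30, 15, 30), (1, 2, 0, 1)],
    )
    def test_matches_exact_enumeration_oracle(self, t_alt, t_depth, n_alt, n_depth):
        p = fisher_enrichment_pvalue(t_alt, t_depth, n_alt, n_depth)
        assert p == pytest.approx(
            fisher_one_sided_exact(t_alt, t_depth, n_alt, n_depth), abs=1e-9
        )

    def test_zero_depth_is_an_error_not_nan(self):
        with pytest.raises(ValueError):
            fisher_enrichment_pvalue(0, 0, 0, 10)
        with pytest.raises(ValueError):
            fisher_tumor_enrichment(sac(1, 1), sac(0, 0))

    @given(
        t_depth=st.integers(2, 40),
        n_depth=st.integers(1, 40),
        n_alt=st.integers(0, 10),
    )
    def test_monotone_in_tumor_alt_count(self, t_depth, n_depth, n_alt):
        """With fixed depths and normal counts, more tumor alt reads never
        increase the enrichment p-value."""
        n_alt = min(n_alt, n_depth)
        last = 1.1
        for t_alt in range(t_depth + 1):
            p = fisher_enrichment_pvalue(t_alt, t_depth, n_alt, n_depth)
            assert p <= last + 1e-12
            last = p


class TestSimpleCriteria:
    @pytest.mark.parametrize(
        "alt_total,max_allowed,expected",
        [(0, 0, True), (1, 0, False), (1, 1, True), (2, 1, False)],
    )
    def test_normal_absence_threshold_inclusive(self, alt_total, max_allowed, expected):
        normal = sac(10, 10, alt_total, 0)
        params = FilterParams(max_normal_alt_reads=max_allowed)
        assert check_normal_absence(normal, params) is expected

    @pytest.mark.parametrize(
        "alt_fwd,alt_rev,expected",
        [(3, 0, False), (0, 3, False), (2, 1, True), (0, 0, False), (1, 1, True)],
    )
    def test_orientation_requires_both_strands(self, alt_fwd, alt_rev, expected):
        assert check_orientation(sac(5, 5, alt_fwd, alt_rev)) is expected


class TestHomopolymer:
    @pytest.mark.parametrize(
        "context,expected",
        [
            ("CGTAAAAATGC", True),     # 5-A run covering the centre
            ("ACGTACGTACG", False),    # no run at all
            ("ACGAAAACGTA", False),    # run of 4 < threshold, at the centre
            ("AAAAACGATCGAT", False),  # 5-run 2 bp left of the centre
            ("ACGTACGTTTTTA", True),   # 5-run starting 1 bp right of the centre
        ],
    )
    def test_run_detection_near_centre(self, context, expected):
        assert detect_homopolymer(context) is expected

    def test_adjacency_window_is_one_base(self):
        # 13-mers, centre index 6; run at distance 2 is clean, distance 1 flags
        assert detect_homopolymer("ACGTACGATTTTT") is False  # run 8..12
        assert detect_homopolymer("ATTTTTACGATCG") is True   # run 1..5, end+1 == centre

    def test_rejects_non_dna_characters(self):
        with pytest.raises(ValueError):
            detect_homopolymer("ACGTAXGTACG")

    @given(st.text(alphabet="ACGT", min_size=11, max_size=11))
    def test_never_flags_without_long_run(self, context):
        longest = max(len(list(grp)) for _, grp in itertools.groupby(context))
        if longest < 5:
            assert detect_homopolymer(context, FilterParams()) is False


class TestIndelRealignment:
    WINDOW = "ACGTACGTGGCATTCAGGATCCTTGAAC"

    def reads_from(self, template, offsets, length=12):
        return tuple(
            AlignedRead(template[o : o + length], o) for o in offsets
        )

    def test_perfect_separation(self):
        """Tumor reads copied from the mutant template, normal from the
        reference: all tumor reads and no normal read support the indel."""
        ref, alt = "TGG", "T"  # 2-bp deletion
        i = self.WINDOW.index("TGG")
        mutant = self.WINDOW[:i] + alt + self.WINDOW[i + len(ref):]
        tumor_offsets = [0, 2, 4, 6]
        reads = IndelReadSet(
            tumor_reads=self.reads_from(mutant, tumor_offsets),
            normal_reads=self.reads_from(self.WINDOW, [0, 3, 5]),
            window=self.WINDOW,
            indel_offset=i,
        )
        assert realign_indel_support(reads, ref, alt) == (4, 0)

    def test_all_reference_reads_support_nothing(self):
        ref, alt = "TGG", "T"
        i = self.WINDOW.index("TGG")
        reads = IndelReadSet(
            tumor_reads=self.reads_from(self.WINDOW, [0, 2, 4]),
            normal_reads=self.reads_from(self.WINDOW, [1, 3]),
            window=self.WINDOW,
            indel_offset=i,
        )
        assert realign_indel_support(reads, ref, alt) == (0, 0)

    def test_insertion_support(self):
        ref, alt = "C", "CAAG"
        i = 10  # window[10] == 'C'
        assert self.WINDOW[i] == "C"
        mutant = self.WINDOW[:i] + alt + self.WINDOW[i + 1:]
        reads = IndelReadSet(
            tumor_reads=self.reads_from(mutant, [4, 6, 8]),
            normal_reads=self.reads_from(self.WINDOW, [4, 6]),
            window=self.WINDOW,
            indel_offset=i,
        )
        assert realign_indel_support(reads, ref, alt) == (3, 0)

    def test_mismatch_tie_counts_as_non_supporting(self):
        """A read equally distant from both templates gives no support."""
        window = "AAACCCGGGTTT"
        ref, alt = "CCC", "C"
        read = AlignedRead("NNNN".replace("N", "A") , 0)  # matches both prefixes
        reads = IndelReadSet((read,), (), window, 3)
        assert realign_indel_support(reads, ref, alt) == (0, 0)

    def test_generated_read_set_matches_provenance(self, study_config):
        from cdc_lossmap import simulate_indel_reads

        reads, truth = simulate_indel_reads(
            study_config, ref_allele="GGT", alt_allele="G",
            n_tumor_mutant=8, n_tumor_reference=5, n_normal_reference=10,
        )
        t_sup, n_sup = realign_indel_support(reads, "GGT", "G")
        assert t_sup == truth.read_provenance["tumor"].count("mutant") == 8
        assert n_sup == 0


class TestFilterChain:
    def test_clean_somatic_snv_passes_everything(self):
        cand = make_candidate(sac(22, 21, 8, 7), sac(25, 25, 0, 0))
        v = apply_somatic_filters(cand)
        assert v.is_somatic
        assert all(
            [v.pass_normal_absence, v.pass_fisher, v.pass_orientation,
             v.pass_homopolymer, v.pass_realignment]
        )

    def test_germline_het_fails_absence_and_fisher(self):
        cand = make_candidate(sac(13, 12, 12, 13), sac(12, 13, 13, 12))
        v = apply_somatic_filters(cand)
        assert not v.pass_normal_absence
        assert not v.pass_fisher
        assert not v.is_somatic

    def test_strand_artifact_fails_orientation_only(self):
        cand = make_candidate(sac(20, 20, 10, 0), sac(25, 25, 0, 0))
        v = apply_somatic_filters(cand)
        assert not v.pass_orientation
        assert v.pass_normal_absence and v.pass_fisher and v.pass_homopolymer
        assert not v.is_somatic

    def test_indel_without_reads_is_an_error(self):
        cand = VariantCandidate(
            sample_id="S1", chrom="chr1", pos=5, ref_allele="AT", alt_allele="A",
            variant_class="del", tumor=sac(10, 10, 5, 5), normal=sac(10, 10),
            context="ACGTACGTACG",
        )
        with pytest.raises(ValueError):
            apply_somatic_filters(cand)

    def test_is_somatic_is_conjunction_of_flags(self):
        cand = make_candidate(sac(22, 21, 8, 7), sac(25, 25, 0, 0))
        base = apply_somatic_filters(cand)
        assert base.is_somatic
        for flag in (
            "pass_normal_absence", "pass_fisher", "pass_orientation",
            "pass_homopolymer", "pass_realignment",
        ):
            kwargs = dict(
                candidate=cand,
                pass_normal_absence=base.pass_normal_absence,
                pass_fisher=base.pass_fisher,
                pass_orientation=base.pass_orientation,
                pass_homopolymer=base.pass_homopolymer,
                pass_realignment=base.pass_realignment,
                fisher_p=base.fisher_p,
            )
            kwargs[flag] = False
            assert FilterVerdict(**kwargs).is_somatic is False


class TestSummary:
    def test_empty_list_gives_zero_counts(self):
        counts = summarize_calls([])
        assert counts["total"] == 0 and counts["missense"] == 0

    def test_only_passing_candidates_are_counted(self):
        passing = apply_somatic_filters(
            make_candidate(sac(22, 21, 8, 7), sac(25, 25, 0, 0))
        )
        failing = apply_somatic_filters(
            make_candidate(sac(13, 12, 12, 13), sac(12, 13, 13, 12))
        )
        counts = summarize_calls([passing, passing, passing, failing])
        assert counts["missense"] == 3
        assert counts["total"] == 3
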