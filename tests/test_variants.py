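"""Variant filtering, subtraction, classification and consequences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trascan.errors import ReferenceMismatchError
from trascan.io import GenomicInterval, GeneModel, VariantCall
from trascan.variants import (
    ConsequenceAnnotator,
    FilterThresholds,
    classify_timepoints,
    filter_calls,
    left_align,
    subtract_germline,
)

from oracles import DictGenome, oracle_snv_consequence, random_gene_genome


def call(pos=100, ref="A", alt="T", rr=20, ar=10, sample="relapse",
         chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, rr, ar, sample)


class TestFilter:
    def test_vaf_bound_is_strict(self):
        """VAF of exactly 0.20 fails the 'more than 20%' condition."""
        kept, log = filter_calls([call(rr=20, ar=5)])
        assert kept == [] and log.rejected == {"low VAF": 1}

    def test_alt_support_bound_is_inclusive_at_five(self):
        kept, _ = filter_calls([call(rr=6, ar=4)])  # VAF 0.40 but 4 reads
        assert kept == []
        kept, _ = filter_calls([call(rr=14, ar=6)])  # VAF 0.30, 6 reads
        assert len(kept) == 1

    def test_zero_depth_rejected_without_division_error(self):
        kept, log = filter_calls([call(rr=0, ar=0)])
        assert kept == [] and log.rejected == {"zero depth": 1}

    def test_total_depth_rule_alternative(self):
        th = FilterThresholds(depth_rule="total")
        kept, _ = filter_calls([call(rr=0, ar=4)], th)  # depth 4 < 5
        assert kept == []
        kept, _ = filter_calls([call(rr=1, ar=4)], th)  # depth 5, VAF 0.8
        assert len(kept) == 1

    def test_order_preserved_and_idempotent(self):
        calls = [call(pos=p, rr=10, ar=7) for p in (5, 3, 9)]
        calls.insert(1, call(pos=7, rr=30, ar=4))
        kept, _ = filter_calls(calls)
        assert [v.pos for v in kept] == [5, 3, 9]
        again, _ = filter_calls(kept)
        assert again == kept


calls_strategy = st.lists(
    st.builds(
        call,
        pos=st.integers(1, 50),
        ref=st.sampled_from(["A", "C"]),
        alt=st.sampled_from(["G", "T"]),
        rr=st.integers(0, 60),
        ar=st.integers(0, 60),
    ),
    max_size=30,
)


class TestSubtraction:
    def test_matching_key_removed(self):
        v1, v2 = call(pos=10), call(pos=20)
        assert subtract_germline([v1, v2], [call(pos=20, sample="germline")]) \
            == [v1]

    def test_alt_allele_distinguishes(self):
        """G>T at a position is kept when germline holds G>A there."""
        tumor = [call(pos=10, ref="G", alt="T")]
        germ = [call(pos=10, ref="G", alt="A", sample="germline")]
        assert subtract_germline(tumor, germ) == tumor

    def test_superset_germline_empties_tumor(self):
        tumor = [call(pos=p) for p in (1, 2, 3)]
        germ = [call(pos=p, sample="germline") for p in (1, 2, 3, 4)]
        assert subtract_germline(tumor, germ) == []

    def test_read_counts_irrelevant_to_matching(self):
        tumor = [call(pos=10, rr=50, ar=25)]
        germ = [call(pos=10, rr=1, ar=1, sample="germline")]
        assert subtract_germline(tumor, germ) == []

    @settings(max_examples=50, derandomize=True)
    @given(tumor=calls_strategy, germ=calls_strategy)
    def test_conservation_against_set_oracle(self, tumor, germ):
        """|output| equals |tumor| minus the key matches, and equals a
        direct set-comprehension oracle."""
        out = subtract_germline(tumor, germ)
        gkeys = {g.key for g in germ}
        assert out == [v for v in tumor if v.key not in gkeys]
        n_match = sum(1 for v in tumor if v.key in gkeys)
        assert len(out) == len(tumor) - n_match


class TestClassifyTimepoints:
    def test_three_way_partition(self):
        both = call(pos=10)
        dx_only = call(pos=20, sample="diagnosis")
        rl_only = call(pos=30)
        part = classify_timepoints(
            [VariantCall("chr1", 10, "A", "T", 20, 10, "diagnosis"), dx_only],
            [both, rl_only],
        )
        assert [v.key for v in part.common] == [both.key]
        assert [v.key for v in part.additional] == [rl_only.key]
        assert [v.key for v in part.lost] == [dx_only.key]

    def test_duplicate_keys_collapse_to_max_alt_reads(self, caplog):
        dup1 = call(pos=10, ar=5)
        dup2 = call(pos=10, ar=9)
        part = classify_timepoints([], [dup1, dup2])
        assert part.additional == (dup2,)

    @settings(max_examples=50, derandomize=True)
    @given(dx=calls_strategy, rl=calls_strategy)
    def test_partition_covers_key_union_disjointly(self, dx, rl):
        part = classify_timepoints(dx, rl)
        keys = lambda vs: {v.key for v in vs}
        c, a, l = keys(part.common), keys(part.additional), keys(part.lost)
        assert c | a | l == keys(dx) | keys(rl)
        assert not (c & a or c & l or a & l)
        assert len(part.common) + len(part.additional) + len(part.lost) == \
            len(c | a | l)


class TestLeftAlign:
    def test_homopolymer_deletion_shifts_left(self):
        #            0123456789
        genome = DictGenome({"chr1": "GTAAAAACGT"})
        v = VariantCall("chr1", 5, "AA", "A", 10, 10, "s")  # del at [4,6)
        lv = left_align(v, genome)
        assert (lv.pos, lv.ref, lv.alt) == (2, "TA", "T")

    def test_snv_untouched(self):
        genome = DictGenome({"chr1": "ACGT"})
        v = VariantCall("chr1", 2, "C", "T", 5, 5, "s")
        assert left_align(v, genome) == v


def toy_gene(seq: str, cds: tuple[int, int], strand="+", chrom="chr1"):
    genome = DictGenome({chrom: seq})
    gene = GeneModel(
        "G1", "G1", "G1.t1",
        GenomicInterval(chrom, cds[0], cds[1]), strand,
        (GenomicInterval(chrom, cds[0], cds[1]),),
    )
    return gene, genome


class TestConsequence:
    def test_nonsense_glu_to_stop_with_label(self):
        """GAG codon hit at position 1 by G>T becomes TAG (E -> *)."""
        #        ATG GAG TAA
        seq = "CCATGGAGTAACC"
        gene, genome = toy_gene(seq, (2, 11))
        v = VariantCall("chr1", 6, "G", "T", 20, 10, "s")  # 0-based 5
        res = ConsequenceAnnotator([gene], genome).annotate(v)
        assert res.consequence == "nonsense"
        assert res.hgvs_like == "c.4G>T (p.E2*)"

    def test_single_base_deletion_is_frameshift_with_fs_label(self):
        seq = "CCATGGAGGAGTAACC"
        gene, genome = toy_gene(seq, (2, 14))
        v = VariantCall("chr1", 8, "GG", "G", 20, 10, "s")
        res = ConsequenceAnnotator([gene], genome).annotate(v)
        assert res.consequence == "frameshift"
        assert "fs" in res.hgvs_like

    def test_third_position_wobble_synonymous(self):
        """GCT -> GCC keeps alanine."""
        #        ATG GCT TAA
        seq = "CCATGGCTTAACC"
        gene, genome = toy_gene(seq, (2, 11))
        v = VariantCall("chr1", 8, "T", "C", 20, 10, "s")
        res = ConsequenceAnnotator([gene], genome).annotate(v)
        assert res.consequence == "synonymous"

    def test_minus_strand_matches_plus_strand_outcome(self):
        """A genomic C>A on the minus strand equals transcript G>T."""
        plus_seq = "CCATGGAGTAACC"
        comp = str.maketrans("ACGT", "TGCA")
        minus_seq = plus_seq.translate(comp)[::-1]
        gene_m, genome_m = toy_gene(minus_seq, (2, 11), strand="-")
        # transcript c.4 G is genomic position len-1-5 = 7 on minus seq
        pos0 = len(plus_seq) - 1 - 5
        v = VariantCall("chr1", pos0 + 1, "C", "A", 20, 10, "s")
        res = ConsequenceAnnotator([gene_m], genome_m).annotate(v)
        assert res.consequence == "nonsense"
        assert res.hgvs_like == "c.4G>T (p.E2*)"

    def test_inframe_deletion(self):
        seq = "CCATGGAGGAGTAACC"
        gene, genome = toy_gene(seq, (2, 14))
        v = VariantCall("chr1", 8, "GGAG", "G", 20, 10, "s")
        res = ConsequenceAnnotator([gene], genome).annotate(v)
        assert res.consequence == "inframe_indel"

    def test_outside_cds_is_non_cds(self):
        seq = "CCATGGAGTAACC"
        gene, genome = toy_gene(seq, (2, 11))
        v = VariantCall("chr1", 1, "C", "G", 20, 10, "s")
        res = ConsequenceAnnotator([gene], genome).annotate(v)
        assert res.consequence == "non_CDS" and res.gene_id is None

    def test_reference_mismatch_names_locus(self):
        seq = "CCATGGAGTAACC"
        gene, genome = toy_gene(seq, (2, 11))
        v = VariantCall("chr1", 6, "A", "T", 20, 10, "s")  # genome has G
        with pytest.raises(ReferenceMismatchError, match="chr1:6"):
            ConsequenceAnnotator([gene], genome).annotate(v)

    def test_random_snvs_match_translation_diff_oracle(self):
        """Random SNVs on random toy genes, both strands, multi-exon:
        codon-level classification equals the full-protein diff."""
        rng = np.random.default_rng(20240917)
        n_checked = 0
        while n_checked < 150:
            gene, genome = random_gene_genome(rng)
            annot = ConsequenceAnnotator([gene], genome)
            coding = [
                p for seg in gene.cds_segments
                for p in range(seg.start, seg.end)
            ]
            for _ in range(5):
                pos0 = coding[int(rng.integers(0, len(coding)))]
                ref = genome.fetch("chrT", pos0, pos0 + 1)
                alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3)))
                              % 4]
                v = VariantCall("chrT", pos0 + 1, ref, alt, 20, 10, "s")
                expected = oracle_snv_consequence(v, gene, genome)
                assert annot.annotate(v).consequence == expected
                n_checked += 1
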