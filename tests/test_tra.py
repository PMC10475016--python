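"""TRA construction, variant intersection and proximity collection."""

import numpy as np
import pytest

from trascan.io import GenomicInterval, GeneModel, TFBSCluster, VariantCall
from trascan.tra import (
    ProximityConfig,
    build_tra_regions,
    genes_within_window,
    intersect_variants_tras,
    regulators_at,
    total_coverage,
)
from trascan.variants import ClassifiedVariant

from oracles import (
    brute_force_regulators_at,
    brute_force_tras,
    make_alteration,
)


def cluster(start, end, name, chrom="chr1"):
    return TFBSCluster(GenomicInterval(chrom, start, end), name)


FIVE_FACTORS = [
    cluster(100, 200, "A"),
    cluster(110, 190, "B"),
    cluster(120, 180, "C"),
    cluster(100, 150, "D"),
    cluster(140, 200, "E"),
]


class TestBuildTras:
    def test_five_factor_example(self):
        """Distinct count reaches 5 only on [140, 150)."""
        (tra,) = build_tra_regions(FIVE_FACTORS, 5)
        assert (tra.interval.start, tra.interval.end) == (140, 150)
        assert tra.regulators == {"A", "B", "C", "D", "E"}
        assert tra.max_distinct_depth == 5

    def test_empty_input(self):
        assert build_tra_regions([], 5) == []

    def test_duplicate_factor_not_double_counted(self):
        rows = [cluster(0, 10, "A"), cluster(0, 10, "A"),
                cluster(0, 10, "B"), cluster(0, 10, "C"),
                cluster(0, 10, "D")]
        assert build_tra_regions(rows, 5) == []
        assert len(build_tra_regions(rows, 4)) == 1

    def test_adjacent_qualifying_segments_merge(self):
        rows = FIVE_FACTORS + [cluster(150, 160, "F"), cluster(150, 160, "G"),
                               cluster(150, 160, "H"), cluster(150, 160, "I"),
                               cluster(150, 160, "J")]
        (tra,) = build_tra_regions(rows, 5)
        assert (tra.interval.start, tra.interval.end) == (140, 160)

    def test_regions_disjoint_sorted_and_rebuild_stable(self):
        rng = np.random.default_rng(5)
        rows = [
            cluster(s := int(rng.integers(0, 5000)),
                    s + int(rng.integers(10, 400)),
                    f"R{int(rng.integers(0, 8))}",
                    chrom=f"chr{int(rng.integers(1, 3))}")
            for _ in range(200)
        ]
        tras = build_tra_regions(rows, 3)
        for a, b in zip(tras, tras[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start or True
                assert a.interval.end <= b.interval.start
        # reinterpreting TRAs as single-factor clusters never splits them
        rebuilt = build_tra_regions(
            [TFBSCluster(t.interval, "X") for t in tras], 1
        )
        assert [t.interval for t in rebuilt] == [t.interval for t in tras]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        rows = [
            cluster(s := int(rng.integers(0, 3000)),
                    s + int(rng.integers(20, 300)),
                    f"R{int(rng.integers(0, 12))}")
            for _ in range(150)
        ]
        cov = [total_coverage(build_tra_regions(rows, k))
               for k in (1, 2, 3, 5, 8)]
        assert cov == sorted(cov, reverse=True)

    def test_matches_per_base_oracle_on_random_instance(self):
        rng = np.random.default_rng(99)
        rows = [
            cluster(s := int(rng.integers(0, 10_000)),
                    s + int(rng.integers(5, 500)),
                    f"R{int(rng.integers(0, 15))}")
            for _ in range(250)
        ]
        got = sorted(
            (t.interval.chrom, t.interval.start, t.interval.end)
            for t in build_tra_regions(rows, 4)
        )
        assert got == brute_force_tras(rows, 4)


class TestRegulatorsAt:
    def test_positions_inside_example(self):
        assert regulators_at(FIVE_FACTORS, "chr1", 145) == \
            {"A", "B", "C", "D", "E"}
        assert regulators_at(FIVE_FACTORS, "chr1", 125) == {"A", "B", "C", "D"}
        assert regulators_at(FIVE_FACTORS, "chr1", 5000) == frozenset()

    def test_matches_containment_oracle(self):
        rng = np.random.default_rng(3)
        rows = [
            cluster(s := int(rng.integers(0, 2000)),
                    s + int(rng.integers(5, 300)),
                    f"R{int(rng.integers(0, 10))}")
            for _ in range(100)
        ]
        for pos in rng.integers(0, 2300, size=40):
            assert regulators_at(rows, "chr1", int(pos)) == \
                brute_force_regulators_at(rows, "chr1", int(pos))


def classified(pos, status="additional", ref="A", alt="T", chrom="chr1"):
    return ClassifiedVariant(
        VariantCall(chrom, pos + 1, ref, alt, 20, 10, "relapse"),
        status, "SNV" if len(ref) == len(alt) == 1 else "indel", "non_CDS",
    )


class TestIntersect:
    def test_anchor_in_and_out_of_tra(self):
        tras = build_tra_regions(FIVE_FACTORS, 5)  # [140,150)
        hits = intersect_variants_tras(
            [classified(145), classified(139)], tras, FIVE_FACTORS
        )
        assert len(hits) == 1
        assert hits[0].involved_regulators == {"A", "B", "C", "D", "E"}
        assert hits[0].variant.call.anchor == 145

    def test_deletion_anchor_rule_counts_once(self):
        tras = build_tra_regions(FIVE_FACTORS, 5)
        # anchor 149 inside, deletion extends past the TRA end
        cv = classified(149, ref="AAAAA", alt="A")
        hits = intersect_variants_tras([cv], tras, FIVE_FACTORS)
        assert len(hits) == 1

    def test_absent_chromosome_is_silent(self):
        tras = build_tra_regions(FIVE_FACTORS, 5)
        assert intersect_variants_tras(
            [classified(145, chrom="chrZ")], tras, FIVE_FACTORS
        ) == []

    def test_region_attribution_takes_union(self):
        tras = build_tra_regions(FIVE_FACTORS, 5)
        (hit,) = intersect_variants_tras(
            [classified(149)], tras, FIVE_FACTORS, attribution="region"
        )
        assert hit.involved_regulators == tras[0].regulators

    def test_status_carried_through(self):
        tras = build_tra_regions(FIVE_FACTORS, 5)
        (hit,) = intersect_variants_tras(
            [classified(145, status="common")], tras, FIVE_FACTORS
        )
        assert hit.variant.status == "common"


def gene(gene_id, start, end, chrom="chr1"):
    return GeneModel(
        gene_id, gene_id, f"{gene_id}.t",
        GenomicInterval(chrom, start, end), "+",
        (),
    )


class TestProximity:
    def test_exact_window_boundary(self):
        """Gap of exactly 20,000 bp is in; 20,001 is out."""
        alt = make_alteration("additional", {"MYC"}, pos=10_000)
        genes = [gene("IN", 30_001, 31_000), gene("OUT", 30_002, 31_000)]
        per_alt, per_status = genes_within_window([alt], genes)
        assert per_alt[alt] == {"IN"}
        assert per_status["additional"] == {"IN"}

    def test_anchor_inside_span_distance_zero(self):
        alt = make_alteration("common", set(), pos=500)
        per_alt, _ = genes_within_window([alt], [gene("G", 100, 1000)])
        assert per_alt[alt] == {"G"}

    def test_empty_gene_set(self):
        alt = make_alteration("common", set(), pos=500)
        per_alt, per_status = genes_within_window([alt], [])
        assert per_alt[alt] == frozenset()
        assert per_status == {"common": set()}

    def test_union_reported_per_status(self):
        a1 = make_alteration("common", set(), pos=100)
        a2 = make_alteration("additional", set(), pos=5_000_000)
        genes = [gene("NEAR1", 50, 80), gene("NEAR2", 5_000_100, 5_000_500)]
        _, per_status = genes_within_window([a1, a2], genes)
        assert per_status == {"common": {"NEAR1"}, "additional": {"NEAR2"}}
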