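"""DE thresholds, transcript-shift calls and Venn partitions."""

import numpy as np
import pandas as pd
import pytest

from trascan.errors import FormatError, TrascanError
from trascan.expression import (
    compute_fold_change,
    de_filter,
    overlap_sets,
    transcript_shift_genes,
)
from trascan.simulate import simulate_expression


def frame(**cols):
    return pd.DataFrame(cols)


class TestFoldChange:
    def test_plain_ratio_without_pseudocount(self):
        df = frame(gene_id=["g"], ctrl_1=[10.0], ctrl_2=[10.0],
                   cond_1=[20.0], cond_2=[20.0], p_value=[0.5])
        out = compute_fold_change(df, ["ctrl_1", "ctrl_2"],
                                  ["cond_1", "cond_2"], pseudocount=0.0)
        assert out["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_pseudocount_rescues_zero_control(self):
        df = frame(gene_id=["g"], ctrl_1=[0.0], cond_1=[5.0], p_value=[0.5])
        out = compute_fold_change(df, ["ctrl_1"], ["cond_1"], pseudocount=0.1)
        assert out["fold_change"].iloc[0] == pytest.approx(51.0)

    def test_equal_means_unit_fc(self):
        df = frame(gene_id=["g"], ctrl_1=[7.0], cond_1=[7.0], p_value=[0.5])
        out = compute_fold_change(df, ["ctrl_1"], ["cond_1"], pseudocount=0.0)
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_missing_sample_column_is_fatal_and_named(self):
        df = frame(gene_id=["g"], ctrl_1=[1.0], cond_1=[1.0])
        with pytest.raises(FormatError, match="ctrl_2"):
            compute_fold_change(df, ["ctrl_1", "ctrl_2"], ["cond_1"])

    def test_welch_p_attached_with_replicates(self):
        rng = np.random.default_rng(0)
        df = frame(
            gene_id=["g"],
            **{f"ctrl_{i}": [v] for i, v in enumerate(10 + rng.normal(0, .1, 3), 1)},
            **{f"cond_{i}": [v] for i, v in enumerate(40 + rng.normal(0, .1, 3), 1)},
        )
        out = compute_fold_change(df, [f"ctrl_{i}" for i in (1, 2, 3)],
                                  [f"cond_{i}" for i in (1, 2, 3)])
        assert out["p_value"].iloc[0] < 0.01


class TestDeFilter:
    def test_threshold_semantics(self):
        df = frame(
            gene_id=["up_edge", "down_edge", "p_edge", "null"],
            fold_change=[2.0, 0.5, 3.0, 1.2],
            p_value=[0.005, 0.005, 0.01, 0.0001],
        )
        up, down = de_filter(df)
        assert up == {"up_edge"}          # FC >= 2 inclusive
        assert down == {"down_edge"}      # reciprocal bound inclusive
        # p_edge: p == 0.01 is not < 0.01; null: |FC| below bound

    def test_up_down_disjoint_always(self):
        rng = np.random.default_rng(1)
        df = frame(
            gene_id=[f"g{i}" for i in range(500)],
            fold_change=2.0 ** rng.normal(0, 2, 500),
            p_value=rng.uniform(0, 1, 500),
        )
        up, down = de_filter(df)
        assert up & down == set()

    def test_missing_p_fatal_with_ids(self):
        df = frame(gene_id=["gA", "gB"], fold_change=[2.5, 3.0],
                   p_value=[0.001, np.nan])
        with pytest.raises(TrascanError, match="gB"):
            de_filter(df)

    def test_planted_recovery_exact(self):
        gene_df, _, truth = simulate_expression(
            n_genes=300, n_up=12, n_down=25, n_shift_genes=40, seed=5
        )
        up, down = de_filter(gene_df.assign(
            fold_change=(gene_df[[c for c in gene_df if c.startswith("cond")]]
                         .mean(axis=1) + 0.1)
            / (gene_df[[c for c in gene_df if c.startswith("ctrl")]]
               .mean(axis=1) + 0.1)
        ))
        assert up == set(truth["up"])
        assert down == set(truth["down"])


class TestShiftGenes:
    def test_conjunction_of_threshold_and_class(self):
        df = frame(
            transcript_id=["t1", "t2", "t3"],
            gene_id=["gA", "gB", "gC"],
            fold_change=[2.5, 2.5, 1.1],
            p_value=[0.001, 0.001, 0.001],
            structure_class=["junction_match", "novel", "junction_match"],
        )
        assert transcript_shift_genes(df) == {"gA"}

    def test_any_passing_transcript_suffices(self):
        df = frame(
            transcript_id=["t1", "t2"],
            gene_id=["gA", "gA"],
            fold_change=[1.0, 0.25],
            p_value=[0.5, 0.0001],
            structure_class=["junction_match", "containment_of_references"],
        )
        assert transcript_shift_genes(df) == {"gA"}


class TestOverlap:
    def test_two_set_partition(self):
        ov = overlap_sets({"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}})
        assert ov.region_members["X&Y"] == {"b", "c"}
        assert ov.region_members["X"] == {"a"}
        assert ov.region_members["Y"] == {"d"}
        assert ov.union_size == 4

    def test_three_disjoint_sets(self):
        ov = overlap_sets({"A": {"1"}, "B": {"2"}, "C": {"3"}})
        assert ov.intersection_all == frozenset()
        assert all(
            ov.region_counts[k] == 0 for k in ov.region_counts if "&" in k
        )

    def test_counts_sum_to_union_on_random_triples(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            sets = {
                name: {f"g{int(i)}" for i in rng.integers(0, 40,
                                                          rng.integers(0, 30))}
                for name in ("A", "B", "C")
            }
            ov = overlap_sets(sets)
            union = set().union(*sets.values())
            assert ov.union_size == len(union)
            # regions are disjoint
            seen: set[str] = set()
            for members in ov.region_members.values():
                assert not (seen & members)
                seen |= members
            assert seen == union

    def test_doubling_one_set_keeps_other_exclusive_regions(self):
        base = {"A": {"a", "x"}, "B": {"b", "x"}, "C": {"c"}}
        grown = {"A": {"a", "x", "q", "r"}, "B": {"b", "x"}, "C": {"c"}}
        assert overlap_sets(base).region_members["B"] == \
            overlap_sets(grown).region_members["B"]
        assert overlap_sets(base).region_members["C"] == \
            overlap_sets(grown).region_members["C"]

    def test_more_than_four_sets_unsupported(self):
        with pytest.raises(TrascanError):
            overlap_sets({str(i): {"x"} for i in range(5)})
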