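"""Expression matrix, RPKM, abundance classes, stage presence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactoseq.datasets import load_unique_deg_example
from lactoseq.expression import (
    ExpressionMatrix,
    classify_abundance,
    compute_rpkm,
    count_unique_by_stage,
    stage_mean_rpkm,
    stage_presence,
)


def _matrix(values: pd.DataFrame, stages=None) -> ExpressionMatrix:
    labels = {s: s[0] for s in values.columns}
    return ExpressionMatrix(values=values, stage_of_sample=labels, stages=stages or ())


class TestExpressionMatrix:
    def test_rejects_negative_values(self):
        values = pd.DataFrame({"L1": [1.0, -2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="negative"):
            _matrix(values)

    def test_rejects_duplicate_gene_ids(self):
        values = pd.DataFrame({"L1": [1.0, 2.0]}, index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate gene"):
            _matrix(values)

    def test_rejects_unlabelled_sample(self):
        values = pd.DataFrame({"L1": [1.0], "D1": [2.0]}, index=["a"])
        with pytest.raises(ValueError, match="stage"):
            ExpressionMatrix(values=values, stage_of_sample={"L1": "L"})


class TestComputeRpkm:
    def test_textbook_value(self):
        # 10 reads on a 1 kb gene in a library of 1e6 -> RPKM 10
        values = pd.DataFrame({"L1": [10, 1_000_000 - 10]}, index=["g", "rest"])
        lengths = pd.Series([1000, 1000], index=["g", "rest"])
        rpkm = compute_rpkm(_matrix(values), lengths)
        assert rpkm.values.loc["g", "L1"] == pytest.approx(10.0)

    def test_zero_counts_give_zero_rpkm(self):
        values = pd.DataFrame({"L1": [0, 50]}, index=["g", "rest"])
        rpkm = compute_rpkm(_matrix(values), pd.Series([500, 500], index=["g", "rest"]))
        assert rpkm.values.loc["g", "L1"] == 0.0

    def test_scale_invariance_within_sample(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(10, 2)), columns=["L1", "D1"],
            index=[f"g{i}" for i in range(10)],
        )
        lengths = pd.Series(rng.integers(200, 2000, 10), index=counts.index)
        a = compute_rpkm(_matrix(counts), lengths)
        b = compute_rpkm(_matrix(counts * 3), lengths)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_inverse_in_length_and_linear_in_counts(self):
        counts = pd.DataFrame({"L1": [10, 20, 990]}, index=["g1", "g2", "rest"])
        lengths = pd.Series([1000, 2000, 100], index=counts.index)
        rpkm = compute_rpkm(_matrix(counts), lengths)
        # g2 has 2x counts and 2x length of g1 -> identical RPKM
        assert rpkm.values.loc["g2", "L1"] == pytest.approx(rpkm.values.loc["g1", "L1"])

    def test_zero_library_names_sample(self):
        values = pd.DataFrame({"L1": [0, 0], "D1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="L1"):
            compute_rpkm(_matrix(values), pd.Series([100, 100], index=["a", "b"]))

    def test_missing_length_names_gene(self):
        values = pd.DataFrame({"L1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            compute_rpkm(_matrix(values), pd.Series([100], index=["a"]))


class TestAbundanceClasses:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (537.391, "high"),    # lactation-stage RPKM of FASN in NP
            (376.222, "medium"),
            (120.146, "medium"),
            (0.0, "low"),
            (9.999, "low"),
            (10.0, "medium"),     # half-open boundary
            (499.999, "medium"),
            (500.0, "high"),      # printed ">= 500" edge
        ],
    )
    def test_binning(self, value, expected):
        assert classify_abundance(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_abundance(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=50))
    def test_bins_partition_nonnegative_values(self, values):
        labels = classify_abundance(values)
        assert len(labels) == len(values)
        assert set(labels) <= {"low", "medium", "high"}


class TestStageMeans:
    def test_single_replicate_is_identity(self):
        values = pd.DataFrame({"L1": [1.0, 2.0], "D1": [3.0, 4.0]}, index=["a", "b"])
        m = _matrix(values)
        m.value_kind = "rpkm"
        means = stage_mean_rpkm(m)
        assert means.loc["a", "L"] == 1.0 and means.loc["b", "D"] == 4.0

    def test_replicate_mean(self):
        values = pd.DataFrame({"L1": [1.0], "L2": [3.0], "D1": [5.0]}, index=["a"])
        means = stage_mean_rpkm(_matrix(values))
        assert means.loc["a", "L"] == 2.0

    def test_matches_elementwise_loop(self, rng):
        values = pd.DataFrame(
            rng.random(size=(20, 6)) * 100,
            columns=["L1", "L2", "L3", "D1", "D2", "D3"],
            index=[f"g{i}" for i in range(20)],
        )
        means = stage_mean_rpkm(_matrix(values))
        for g in values.index:
            for stage, cols in (("L", ["L1", "L2", "L3"]), ("D", ["D1", "D2", "D3"])):
                expected = sum(values.loc[g, c] for c in cols) / 3
                assert means.loc[g, stage] == pytest.approx(expected)


class TestStagePresence:
    def test_unique_gene_detection(self):
        means = pd.DataFrame(
            {"L": [5.0, 1.0], "D": [0.0, 1.0], "NP": [0.0, 1.0]}, index=["only_l", "everywhere"]
        )
        pres = stage_presence(means, tau=0.0)
        assert pres.unique_genes("L") == ["only_l"]
        assert pres.unique_genes("D") == []

    def test_venn_matches_brute_force_sets(self, rng):
        means = pd.DataFrame(
            (rng.random(size=(50, 3)) > 0.4) * rng.random(size=(50, 3)) * 10,
            columns=["L", "D", "NP"],
            index=[f"g{i}" for i in range(50)],
        )
        pres = stage_presence(means, tau=0.0)
        # brute force with plain python sets
        sets = {s: {g for g in means.index if means.loc[g, s] > 0} for s in means.columns}
        for key, count in pres.venn.items():
            members = set(means.index)
            for s in means.columns:
                members &= sets[s] if s in key else (set(means.index) - sets[s])
            assert count == len(members), key

    def test_venn_regions_sum_to_gene_count(self, rng):
        means = pd.DataFrame(
            rng.random(size=(30, 3)) * (rng.random(size=(30, 3)) > 0.5),
            columns=["L", "D", "NP"],
        )
        pres = stage_presence(means, tau=0.0)
        assert sum(pres.venn.values()) == 30


class TestUniqueCountTally:
    def test_bundled_unique_deg_table(self):
        # the bundled dairy-goat example: 6 dry-off and 2 involution genes
        table = load_unique_deg_example()
        counts = count_unique_by_stage(table)
        assert counts == {"L": 0, "D": 6, "NP": 2}
        assert sum(counts.values()) == len(table) == 8

    def test_empty_table_reports_zeros(self):
        counts = count_unique_by_stage(pd.DataFrame({"stage": []}))
        assert counts == {"L": 0, "D": 0, "NP": 0}

    def test_random_labels_match_counter(self, rng):
        from collections import Counter

        labels = rng.choice(["L", "D", "NP"], size=100)
        counts = count_unique_by_stage(pd.DataFrame({"stage": labels}))
        assert counts == {s: Counter(labels).get(s, 0) for s in ("L", "D", "NP")}

    def test_unknown_stage_label_raises(self):
        with pytest.raises(ValueError, match="unknown stage"):
            count_unique_by_stage(pd.DataFrame({"stage": ["X"]}))
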