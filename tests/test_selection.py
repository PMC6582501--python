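"""QC floor, within-sample ranking and the A/B/C selection criteria."""

import numpy as np
import pandas as pd
import pytest

from ctcpanel import (
    CountMatrix,
    CriterionParams,
    QuantileMatrix,
    RankMatrix,
    combine_criteria,
    criterion_a,
    criterion_b,
    criterion_c,
    evaluate_criteria,
    qc_filter,
    quantile_scores,
    rank_within_sample,
)

from ._oracles import brute_force_criteria
from .conftest import random_toy_matrix


def matrix_from_array(arr, groups, genes=None, samples=None, assays="plasma"):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=genes, columns=samples),
        pd.Series(groups, index=samples),
        assays,
    )


class TestQcFilter:
    def test_floor_two_masks_low_counts(self):
        cm = matrix_from_array([[0], [2], [3], [50]], ["tumor"])
        masked = qc_filter(cm, floor=2)
        col = masked.values_frame.iloc[:, 0]
        assert col.isna().tolist() == [True, True, False, False]
        assert col.dropna().tolist() == [3.0, 50.0]

    def test_floor_zero_removes_only_zeros(self):
        cm = matrix_from_array([[0], [1], [2]], ["tumor"])
        masked = qc_filter(cm, floor=0)
        assert masked.values_frame.iloc[:, 0].isna().tolist() == [True, False, False]

    def test_floor_above_max_gives_empty_sample_error_downstream(self):
        cm = matrix_from_array([[1], [2]], ["tumor"])
        masked = qc_filter(cm, floor=10)
        assert masked.n_removed == 2
        with pytest.raises(ValueError, match="s0"):
            rank_within_sample(masked)


class TestRanking:
    def test_descending_ranks(self):
        cm = matrix_from_array([[5], [3], [9]], ["tumor"])
        rm = rank_within_sample(qc_filter(cm, floor=0))
        assert rm.ranks.iloc[:, 0].tolist() == [2.0, 3.0, 1.0]

    def test_mean_tie_convention(self):
        cm = matrix_from_array([[4], [4], [1]], ["tumor"])
        rm = rank_within_sample(qc_filter(cm, floor=0))
        assert rm.ranks.iloc[:, 0].tolist() == [1.5, 1.5, 3.0]

    def test_rank_sums_conserved_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            counts = rng.integers(0, 40, size=(50, 6))
            counts[0, :] = 50  # keep every sample nonempty after QC
            cm = matrix_from_array(counts, ["tumor"] * 3 + ["control"] * 3)
            rm = rank_within_sample(qc_filter(cm, floor=2))
            g = rm.retained_per_sample
            sums = rm.ranks.sum(axis=0, skipna=True)
            expected = g * (g + 1) / 2.0
            assert np.allclose(sums, expected)

    def test_scale_invariance_within_sample(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(3, 60, size=(30, 4))  # all above the floor
        cm = matrix_from_array(counts, ["tumor"] * 2 + ["control"] * 2)
        rm = rank_within_sample(qc_filter(cm, floor=2))
        scaled = counts.copy()
        scaled[:, 1] *= 7  # batch-effect-like per-sample scaling
        cm2 = matrix_from_array(scaled, ["tumor"] * 2 + ["control"] * 2)
        rm2 = rank_within_sample(qc_filter(cm2, floor=2))
        pd.testing.assert_frame_equal(rm.ranks, rm2.ranks)

    def test_monotone_in_own_count(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(3, 50, size=(20, 3))
        cm = matrix_from_array(counts, ["tumor", "tumor", "control"])
        rm = rank_within_sample(qc_filter(cm, floor=2))
        q = quantile_scores(rm)
        bumped = counts.copy()
        bumped[4, 1] += 13
        cm2 = matrix_from_array(bumped, ["tumor", "tumor", "control"])
        rm2 = rank_within_sample(qc_filter(cm2, floor=2))
        q2 = quantile_scores(rm2)
        assert rm2.ranks.iloc[4, 1] <= rm.ranks.iloc[4, 1]
        assert q2.scores.iloc[4, 1] >= q.scores.iloc[4, 1]


class TestQuantileScores:
    def test_range_and_missing_to_zero(self):
        cm = matrix_from_array([[0], [5], [9], [20]], ["tumor"])
        q = quantile_scores(rank_within_sample(qc_filter(cm, floor=2)))
        col = q.scores.iloc[:, 0]
        assert col.tolist() == [0.0, 0.0, 0.5, 1.0]
        assert ((col >= 0) & (col <= 1)).all()

    def test_single_retained_gene_scores_one(self):
        cm = matrix_from_array([[1], [44]], ["tumor"])
        q = quantile_scores(rank_within_sample(qc_filter(cm, floor=2)))
        assert q.scores.iloc[:, 0].tolist() == [0.0, 1.0]


class TestCriteria:
    def test_criterion_a_hand_computed_study_sizes(self):
        # 18 tumor at score 0.9, 4 controls at 0.1: m = 16.6/22 ~ 0.7545
        scores = pd.DataFrame(
            [[0.9] * 18 + [0.1] * 4, [0.5] * 22],
            index=["hit", "flat"],
            columns=[f"s{j}" for j in range(22)],
        )
        groups = pd.Series(
            ["tumor"] * 18 + ["control"] * 4, index=scores.columns
        )
        q = QuantileMatrix(scores, groups, "plasma")
        got = criterion_a(q, CriterionParams(), "plasma")
        assert got == {"hit"}  # constant gene never passes strict inequalities

    def test_criterion_b_direct_rule(self):
        ranks = pd.DataFrame(
            {
                "t1": [1.0, 500.0, 11.0],
                "t2": [400.0, 2.0, 3.0],
                "c1": [500.0, 450.0, 10.0],
            },
            index=["top_in_tumor", "also_top", "top_in_control"],
        )
        groups = pd.Series(
            {"t1": "tumor", "t2": "tumor", "c1": "control"}
        )
        rm = RankMatrix(ranks, groups, "plasma")
        got = criterion_b(rm, CriterionParams(), "plasma")
        assert got == {"top_in_tumor", "also_top"}

    def test_criterion_c_boundaries_inclusive(self):
        # exactly 5 tumor top-20 hits and exactly 1 control hit -> selected;
        # 4 tumor hits -> excluded
        n_t, n_c = 6, 2
        ranks = pd.DataFrame(
            [
                [15.0] * 5 + [300.0] + [15.0, 300.0],
                [15.0] * 4 + [300.0] * 2 + [300.0, 300.0],
            ],
            index=["five_hits", "four_hits"],
            columns=[f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(n_c)],
        )
        groups = pd.Series(
            ["tumor"] * n_t + ["control"] * n_c, index=ranks.columns
        )
        rm = RankMatrix(ranks, groups, "plasma")
        got = criterion_c(rm, CriterionParams(), "plasma")
        assert got == {"five_hits"}

    def test_missing_never_counts_as_top_rank(self):
        ranks = pd.DataFrame(
            {"t1": [1.0], "c1": [np.nan]}, index=["g"]
        )
        groups = pd.Series({"t1": "tumor", "c1": "control"})
        rm = RankMatrix(ranks, groups, "plasma")
        assert criterion_b(rm, CriterionParams(), "plasma") == {"g"}

    def test_missing_assay_rejected(self):
        cm = matrix_from_array([[5], [9]], ["tumor"], assays="plasma")
        with pytest.raises(ValueError):
            evaluate_criteria(cm, assay="ctc")

    def test_criteria_match_brute_force_on_random_toys(self, params):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            cm = random_toy_matrix(rng)
            got = evaluate_criteria(cm, params, "plasma")
            counts_by_gene = {
                g: dict(cm.counts.loc[g]) for g in cm.gene_ids
            }
            expected = brute_force_criteria(
                counts_by_gene, dict(cm.groups), floor=params.floor
            )
            assert got == expected

    def test_invariance_to_gene_and_sample_order(self, params):
        rng = np.random.default_rng(77)
        cm = random_toy_matrix(rng)
        flags = evaluate_criteria(cm, params, "plasma")
        perm_genes = rng.permutation(cm.gene_ids)
        perm_samples = rng.permutation(cm.sample_ids)
        cm2 = CountMatrix(
            cm.counts.loc[perm_genes, perm_samples],
            cm.groups.loc[perm_samples],
            cm.assays.loc[perm_samples],
        )
        assert evaluate_criteria(cm2, params, "plasma") == flags


class TestCombine:
    def test_table_style_combinations(self, params):
        flags_plasma = {"CCL5": {"A", "B", "C"}, "GIMAP4": {"B"}, "LONE": {"C"}}
        flags_ctc = {"CCL5": {"B"}, "GIMAP4": {"B"}, "LONE": set()}
        report = combine_criteria(flags_plasma, flags_ctc, params)
        assert report.flags("CCL5")["total_hits"] == 4
        assert report.flags("CCL5")["included"]
        assert report.flags("GIMAP4") == {
            "plasma": {"B"},
            "ctc": {"B"},
            "total_hits": 2,
            "included": True,
        }
        assert not report.flags("LONE")["included"]
        assert report.included_genes == ["CCL5", "GIMAP4"]

    def test_sorted_by_hits_then_gene(self, params):
        flags = {"z": {"A"}, "a": {"A"}, "m": {"A", "B"}}
        report = combine_criteria(flags, {g: set() for g in flags}, params)
        assert report.frame["gene_id"].tolist() == ["m", "a", "z"]

    def test_mismatched_universe_rejected(self, params):
        with pytest.raises(ValueError):
            combine_criteria({"a": set()}, {"b": set()}, params)

    def test_report_tsv_round_trip(self, params, tmp_path):
        report = combine_criteria(
            {"x": {"A", "B"}, "y": set()}, {"x": set(), "y": {"C"}}, params
        )
        path = tmp_path / "report.tsv"
        report.to_tsv(path)
        back = type(report).read_tsv(path)
        pd.testing.assert_frame_equal(back.frame, report.frame)
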