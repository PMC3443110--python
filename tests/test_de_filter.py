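"""The four-criterion differential-expression filter."""

import numpy as np
import pandas as pd
import pytest

from rankde import (
    FilterConfig,
    ScalingConfig,
    compare_groups,
    effect_map,
    rank_by_fold,
    samples_for,
    scale_matrix,
    simulate_experiment,
    simulate_null,
    summarize_contrast,
    SimulationConfig,
    ExpressionMatrix,
)


def matrix_from_rows(rows: dict, samples: list[str], calls: str = "P") -> ExpressionMatrix:
    idx = pd.Index(list(rows), name="gene_id")
    signals = pd.DataFrame(list(rows.values()), index=idx, columns=samples, dtype=float)
    call_frame = pd.DataFrame(
        np.full(signals.shape, calls), index=idx, columns=samples
    )
    return ExpressionMatrix(signals, call_frame)


A3 = ["a1", "a2", "a3"]
B3 = ["b1", "b2", "b3"]

PN11_CONFIG = FilterConfig(p_max=0.057, adaptive_min_p=True)


class TestCompareGroupsHandExamples:
    def test_clean_eightfold_increase_passes_all_criteria(self):
        m = matrix_from_rows({"g": [50, 55, 60, 400, 420, 440]}, A3 + B3)
        out = compare_groups(m, A3, B3, PN11_CONFIG).loc["g"]
        assert out["fold"] == pytest.approx(7.65, abs=0.05)
        assert out["p_two_tailed"] == pytest.approx(0.1)
        assert out["pairwise_valid"] == 9
        assert out[["pass_fold", "pass_detection", "pass_rank_test", "pass_pairwise"]].all()
        assert out["effect"] == "Increased"

    def test_identical_groups_are_unchanged(self):
        m = matrix_from_rows({"g": [100, 120, 140, 100, 120, 140]}, A3 + B3)
        out = compare_groups(m, A3, B3).loc["g"]
        assert out["fold"] == pytest.approx(1.0)
        assert out["effect"] == "Unchanged"

    def test_adaptive_rule_raises_3v3_threshold_to_design_minimum(self):
        # 0.057 is unattainable for 3v3 (floor p = 0.1); the adaptive rule
        # accepts complete separation while the rigid rule rejects it
        m = matrix_from_rows({"g": [50, 55, 60, 400, 420, 440]}, A3 + B3)
        adaptive = compare_groups(m, A3, B3, FilterConfig(adaptive_min_p=True))
        rigid = compare_groups(m, A3, B3, FilterConfig(adaptive_min_p=False))
        assert adaptive.loc["g", "effect"] == "Increased"
        assert rigid.loc["g", "effect"] == "Unchanged"
        assert PN11_CONFIG.effective_p(3, 3) == pytest.approx(0.1)

    def test_detection_criterion_requires_present_in_high_group(self):
        m = matrix_from_rows({"g": [50, 55, 60, 400, 420, 440]}, A3 + B3, calls="A")
        out = compare_groups(m, A3, B3, PN11_CONFIG).loc["g"]
        assert not out["pass_detection"]
        assert out["effect"] == "Unchanged"

    def test_detection_cap_at_group_size(self):
        # min_present_high=4 with 3-member groups caps to 3/3 Present
        m = matrix_from_rows({"g": [50, 55, 60, 400, 420, 440]}, A3 + B3)
        config = FilterConfig(min_present_high=4)
        out = compare_groups(m, A3, B3, config).loc["g"]
        assert out["pass_detection"]

    def test_pairwise_criterion_counts_same_direction_pairs(self):
        # one B replicate below 2x every A value kills 3 of 9 pairs -> 6 left,
        # exactly the (m-1)*n = 6 threshold
        m = matrix_from_rows({"g": [50, 55, 60, 95, 420, 440]}, A3 + B3)
        out = compare_groups(m, A3, B3, PN11_CONFIG).loc["g"]
        assert out["pairwise_valid"] == 6
        assert out["pass_pairwise"]

    def test_floor_collapses_subthreshold_fold(self):
        # both groups below the floor: means identical after flooring
        m = matrix_from_rows({"g": [1, 2, 3, 8, 9, 9.5]}, A3 + B3)
        out = compare_groups(m, A3, B3, scaling=ScalingConfig(floor=10)).loc["g"]
        assert out["fold"] == pytest.approx(1.0)
        assert out["effect"] == "Unchanged"

    def test_overlapping_groups_rejected(self):
        m = matrix_from_rows({"g": [1, 2, 3, 4, 5, 6]}, A3 + B3)
        with pytest.raises(ValueError, match="overlap"):
            compare_groups(m, A3, ["a3", "b1", "b2"])

    def test_unknown_sample_rejected(self):
        m = matrix_from_rows({"g": [1, 2, 3, 4, 5, 6]}, A3 + B3)
        with pytest.raises(ValueError, match="not in matrix"):
            compare_groups(m, A3, ["b1", "b2", "zz"])


@pytest.fixture(scope="module")
def experiment():
    exp = simulate_experiment(SimulationConfig(n_genes=1500, seed=17))
    matrix, _ = scale_matrix(exp.matrix)
    wt = samples_for(exp.sample_sheet, "WT", "PN56")
    ko = samples_for(exp.sample_sheet, "KO", "PN56")
    return matrix, wt, ko


class TestFilterProperties:
    def test_raising_fold_threshold_never_enlarges_selection(self, experiment):
        matrix, wt, ko = experiment
        selected = None
        for fold in (1.5, 2.0, 3.0, 5.0):
            out = compare_groups(matrix, wt, ko, FilterConfig(fold_threshold=fold))
            current = set(out.index[out["effect"] != "Unchanged"])
            if selected is not None:
                assert current <= selected
            selected = current

    def test_disabling_pairwise_rule_never_shrinks_selection(self, experiment):
        matrix, wt, ko = experiment
        with_rule = compare_groups(matrix, wt, ko, FilterConfig(pairwise_rule=True))
        without = compare_groups(matrix, wt, ko, FilterConfig(pairwise_rule=False))
        sel_with = set(with_rule.index[with_rule["effect"] != "Unchanged"])
        sel_without = set(without.index[without["effect"] != "Unchanged"])
        assert sel_with <= sel_without

    def test_null_3v3_call_rates(self):
        exp = simulate_null(SimulationConfig(n_genes=2000, noise_sd=0.4, seed=23))
        matrix, _ = scale_matrix(exp.matrix)
        wt = samples_for(exp.sample_sheet, "WT", "PN11")
        ko = samples_for(exp.sample_sheet, "KO", "PN11")
        out = compare_groups(matrix, wt, ko, PN11_CONFIG)
        # p-criterion alone is bounded by its 3v3 ceiling of 0.1
        p_rate = (out["p_two_tailed"] <= PN11_CONFIG.effective_p(3, 3) + 1e-12).mean()
        assert p_rate <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / len(out))
        # the full filter is far stricter than the ceiling
        assert (out["effect"] != "Unchanged").mean() <= 0.01

    def test_planted_fourfold_effects_recovered(self):
        # detection always Present, baselines far above the floor
        cfg = SimulationConfig(
            n_genes=2000, noise_sd=0.3, de_fraction=0.05, effect_log2=2.0,
            present_threshold=0.0, baseline_log2_mean=8.0, baseline_log2_sd=1.5,
            seed=31,
        )
        exp = simulate_experiment(cfg)
        matrix, _ = scale_matrix(exp.matrix)
        wt = samples_for(exp.sample_sheet, "WT", "PN56")
        ko = samples_for(exp.sample_sheet, "KO", "PN56")
        called = effect_map(compare_groups(matrix, wt, ko))
        truth = exp.truth.effect_map("PN56")
        planted = [g for g, e in truth.items() if e != "Unchanged"]
        nulls = [g for g, e in truth.items() if e == "Unchanged"]
        sensitivity = np.mean([called[g] == truth[g] for g in planted])
        fpr = np.mean([called[g] != "Unchanged" for g in nulls])
        assert sensitivity >= 0.9
        assert fpr <= 0.01

    def test_small_planted_folds_are_excluded_by_criterion_1(self):
        # 1.5-fold planted effects sit below the >2-fold requirement
        cfg = SimulationConfig(
            n_genes=500, noise_sd=0.1, de_fraction=0.1, effect_log2=np.log2(1.5),
            present_threshold=0.0, baseline_log2_mean=8.0, baseline_log2_sd=1.0,
            seed=5,
        )
        exp = simulate_experiment(cfg)
        matrix, _ = scale_matrix(exp.matrix)
        wt = samples_for(exp.sample_sheet, "WT", "PN56")
        ko = samples_for(exp.sample_sheet, "KO", "PN56")
        out = compare_groups(matrix, wt, ko)
        assert summarize_contrast(out) == (0, 0)


class TestSummaries:
    def test_summarize_counts_directions(self):
        df = pd.DataFrame({"effect": ["Increased", "Increased", "Decreased", "Unchanged"]})
        assert summarize_contrast(df) == (2, 1)

    def test_all_unchanged(self):
        df = pd.DataFrame({"effect": ["Unchanged"] * 5})
        assert summarize_contrast(df) == (0, 0)

    def test_rank_by_fold_orders_by_extremity(self):
        df = pd.DataFrame(
            {
                "mean_log2_a": [5, 5, 5, 5],
                "mean_log2_b": [8, 7, 6.32, 5],
                "fold": [8.0, 4.0, 2.5, 1.0],
                "effect": ["Increased"] * 3 + ["Unchanged"],
            },
            index=pd.Index(["w", "x", "y", "z"], name="gene_id"),
        )
        top = rank_by_fold(df, "Increased", 2)
        assert list(top["gene_id"]) == ["w", "x"]
        assert list(top["fold"]) == [8.0, 4.0]
        empty = rank_by_fold(df, "Decreased", 5)
        assert empty.empty
        assert rank_by_fold(df, "Increased", 0).empty

    def test_rank_by_fold_decreases_sort_ascending_and_merge_annotations(self):
        df = pd.DataFrame(
            {
                "mean_log2_a": [9.0, 9.0],
                "mean_log2_b": [6.0, 7.0],
                "fold": [0.125, 0.25],
                "effect": ["Decreased", "Decreased"],
            },
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        ann = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "symbol": ["Aqp3", "Pax6"],
                "description": ["aquaporin 3", "paired box gene 6"],
                "go_bp_text": ["", ""],
            }
        )
        top = rank_by_fold(df, "Decreased", 2, annotations=ann)
        assert list(top["symbol"]) == ["Aqp3", "Pax6"]
        assert list(top.columns) == [
            "gene_id", "symbol", "description", "mean_log2_a", "mean_log2_b", "fold",
        ]
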