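import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from interarray.simulate import SimulationConfig, generate_experiment
from interarray.stats import (amplitude_summary, bh_adjust, call_differential,
                              equivalent_genes, merge_timepoints,
                              one_sample_t, signed_fold_change, two_group_t,
                              two_color_probe_stats)


class TestOneSampleT:
    def test_matches_closed_form_t_distribution(self):
        # df=2: P(T <= t) = 1/2 (1 + t / sqrt(2 + t^2)), computed by hand
        t, p, degen = one_sample_t([1.0, 1.2, 0.8])
        assert t == pytest.approx(8.660254037844387, rel=1e-9)
        assert p == pytest.approx(0.013072457560346473, rel=1e-9)
        assert not degen

    def test_constant_zero_gives_p_one(self):
        t, p, degen = one_sample_t([0.0, 0.0, 0.0])
        assert (t, p, degen) == (0.0, 1.0, True)

    def test_constant_nonzero_gives_p_zero_flagged(self):
        t, p, degen = one_sample_t([0.7, 0.7, 0.7])
        assert p == 0.0 and degen and t == np.inf

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])


class TestTwoGroupT:
    def test_matches_pooled_t_oracle(self):
        # textbook pooled formula + numerical t-density integration (df=4)
        t, p, _ = two_group_t([1, 1.1, 0.9], [0, 0.1, -0.1])
        assert t == pytest.approx(12.247448713915887, rel=1e-9)
        assert p == pytest.approx(0.00025521674944191684, rel=1e-6)

    def test_identical_groups_give_t_zero_p_one(self):
        t, p, _ = two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swapping_groups_negates_t(self):
        t1, p1, _ = two_group_t([1, 1.1, 0.9], [0, 0.1, -0.1])
        t2, p2, _ = two_group_t([0, 0.1, -0.1], [1, 1.1, 0.9])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_group_t([1.0], [0.0, 0.1])


class TestBHAdjust:
    def test_hand_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_equal_values_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_order_invariant_capped_and_dominates_raw(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(np.sort(bh_adjust(p[perm])), np.sort(adj))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30))
    def test_monotone_in_rank(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


def stat_frame(rows):
    df = pd.DataFrame(rows, columns=["mean_log2_ratio", "p_bh"])
    df["FC"] = signed_fold_change(df["mean_log2_ratio"])
    df["contrast"] = "mg_vs_ctrl"
    df["timepoint"] = "3h"
    return df


class TestCallDifferential:
    @pytest.mark.parametrize("mlr,p_bh,expect_called,expect_dir", [
        (1.098, 0.2, True, "induced"),     # |FC| = 2.14, p fails
        (0.378, 0.01, True, "induced"),    # |FC| = 1.3, p passes
        (0.378, 0.2, False, "none"),       # neither criterion
        (-1.2, 0.5, True, "repressed"),
    ])
    def test_union_rule(self, mlr, p_bh, expect_called, expect_dir):
        out = call_differential(stat_frame([(mlr, p_bh)]))
        assert out.iloc[0]["called"] == expect_called
        assert out.iloc[0]["direction"] == expect_dir

    def test_intersection_rule_requires_both(self):
        out = call_differential(stat_frame([(1.098, 0.2), (1.098, 0.01)]),
                                rule="intersection")
        assert out["called"].tolist() == [False, True]

    def test_p_only_with_threshold_one_calls_every_nonzero_mean(self):
        out = call_differential(stat_frame([(0.001, 1.0), (0.0, 1.0)]),
                                rule="p_only", p_threshold=1.0)
        assert out["called"].tolist() == [True, False]


class TestMergeTimepoints:
    def gene_rows(self, entries):
        rows = []
        for gene, tp, direction in entries:
            rows.append({"gene": gene, "contrast": "mg_vs_ctrl",
                         "timepoint": tp, "direction": direction,
                         "called": direction != "none",
                         "FC": 2.0 if direction == "induced" else -2.0,
                         "splice_conflict": False})
        return pd.DataFrame(rows)

    def test_single_timepoint_member(self):
        lst, kin = merge_timepoints(
            self.gene_rows([("G1", "3h", "induced")]), "L1")
        assert ("G1", "induced") in lst
        assert not kin["biphasic"].any()

    def test_opposite_directions_across_timepoints_is_biphasic(self):
        lst, kin = merge_timepoints(
            self.gene_rows([("G1", "3h", "induced"),
                            ("G1", "12h", "repressed")]), "L1")
        assert lst.directions_of("G1") == {"induced", "repressed"}
        assert "biphasic" in lst.flags("G1", "induced")
        assert kin["biphasic"].all()

    def test_never_called_gene_absent(self):
        lst, _ = merge_timepoints(
            self.gene_rows([("G1", "3h", "none")]), "L1")
        assert len(lst) == 0

    def test_peak_timepoint_is_busiest(self):
        lst, kin = merge_timepoints(
            self.gene_rows([("G1", "3h", "induced"),
                            ("G2", "6h", "induced"),
                            ("G3", "6h", "repressed")]), "L1")
        assert (kin["peak_timepoint"] == "6h").all()


class TestAmplitudeSummary:
    def test_odd_length_median(self):
        df = pd.DataFrame({"direction": ["repressed"] * 3,
                           "FC": [-2.5, -2.0, -1.5]})
        out = amplitude_summary(df)
        assert out["repressed"].median_FC == -2.0
        assert out["repressed"].Q1 <= -2.0 <= out["repressed"].Q3

    def test_identical_distributions_give_p_near_one(self):
        df = pd.DataFrame({"direction": ["induced"] * 4 + ["repressed"] * 4,
                           "FC": [1.5, 2.0, 2.5, 3.0,
                                  -1.5, -2.0, -2.5, -3.0]})
        out = amplitude_summary(df)
        assert out["induced"].ranksum_p > 0.9

    def test_separated_distributions_give_small_p(self):
        df = pd.DataFrame({"direction": ["induced"] * 20 + ["repressed"] * 20,
                           "FC": [1.5] * 20 + [-3.0] * 20})
        out = amplitude_summary(df)
        assert out["induced"].ranksum_p < 0.001

    def test_empty_direction_omitted(self):
        df = pd.DataFrame({"direction": ["induced"] * 3,
                           "FC": [1.5, 2.0, 2.5]})
        out = amplitude_summary(df)
        assert "repressed" not in out
        assert math.isnan(out["induced"].ranksum_p)


class TestCalibrationAndPower:
    def test_null_raw_p_uniformity(self):
        """Type-I error of the replicate t test is at nominal level."""
        cfg = SimulationConfig(seed=19, n_genes=2000,
                               class_proportions={"NULL": 1.0},
                               probes_per_gene={1: 1.0}, frac_riken=0.0,
                               frac_control=0.0)
        ds = generate_experiment(cfg)
        stats = two_color_probe_stats(ds.tables["exp1"], ds.design, 1)
        one_tp = stats[stats["timepoint"] == "6h"]
        frac = (one_tp["p_raw"] <= 0.05).mean()
        sd = math.sqrt(0.05 * 0.95 / len(one_tp))
        assert abs(frac - 0.05) <= 3 * sd

    def test_power_on_planted_effects(self, noisy_dataset, noisy_result):
        """Planted 4-fold effects at sd 0.25, n=3 are called >= 90%."""
        truth = noisy_dataset.truth
        de_novo = set(truth.loc[truth["planted_class"] == "DE_NOVO", "gene"])
        gs = noisy_result.gene_stats
        sub = gs[(gs["contrast"] == "mghi_vs_hi") & gs["gene"].isin(de_novo)]
        called_genes = set(sub.loc[sub["called"], "gene"])
        assert len(called_genes) / len(de_novo) >= 0.9


class TestEquivalence:
    def test_band_and_p_both_required(self):
        df = pd.DataFrame({
            "gene": ["G1", "G2", "G3"],
            "p_raw": [0.5, 0.01, 0.5],
            "mean_log2_ratio": [0.1, 0.1, 1.0]})
        assert equivalent_genes(df) == {"G1"}

    def test_all_timepoints_must_agree(self):
        df = pd.DataFrame({
            "gene": ["G1", "G1"],
            "p_raw": [0.5, 0.01],
            "mean_log2_ratio": [0.1, 0.1]})
        assert equivalent_genes(df) == set()
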