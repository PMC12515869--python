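"""Fold change, assumption-gated testing, BH oracle, calls and recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lactylome as lm
from lactylome.differential import (DOWN, NS, STUDENT, UNTESTABLE, UP, WELCH,
                                    adjust_bh, call_significant, select_test)
from lactylome.differential import test_feature as gated_p_value

from conftest import toy_table


def bh_bruteforce(pvalues):
    """Independent step-up oracle: q_i = min over p_(j) >= p_(i) of
    p_(j) * m / rank(j), clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestFoldChange:
    def test_hand_examples(self, design_3v3):
        table = toy_table([[1, 1, 1, 1.6, 1.6, 1.6],
                           [1, 1, 1, 2, 2, 2],
                           [1, 1, 1, 1, 1, 1]])
        fc = lm.compute_fold_change(table, design_3v3)["fc"]
        assert np.allclose(fc, [1.6, 2.0, 1.0])

    def test_min_per_group_flags_untestable(self, design_3v3):
        table = toy_table([[1, np.nan, np.nan, 2, 2, 2]])
        out = lm.compute_fold_change(table, design_3v3)
        assert not out["testable"].iloc[0]
        assert out["fc"].iloc[0] == 2.0  # still computable from one value

    def test_all_missing_group_undefined(self, design_3v3):
        table = toy_table([[np.nan, np.nan, np.nan, 2, 2, 2]])
        out = lm.compute_fold_change(table, design_3v3)
        assert np.isnan(out["fc"].iloc[0])
        assert not out["testable"].iloc[0]


class TestSelectTest:
    def test_normal_samples_mostly_student(self, rng):
        # three 5%-level gates -> null pass rate ~0.95^3 ~ 0.857
        decisions = [select_test(rng.normal(0, 1, 50),
                                 rng.normal(0, 1, 50)).decision
                     for _ in range(300)]
        assert decisions.count(STUDENT) / len(decisions) >= 0.8

    def test_unequal_variance_triggers_welch(self, rng):
        decisions = [select_test(rng.normal(0, 1, 50),
                                 rng.normal(0, 10, 50)).decision
                     for _ in range(100)]
        assert decisions.count(WELCH) / len(decisions) >= 0.95

    def test_constant_equal_groups_untestable(self):
        report = select_test(np.array([1.0, 1.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        assert report.decision == UNTESTABLE
        assert gated_p_value(np.array([1.0] * 3), np.array([1.0] * 3),
                            report.decision) == 1.0

    def test_gate_invariant(self, rng):
        """decision == student iff both Shapiro ps and the Levene p clear
        the gate level."""
        for _ in range(50):
            a, b = rng.normal(0, 1, 8), rng.normal(0, rng.uniform(0.5, 4), 8)
            rep = select_test(a, b, gate_alpha=0.05)
            should_student = (rep.shapiro_p_control >= 0.05
                              and rep.shapiro_p_case >= 0.05
                              and rep.levene_p >= 0.05)
            assert (rep.decision == STUDENT) == should_student


class TestTestFeature:
    def test_identical_groups_p_one(self):
        a = np.array([0.1, 0.5, 0.9])
        rep = select_test(a, a.copy())
        assert gated_p_value(a, a.copy(), rep.decision) > 0.99

    def test_separation_limit(self):
        control = np.log2([1, 1, 1]) + np.array([-1e-6, 0, 1e-6])
        case = np.log2([4, 4, 4]) + np.array([-1e-6, 0, 1e-6])
        rep = select_test(control, case)
        assert gated_p_value(control, case, rep.decision) < 1e-6

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        reps = 1500
        for _ in range(reps):
            a, b = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
            rep = select_test(a, b)
            if gated_p_value(a, b, rep.decision) < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestAdjustBH:
    def test_hand_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_boundaries(self):
        assert adjust_bh([0.2]).tolist() == [0.2]
        assert adjust_bh([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
        assert adjust_bh([]).size == 0

    @settings(deadline=None, max_examples=200)
    @given(p=st.lists(st.floats(min_value=0.0, max_value=1.0,
                                allow_nan=False), min_size=1, max_size=50))
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(adjust_bh(p), bh_bruteforce(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])


class TestCallSignificant:
    @pytest.mark.parametrize("fc,p,expected", [
        (1.6, 0.01, UP),
        (1.4, 0.001, NS),     # fold change below the window
        (0.5, 0.03, DOWN),
        (2.0, 0.2, NS),       # not significant
        (1.5, 0.01, NS),      # boundary is exclusive
    ])
    def test_threshold_rule(self, fc, p, expected):
        assert call_significant(fc, p) == expected

    def test_nonpositive_fc_rejected(self):
        with pytest.raises(ValueError):
            call_significant(0.0, 0.01)


class TestDifferentialModel:
    def test_near_noiseless_spikes_all_called(self, proteome_500):
        design = lm.SyntheticDesign(noise_sd=0.01, sample_scale_sd=0.0,
                                    spike_frac_proteins=0.0, missing_rate=0.0,
                                    true_site_fc=2.0, seed=13)
        cat = lm.generate_lactylome(proteome_500, design)
        site, prot, truth = lm.generate_intensities(cat, design)
        corrected = lm.quantify_pipeline(site, prot, cat.site_protein_map(),
                                         design.group_design())
        res = lm.DifferentialModel(corrected, design.group_design()).fit()
        truth = truth.set_index("feature_id")
        spiked = truth.index[truth.spike_level == "site"]
        assert (res.table.loc[spiked, "call"] == UP).all()
        null = res.table.index.difference(spiked)
        assert (res.table.loc[null, "call"] == NS).all()

    def test_symmetry_under_group_swap(self, synthetic_run):
        design = synthetic_run["design"].group_design()
        swapped = lm.GroupDesign(control=design.case, case=design.control)
        corrected = synthetic_run["corrected"].iloc[:120]
        a = lm.DifferentialModel(corrected, design).fit().table
        b = lm.DifferentialModel(corrected, swapped).fit().table
        assert np.allclose(a["fc"], 1.0 / b["fc"], rtol=1e-9)
        assert np.allclose(a["p"], b["p"], atol=1e-9)
        assert ((a["call"] == UP) == (b["call"] == DOWN)).all()

    def test_case_scaling_monotone_in_fc(self, synthetic_run, design_3v3):
        corrected = synthetic_run["corrected"].iloc[:50]
        design = synthetic_run["design"].group_design()
        boosted = corrected.copy()
        boosted[list(design.case)] *= 1.7
        fc0 = lm.compute_fold_change(corrected, design)["fc"]
        fc1 = lm.compute_fold_change(boosted, design)["fc"]
        assert (fc1 >= fc0 - 1e-12).all()

    def test_recovery_on_default_spiked_conditions(self, synthetic_run):
        res = lm.DifferentialModel(synthetic_run["corrected"],
                                   synthetic_run["design"].group_design()).fit()
        truth = synthetic_run["truth"].set_index("feature_id")
        tab = res.table.join(truth[["spike_level"]])
        spiked = tab[tab.spike_level == "site"]
        called = tab[tab.call == UP]
        sensitivity = (spiked.call == UP).mean()
        fdp = 1 - (called.spike_level == "site").mean() if len(called) else 0.0
        assert sensitivity >= 0.7
        assert fdp <= 0.15

    def test_summary_and_counts_consistent(self, synthetic_run):
        res = lm.DifferentialModel(synthetic_run["corrected"],
                                   synthetic_run["design"].group_design()).fit()
        c = res.counts
        assert c["up"] + c["down"] + c["ns"] + c["untestable"] == c["n_features"]
        text = res.summary()
        assert f"up:   {c['up']}" in text and "fc > 1.5" in text

    def test_volcano_frame_columns(self, synthetic_run):
        res = lm.DifferentialModel(synthetic_run["corrected"].iloc[:30],
                                   synthetic_run["design"].group_design()).fit()
        vol = res.volcano_frame()
        assert list(vol.columns) == ["log2fc", "neg_log10_p", "call"]
        assert (vol["neg_log10_p"] >= 0).all()
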