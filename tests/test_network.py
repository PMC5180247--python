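"""Correlation networks: rank correlation, permutation-null thresholds with
their exact-enumeration oracle, DCC scans, group-specific edges and
reversed correlation changes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ionnet as inn
from conftest import make_plain_config


class TestSpearmanRho:
    def test_monotone_identity_reversal(self):
        assert inn.spearman_rho([1, 5, 9, 20], [2, 3, 10, 11]) == 1.0
        assert inn.spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_closed_form_tie_free(self):
        # sum d^2 = 6 at n = 6 -> 1 - 36/210
        rho = inn.spearman_rho(range(1, 7), [2, 1, 4, 3, 6, 5])
        assert rho == pytest.approx(1 - 6 * 6 / 210)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            inn.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=12,
                    unique=True),
           st.lists(st.floats(-1e6, 1e6), min_size=12, max_size=12,
                    unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_range_and_monotone_invariance(self, x, y):
        y = y[:len(x)]
        rho = inn.spearman_rho(x, y)
        assert -1.0 <= rho <= 1.0
        assert inn.spearman_rho(y, x) == pytest.approx(rho)
        assert inn.spearman_rho([math.atan(v / 1e6) for v in x], y) == \
            pytest.approx(rho)


class TestDeltaScc:
    def test_published_worked_example(self):
        assert inn.delta_scc(0.886, -0.6) == 1.486
        assert inn.delta_scc(-0.319, 0.886) == -1.205
        assert inn.delta_scc(0.5, 0.5) == 0.0

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=100, derandomize=True)
    def test_antisymmetric_and_bounded(self, a, b):
        d = inn.delta_scc(a, b)
        assert abs(d) <= 2.0
        assert inn.delta_scc(b, a) == pytest.approx(-d)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inn.delta_scc(1.2, 0.0)


class TestExactNullTail:
    def test_small_n_counts(self):
        assert inn.exact_null_scc_tail(3, 1.0) == pytest.approx(1 / 6)
        assert inn.exact_null_scc_tail(4, 1.0) == pytest.approx(1 / 24)
        assert inn.exact_null_scc_tail(5, -1.0) == 1.0

    def test_n6_atoms_bracket_the_5pct_point(self):
        # null atoms at n = 6: ... 0.7714 (sum d^2 = 8), 0.8286 (= 6) ...
        assert inn.exact_null_scc_tail(6, 1 - 6 * 8 / 210) == pytest.approx(
            37 / 720)
        assert inn.exact_null_scc_tail(6, 1 - 6 * 6 / 210) == pytest.approx(
            21 / 720)

    def test_matches_independent_pairwise_enumeration_at_n4(self):
        # oracle enumerating BOTH permutations (576 pairs) rather than one
        from scipy import stats
        vals = [stats.spearmanr(p, q).statistic
                for p in itertools.permutations(range(4))
                for q in itertools.permutations(range(4))]
        for q_ in (-1.0, -0.5, 0.0, 0.4, 0.8, 1.0):
            expected = np.mean([v >= q_ - 1e-9 for v in vals])
            assert inn.exact_null_scc_tail(4, q_) == pytest.approx(expected)

    def test_enumeration_limit(self):
        with pytest.raises(ValueError):
            inn.exact_null_scc_tail(9, 0.5)


class TestSimulatedThresholds:
    def test_scc_threshold_near_published_value(self):
        est = inn.simulate_scc_threshold(6, inner_reps=1000, outer_reps=200,
                                         seed=0)
        assert est.point == pytest.approx(0.749, abs=0.03)
        assert 0.0 < est.ci_half_width < 0.08

    def test_dcc_threshold_near_published_value(self):
        est = inn.simulate_dcc_threshold(6, inner_reps=1000, outer_reps=200,
                                         seed=0)
        assert est.point == pytest.approx(1.05, abs=0.05)

    def test_dcc_exceeds_scc_threshold(self):
        scc = inn.simulate_scc_threshold(6, outer_reps=50, seed=1).point
        dcc = inn.simulate_dcc_threshold(6, outer_reps=50, seed=1).point
        assert dcc > scc

    def test_threshold_decreases_with_sample_size(self):
        pts = [inn.simulate_scc_threshold(n, outer_reps=50, seed=2).point
               for n in (4, 6, 10)]
        assert pts[0] > pts[1] > pts[2]
        pts = [inn.simulate_dcc_threshold(n, outer_reps=50, seed=2).point
               for n in (4, 6, 10)]
        assert pts[0] > pts[1] > pts[2]

    def test_alpha_to_zero_reaches_support_maximum(self):
        est = inn.simulate_scc_threshold(4, alpha=1e-4, inner_reps=2000,
                                         outer_reps=20, seed=3)
        assert est.point == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_tail_at_simulated_point_near_alpha(self, n):
        est = inn.simulate_scc_threshold(n, inner_reps=1000, outer_reps=100,
                                         seed=4)
        tail = inn.exact_null_scc_tail(n, est.point)
        assert 0.03 <= tail <= 0.07

    def test_dcc_point_agrees_with_large_monte_carlo_oracle(self):
        # independent oracle: one-shot quantile of 10^6 null differences
        rng = np.random.default_rng(5)
        n = 6
        def draws(size):
            a = np.argsort(rng.random((size, n)), axis=1)
            b = np.argsort(rng.random((size, n)), axis=1)
            return 1 - 6 * ((a - b) ** 2).sum(axis=1) / (n * (n * n - 1))
        oracle = np.quantile(draws(10 ** 6) - draws(10 ** 6), 0.95)
        est = inn.simulate_dcc_threshold(6, inner_reps=1000, outer_reps=200,
                                         seed=6)
        assert abs(est.point - oracle) < 2 * est.ci_half_width


class TestSccMatrix:
    def test_full_panel_gives_105_edges(self, default_dataset):
        edges = inn.scc_matrix(default_dataset, "WT", 4.0)
        assert len(edges) == 105
        assert (edges["element_a"] != edges["element_b"]).all()

    def test_four_elements_give_six_edges(self):
        cfg = make_plain_config(elements=("Fe", "Zn", "Cu", "Se"))
        ds = inn.generate_dataset(cfg, seed=0)
        assert len(inn.scc_matrix(ds, "WT", 4.0)) == 6

    def test_missing_cell_rejected(self, default_dataset):
        with pytest.raises(KeyError):
            inn.scc_matrix(default_dataset, "Se", 2.0)

    def test_significance_flag_matches_threshold(self, default_dataset):
        edges = inn.scc_matrix(default_dataset, "AD", 8.0, tau_scc=0.749)
        assert (edges["significant"] == (edges["scc"].abs() > 0.749)).all()


class TestDccScan:
    def test_relabelled_dataset_has_zero_deltas(self):
        cfg = make_plain_config(groups=("WT",), timepoints=(4., 6.))
        ds = inn.generate_dataset(cfg, seed=0)
        clone = ds.records.copy()
        clone["group"] = "AD"
        clone["sample_id"] = "x" + clone["sample_id"]
        both = inn.IonomeDataset(pd.concat([ds.records, clone],
                                           ignore_index=True))
        dcc = inn.dcc_scan(both, "AD", "WT")
        assert (dcc["delta"] == 0).all()
        assert not dcc["significant"].any()

    def test_antisymmetric_under_group_swap(self, default_dataset):
        fwd = inn.dcc_scan(default_dataset, "AD", "WT")
        rev = inn.dcc_scan(default_dataset, "WT", "AD")
        assert np.allclose(fwd["delta"], -rev["delta"])

    def test_planted_opposite_correlations_detected(self):
        planted = [("A", 4.0, "Fe", "Mn", 0.9), ("B", 4.0, "Fe", "Mn", -0.9)]
        cfg = make_plain_config(groups=("A", "B"), planted=planted)
        hits = 0
        for seed in range(20):
            dcc = inn.dcc_scan(inn.generate_dataset(cfg, seed=seed), "A", "B")
            row = dcc[(dcc["element_a"] == "Fe") & (dcc["element_b"] == "Mn")]
            hits += bool(row["significant"].iloc[0])
        assert hits >= 16

    def test_no_shared_times_rejected(self):
        cfg = inn.SyntheticConfig(
            groups=("A", "B"), timepoints_by_group={"A": (2.,), "B": (4.,)},
            n_replicates=6, elements=("Fe", "Zn", "Cu"),
            cell_means={(g, t, e): 1.0 for g, ts in
                        {"A": (2.,), "B": (4.,)}.items() for t in ts
                        for e in ("Fe", "Zn", "Cu")},
            cell_cv={"Fe": 0.2, "Zn": 0.2, "Cu": 0.2})
        ds = inn.generate_dataset(cfg, seed=0)
        with pytest.raises(ValueError):
            inn.dcc_scan(ds, "A", "B")


class TestGroupSpecificEdges:
    @staticmethod
    def _edges(rows):
        return pd.DataFrame(rows, columns=["element_a", "element_b", "group",
                                           "time_months", "scc", "significant"])

    def test_single_group_edge_is_specific(self):
        edges = self._edges([
            ("Fe", "Zn", "A", 4.0, 0.9, True),
            ("Fe", "Zn", "B", 4.0, 0.1, False),
            ("Fe", "Zn", "A", 6.0, 0.2, False),
        ])
        assert inn.group_specific_edges(edges) == {"A": [("Fe", "Zn")], "B": []}

    def test_edge_in_two_groups_is_specific_to_none(self):
        edges = self._edges([
            ("Fe", "Zn", "A", 4.0, 0.9, True),
            ("Fe", "Zn", "B", 6.0, 0.9, True),
        ])
        assert inn.group_specific_edges(edges) == {"A": [], "B": []}

    def test_planted_single_group_correlation_recovered(self):
        # disease-only Zn-Se coupling at a single shared time point
        planted = [("AD", 4.0, "Zn", "Se", 0.95)]
        cfg = make_plain_config(groups=("WT", "AD"), planted=planted)
        hits = 0
        for seed in range(20):
            ds = inn.generate_dataset(cfg, seed=seed)
            specific = inn.group_specific_edges(inn.scc_tables(ds))
            hits += ("Zn", "Se") in specific["AD"] or ("Se", "Zn") in specific["AD"]
        assert hits >= 11


class TestOverlapAndReversed:
    @staticmethod
    def _dcc(rows):
        return pd.DataFrame(rows, columns=[
            "element_a", "element_b", "time_months", "group1", "group2",
            "scc_group1", "scc_group2", "delta", "significant"])

    def test_published_fe_mn_example_is_shared_and_reversed(self):
        ad_wt = self._dcc([("Fe", "Mn", 4.0, "AD", "WT", 0.886, -0.6,
                            inn.delta_scc(0.886, -0.6), True)])
        se_ad = self._dcc([("Fe", "Mn", 4.0, "Se", "AD", -0.319, 0.886,
                            inn.delta_scc(-0.319, 0.886), True)])
        shared, rev = inn.overlap_and_reversed_dccs(ad_wt, se_ad)
        assert len(shared) == 1 and len(rev) == 1
        assert rev.loc[0, "delta_a"] == 1.486
        assert rev.loc[0, "delta_b"] == -1.205

    def test_same_sign_overlap_not_reversed(self):
        a = self._dcc([("Fe", "Mn", 4.0, "A", "B", 0.9, -0.4, 1.3, True)])
        b = self._dcc([("Fe", "Mn", 4.0, "C", "A", 0.8, -0.4, 1.2, True)])
        shared, rev = inn.overlap_and_reversed_dccs(a, b)
        assert len(shared) == 1 and len(rev) == 0

    def test_disjoint_sets_give_empty_outputs(self):
        a = self._dcc([("Fe", "Mn", 4.0, "A", "B", 0.9, -0.4, 1.3, True)])
        b = self._dcc([("Zn", "Cu", 6.0, "C", "A", 0.8, -0.4, 1.2, True)])
        shared, rev = inn.overlap_and_reversed_dccs(a, b)
        assert shared.empty and rev.empty

    def test_end_to_end_fe_mn_reversal_recovered(self):
        """Planting a clear reversal pattern (disease flips Fe-Mn strongly
        positive, treatment restores it strongly negative) is recovered as a
        reversed DCC in the majority of seeds."""
        planted = [("AD", 4.0, "Fe", "Mn", 0.9),
                   ("WT", 4.0, "Fe", "Mn", -0.6),
                   ("Se", 4.0, "Fe", "Mn", -0.75)]
        cfg = make_plain_config(groups=("WT", "AD", "Se"), planted=planted)
        hits = 0
        for seed in range(15):
            ds = inn.generate_dataset(cfg, seed=seed)
            ad_wt = inn.dcc_scan(ds, "AD", "WT")
            se_ad = inn.dcc_scan(ds, "Se", "AD")
            _, rev = inn.overlap_and_reversed_dccs(ad_wt, se_ad)
            hits += (((rev["element_a"] == "Fe") & (rev["element_b"] == "Mn")
                      & (rev["time_months"] == 4.0)).any())
        assert hits >= 8
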