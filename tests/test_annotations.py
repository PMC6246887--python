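"""Consensus boundary construction from observer press logs."""

import numpy as np
import pandas as pd
import pytest

from filmseg import annotations as ann
from filmseg.synth import GroundTruth, simulate_observers

from conftest import make_annotations


class TestCorrectRt:
    def test_shifts_presses_by_reaction_time(self):
        a = make_annotations({"o1": [10.9, 20.9]}, rt_corrected=False)
        out = ann.correct_rt(a, rt=0.9)
        assert out["press_time_s"].tolist() == [10.0, 20.0]
        assert out.attrs["rt_corrected"]

    def test_zero_rt_is_identity(self):
        a = make_annotations({"o1": [5.0, 9.5]}, rt_corrected=False)
        assert ann.correct_rt(a, rt=0.0)["press_time_s"].tolist() == [5.0, 9.5]

    def test_clamps_at_zero(self):
        a = make_annotations({"o1": [0.5]}, rt_corrected=False)
        assert ann.correct_rt(a, rt=0.9)["press_time_s"].tolist() == [0.0]

    def test_double_correction_rejected(self):
        a = make_annotations({"o1": [5.0]}, rt_corrected=False)
        once = ann.correct_rt(a, rt=0.9)
        with pytest.raises(ValueError, match="already"):
            ann.correct_rt(once, rt=0.9)


class TestMergeBoundaries:
    def test_pass1_chains_presses_within_one_tr(self):
        # 10.0 -> 10.8 (0.8 s) -> 12.1 (1.3 s), both gaps <= TR = 2.47
        a = make_annotations({"o1": [10.0], "o2": [10.8], "o3": [12.1]})
        out = ann.merge_boundaries(a, tr=2.47)
        assert len(out) == 1
        assert out.loc[0, "time_s"] == pytest.approx(10.9667, abs=1e-3)
        assert out.loc[0, "n_observers"] == 3

    def test_pass2_no_merge_when_gap_at_least_two_tr(self):
        # pass-1 boundaries at 10.0 (n=3) and 13.0 (n=4); 2*TR = 3.0 = gap
        a = make_annotations({"o1": [9.8], "o2": [10.0], "o3": [10.2],
                              "o4": [12.8], "o5": [12.9], "o6": [13.1],
                              "o7": [13.2]})
        out = ann.merge_boundaries(a, tr=1.5)
        assert out["n_observers"].tolist() == [3, 4]
        assert out["time_s"].tolist() == pytest.approx([10.0, 13.0])

    def test_pass2_merges_close_pair_with_two_plus_observers_each(self):
        # pass-1 clusters {9, 9.5, 10} (mean 9.5, n=3) and {11.2, 11.4}
        # (mean 11.3, n=2); gap 1.8 < 2*TR = 2 -> one boundary at the mean
        # of all five presses with summed observer count
        a = make_annotations({"o1": [9.0], "o2": [9.5], "o3": [10.0],
                              "o4": [11.2], "o5": [11.4]})
        out = ann.merge_boundaries(a, tr=1.0)
        assert len(out) == 1
        assert out.loc[0, "n_observers"] == 5
        assert out.loc[0, "time_s"] == pytest.approx(10.22)

    def test_pass2_runs_once_not_to_convergence(self):
        # three clusters each 1.8 s apart: a convergent merge would chain all
        # three; the single pass merges only the first pair
        a = make_annotations({"o1": [9.9], "o2": [10.1],
                              "o3": [11.7], "o4": [11.9],
                              "o5": [13.5], "o6": [13.7]})
        out = ann.merge_boundaries(a, tr=1.0)
        assert out["n_observers"].tolist() == [4, 2]

    def test_one_observer_pressing_twice_counts_once(self):
        a = make_annotations({"o1": [10.0, 10.4], "o2": [10.2]})
        out = ann.merge_boundaries(a, tr=2.0)
        assert out.loc[0, "n_observers"] == 2
        # o1's presses average to 10.2 first, then mean with o2's 10.2
        assert out.loc[0, "time_s"] == pytest.approx(10.2)

    def test_invariant_to_observer_relabeling_and_order(self):
        rng = np.random.default_rng(0)
        presses = {f"o{i}": sorted(rng.uniform(0, 100, 5)) for i in range(6)}
        a = make_annotations(presses)
        out1 = ann.merge_boundaries(a, tr=2.0)
        shuffled = a.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled.attrs["rt_corrected"] = True
        relabeled = shuffled.copy()
        relabeled["observer_id"] = shuffled["observer_id"].map(
            {f"o{i}": f"x{5 - i}" for i in range(6)})
        relabeled.attrs["rt_corrected"] = True
        out2 = ann.merge_boundaries(relabeled, tr=2.0)
        assert np.allclose(out1["time_s"], out2["time_s"])
        assert out1["n_observers"].tolist() == out2["n_observers"].tolist()

    def test_observer_votes_never_exceed_press_count(self):
        rng = np.random.default_rng(3)
        a = make_annotations(
            {f"o{i}": sorted(rng.uniform(0, 60, 8)) for i in range(5)})
        out = ann.merge_boundaries(a, tr=2.0)
        assert out["n_observers"].sum() <= len(a)

    def test_empty_input(self):
        a = make_annotations({})
        assert ann.merge_boundaries(a, tr=2.0).empty


class TestDropRunEnd:
    @pytest.mark.parametrize("time,kept", [(595.0, False), (589.0, True)])
    def test_ten_second_margin(self, time, kept):
        b = pd.DataFrame({"run_id": ["r"], "time_s": [time],
                          "n_observers": [5]})
        out = ann.drop_run_end(b, run_duration=600.0)
        assert (len(out) == 1) is kept

    def test_empty(self):
        b = pd.DataFrame(columns=["run_id", "time_s", "n_observers"])
        assert ann.drop_run_end(b, 600.0).empty


class TestSelectThreshold:
    def _boundaries(self, n_observer_values):
        return pd.DataFrame({"time_s": np.arange(len(n_observer_values),
                                                 dtype=float) * 20,
                             "n_observers": n_observer_values})

    def test_picks_count_closest_to_observer_mean(self):
        # counts at k: 1..3 -> 25, 4 -> 25, 5 -> 21, 6 -> 15; mean total 20
        b = self._boundaries([4] * 4 + [5] * 6 + [6] * 15)
        a = make_annotations({"o1": list(np.arange(20.0)),
                              "o2": list(np.arange(20.0) + 0.1)})
        assert ann.select_threshold(b, a) == 5

    def test_tie_goes_to_lower_threshold(self):
        # counts: k=5 -> 22, k=6 -> 20, everything else worse; mean 21
        b = self._boundaries([1, 1, 2, 2, 3, 3, 4, 4] + [5] * 2 + [6] * 20)
        a = make_annotations({"o1": list(np.arange(21.0)),
                              "o2": list(np.arange(21.0) + 0.1)})
        assert ann.select_threshold(b, a) == 5

    def test_degenerate_full_agreement_returns_one(self):
        b = self._boundaries([3] * 10)
        a = make_annotations({f"o{i}": list(np.arange(10.0)) for i in range(3)})
        assert ann.select_threshold(b, a) == 1

    def test_thresholding_keeps_only_qualifying_boundaries(self):
        b = self._boundaries([2, 5, 7, 3, 9])
        out = ann.apply_threshold(b, 5)
        assert (out["n_observers"] >= 5).all()
        assert len(out) == 3


class TestBinSalience:
    def test_equal_tallies_split_evenly(self):
        b = pd.DataFrame({"time_s": np.arange(12.0),
                          "n_observers": [5] * 4 + [6] * 4 + [7] * 4})
        out = ann.bin_salience(b)
        assert out["salience_bin"].value_counts().tolist() == [4, 4, 4]

    def test_counts_sum_to_input(self):
        rng = np.random.default_rng(5)
        b = pd.DataFrame({"time_s": np.arange(40.0),
                          "n_observers": rng.integers(5, 17, 40)})
        out = ann.bin_salience(b)
        assert out["salience_bin"].notna().all()
        assert len(out) == 40

    def test_degenerate_single_level_flagged(self):
        b = pd.DataFrame({"time_s": [0.0, 1.0], "n_observers": [5, 5]})
        out = ann.bin_salience(b)
        assert out.attrs["degenerate_salience_bins"]


class TestFullChain:
    def test_perfect_agreement_recovers_ground_truth(self, small_gt):
        log = simulate_observers(small_gt, rt_mean=0.9, rt_jitter=0.0)
        b = ann.consensus_boundaries(log, tr=small_gt.tr,
                                     run_duration=small_gt.run_length)
        assert len(b) == len(small_gt.boundary_times)
        assert np.allclose(b["time_s"], small_gt.boundary_times, atol=1e-9)
        assert (b["n_observers"] == small_gt.n_observers).all()


class TestCompareObserverGroups:
    def test_duplicated_group_matches_fully(self):
        # group B is a relabeled copy of group A: the observed consensus
        # sets coincide, while random re-splits mix the copies and agree
        # no better (almost always worse, given press-time jitter)
        gt = GroundTruth(boundary_times=[20.0, 60.0, 110.0, 150.0],
                         salience_prob=0.9, amplitudes=1.0, run_length=200.0,
                         tr=2.0, n_observers=4, seed=0)
        log_a = simulate_observers(gt, rt_mean=0.9, rt_jitter=0.3)
        log_b = log_a.copy()
        log_b["observer_id"] = log_b["observer_id"] + "_copy"
        log_b.attrs["rt_corrected"] = False
        res = ann.compare_observer_groups(log_a, log_b, tr=2.0,
                                          run_duration=200.0, n_perm=50,
                                          rng=0)
        assert res["observed_match"] == 4
        assert res["p_lower"] >= 0.5

    def test_seeded_runs_reproducible(self):
        gt = GroundTruth(boundary_times=[20.0, 60.0, 110.0],
                         salience_prob=0.8, amplitudes=1.0, run_length=200.0,
                         tr=2.0, n_observers=6, seed=3)
        log = simulate_observers(gt, rt_mean=0.9, rt_jitter=0.2)
        half = list(pd.unique(log["observer_id"]))[:3]
        a = log[log["observer_id"].isin(half)].copy()
        b = log[~log["observer_id"].isin(half)].copy()
        for df in (a, b):
            df.attrs["rt_corrected"] = False
        r1 = ann.compare_observer_groups(a, b, tr=2.0, run_duration=200.0,
                                         n_perm=30, rng=5)
        a2, b2 = a.copy(), b.copy()
        for df in (a2, b2):
            df.attrs["rt_corrected"] = False
        r2 = ann.compare_observer_groups(a2, b2, tr=2.0, run_duration=200.0,
                                         n_perm=30, rng=5)
        assert r1["p_lower"] == r2["p_lower"]
        assert np.array_equal(r1["null_matches"], r2["null_matches"])


class TestMatchBoundaries:
    def test_greedy_one_to_one(self):
        # one reference boundary between two test events: only one match
        assert ann.match_boundaries([10.0], [9.5, 10.4], window=1.0) == 1

    def test_no_double_counting(self):
        assert ann.match_boundaries([10.0, 10.5], [10.2], window=1.0) == 1
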