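import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from sheltering.core_model import GroupComposition, ModelParams
from sheltering.group_statistics import (
    binomial_sociality_test,
    consensus_metrics,
    consensus_table,
    occupancy_difference_distribution,
    ps_cs_permutation_test,
    resampling_condition_test,
)
from sheltering.simulator import simulate_trials

GRID = list(range(0, 190, 10)) + [1440]


def _trajectory_table(trial_id, ps_series, cs_series, n=10):
    rows = []
    for t, ps, cs in zip(GRID, ps_series, cs_series):
        rows.append((trial_id, t, ps, cs, n - ps - cs))
    return make_table(rows)


class TestConsensusMetrics:
    def test_split_trial_is_not_a_consensus_under_sheltered_basis(self):
        # a 7-vs-3 final split stays below the 90% consensus threshold
        tab = _trajectory_table("t1", [0] * 19 + [7], [0] * 19 + [3])
        s = consensus_metrics(tab, basis="sheltered")
        assert s.winner == "PS"
        assert s.consensus is False

    def test_nine_one_zero_is_consensus_under_both_bases(self):
        # 9 PS / 1 CS / 0 outside sits exactly at the (inclusive) 0.9 threshold
        tab = _trajectory_table("t1", [0] * 19 + [9], [0] * 19 + [1])
        assert consensus_metrics(tab, basis="sheltered").consensus is True
        assert consensus_metrics(tab, basis="total").consensus is True

    def test_settling_time_from_first_lead(self):
        ps = [0] + [k for k in range(1, 20)]
        cs = [0] * 20
        tab = _trajectory_table("t1", [min(p, 9) for p in ps], cs)
        s = consensus_metrics(tab)
        assert s.winner == "PS" and s.t_w_min == 10 and not s.t_w_censored

    def test_tie_at_end_censors_settling_time(self):
        tab = _trajectory_table("t1", [0] * 19 + [5], [0] * 19 + [5])
        s = consensus_metrics(tab)
        assert s.winner is None and s.t_w_min is None and s.t_w_censored

    def test_no_sheltered_flags_consensus_undefined(self):
        tab = _trajectory_table("t1", [0] * 20, [0] * 20)
        assert consensus_metrics(tab, basis="sheltered").consensus is None

    def test_settling_time_matches_bruteforce_rescan(self, rng):
        # oracle: literal O(T^2) check of the definition on random walks
        for rep in range(30):
            ps = rng.integers(0, 6, size=len(GRID))
            cs = rng.integers(0, 6, size=len(GRID))
            tab = _trajectory_table(f"t{rep}", ps, cs, n=12)
            s = consensus_metrics(tab)
            if ps[-1] > cs[-1]:
                winner_ps, winner_cs = ps, cs
            elif cs[-1] > ps[-1]:
                winner_ps, winner_cs = cs, ps
            else:
                assert s.t_w_min is None
                continue
            expected = None
            for k in range(len(GRID)):
                if all(winner_ps[m] > winner_cs[m] for m in range(k, len(GRID))):
                    expected = GRID[k]
                    break
            assert s.t_w_min == expected

    def test_consensus_table_collects_all_trials(self):
        tab = pd.concat(
            [
                _trajectory_table("a", [0] * 19 + [10], [0] * 20),
                _trajectory_table("b", [0] * 19 + [4], [0] * 19 + [6]),
            ]
        )
        ct = consensus_table(tab)
        assert set(ct.trial_id) == {"a", "b"}
        assert ct.set_index("trial_id").loc["a", "winner"] == "PS"
        assert ct.set_index("trial_id").loc["b", "winner"] == "CS"


class TestResamplingConditionTest:
    def test_same_table_is_never_significant(self):
        tabs = []
        rng = np.random.default_rng(1)
        for k in range(6):
            ps = np.sort(rng.integers(0, 8, size=len(GRID)))
            tabs.append(_trajectory_table(f"t{k}", ps, [0] * len(GRID)))
        tab = pd.concat(tabs)
        res = resampling_condition_test(tab, tab, 2000, seed=2)
        assert not res.table.significant.any()

    def test_threefold_exploration_difference_is_detected_early(self):
        fast = {"naive": ModelParams(1e-3, 0.63, 0.002, 1.19)}
        slow = {"naive": ModelParams(1e-3 / 3, 0.63, 0.002, 1.19)}
        ta = pd.concat(
            t.to_frame()
            for t in simulate_trials(GroupComposition(10, 0, fast), 15, 86_400, seed=3,
                                     record_times_min=GRID)
        )
        tb = pd.concat(
            t.to_frame()
            for t in simulate_trials(GroupComposition(10, 0, slow), 19, 86_400, seed=4,
                                     record_times_min=GRID)
        )
        res = resampling_condition_test(ta, tb, 2000, seed=5)
        early = res.table[res.table.time_min.between(20, 90)]
        assert early.significant.all()

    def test_requires_two_trials(self):
        tab = _trajectory_table("only", [0] * 20, [0] * 20)
        with pytest.raises(ValueError):
            resampling_condition_test(tab, tab, 100, seed=0)

    def test_mismatched_grids_raise(self):
        a = _trajectory_table("a", [0] * 20, [0] * 20)
        b = make_table([("b", 0, 0, 0, 10), ("b", 99, 5, 0, 5)])
        with pytest.raises(ValueError):
            resampling_condition_test(pd.concat([a, a.assign(trial_id="a2")]),
                                      pd.concat([b, b.assign(trial_id="b2")]),
                                      100, seed=0)


class TestBinomialSocialityTest:
    def test_identical_trials_never_reject(self):
        tab = pd.concat(
            _trajectory_table(f"t{k}", [0] * 19 + [7], [0] * 19 + [3]) for k in range(8)
        )
        res = binomial_sociality_test(tab, "PS", 2000, seed=6)
        final = res.table[res.table.time_min == 1440].iloc[0]
        assert final.statistic == 0.0 and not final.significant

    def test_social_dynamics_rejected_after_onset(self):
        # once aggregates have formed, the across-trial variance of the PS
        # count is far above the binomial null in nearly every dataset
        params = {"naive": ModelParams(1e-3, 0.63, 0.002, 1.19)}
        comp = GroupComposition(10, 0, params)
        times = [120, 1440]
        hits = dict.fromkeys(times, 0)
        reps = 100
        for child in np.random.SeedSequence(7).spawn(reps):
            seed = int(child.generate_state(1, dtype=np.uint32)[0])
            tab = pd.concat(
                t.to_frame()
                for t in simulate_trials(comp, 15, 86_400, seed=seed,
                                         record_times_min=times)
            )
            res = binomial_sociality_test(tab, "PS", 1000, seed=seed)
            for t in times:
                hits[t] += int(res.table.set_index("time_min").loc[t].significant)
        assert hits[120] / reps >= 0.9
        assert hits[1440] / reps >= 0.8

    def test_zero_sheltered_steps_are_skipped(self):
        tab = pd.concat(
            _trajectory_table(f"t{k}", [0] * 19 + [9], [0] * 19 + [1]) for k in range(4)
        )
        res = binomial_sociality_test(tab, "PS", 500, seed=9)
        assert res.table[res.table.time_min == 0].iloc[0].skipped


class TestPermutationTest:
    def test_mirrored_table_gives_p_near_one(self):
        half = [_trajectory_table(f"t{k}", [0] * 19 + [8], [0] * 19 + [2]) for k in range(4)]
        mirror = [_trajectory_table(f"m{k}", [0] * 19 + [2], [0] * 19 + [8]) for k in range(4)]
        tab = pd.concat(half + mirror)
        res = ps_cs_permutation_test(tab, "PS", 2000, seed=10)
        assert res.table[res.table.time_min == 1440].iloc[0].p_value > 0.5

    def test_total_asymmetry_is_significant(self):
        tab = pd.concat(
            _trajectory_table(f"t{k}", [0] * 19 + [10], [0] * 20) for k in range(6)
        )
        res = ps_cs_permutation_test(tab, "PS", 2000, seed=11)
        assert res.table[res.table.time_min == 1440].iloc[0].significant

    def test_odour_preference_power_at_three_hours(self):
        # replicate synthetic naive datasets: PS preference should be detected
        # at 180 min in the vast majority of experiments
        params = {"naive": ModelParams(1e-3, 0.63, 0.002, 1.19)}
        hits = 0
        reps = 300
        for k, child in enumerate(np.random.SeedSequence(12).spawn(reps)):
            seed = int(child.generate_state(1, dtype=np.uint32)[0])
            tab = pd.concat(
                t.to_frame()
                for t in simulate_trials(GroupComposition(10, 0, params), 15, 10_800,
                                         seed=seed, record_times_min=[180])
            )
            res = ps_cs_permutation_test(tab, "PS", 1000, seed=seed)
            hits += int(res.table.iloc[0].significant)
        assert hits / reps >= 0.8


class TestOccupancyDifference:
    def test_single_trial_point_mass(self):
        tab = _trajectory_table("t1", [0] * 19 + [8], [0] * 19 + [1])
        hist = occupancy_difference_distribution(tab)
        final = hist[hist.time_min == 1440]
        assert final.diff().size >= 1
        assert final["diff"].tolist() == [7] and final.n_trials.tolist() == [1]

    def test_histogram_counts_sum_to_trial_count(self):
        rng = np.random.default_rng(13)
        tabs = []
        for k in range(9):
            ps = rng.integers(0, 6, size=len(GRID))
            cs = rng.integers(0, 5, size=len(GRID))
            tabs.append(_trajectory_table(f"t{k}", ps, cs, n=12))
        hist = occupancy_difference_distribution(pd.concat(tabs))
        assert (hist.groupby("time_min").n_trials.sum() == 9).all()

    def test_symmetric_dynamics_give_symmetric_differences(self):
        params = {"naive": ModelParams(1e-3, 0.5, 0.002, 1.19)}
        tab = pd.concat(
            t.to_frame()
            for t in simulate_trials(GroupComposition(10, 0, params), 400, 86_400,
                                     seed=14, record_times_min=[1440])
        )
        hist = occupancy_difference_distribution(tab)
        mean_diff = (hist["diff"] * hist.n_trials).sum() / hist.n_trials.sum()
        # symmetric mu: mean of N_ps - N_cs is 0 within MC error (sd ~ 10/sqrt(400))
        assert abs(mean_diff) < 3 * 10 / np.sqrt(400)


def test_results_invariant_to_trial_ordering():
    rng = np.random.default_rng(15)
    tabs = []
    for k in range(7):
        ps = rng.integers(0, 6, size=len(GRID))
        cs = rng.integers(0, 5, size=len(GRID))
        tabs.append(_trajectory_table(f"t{k}", ps, cs, n=12))
    tab = pd.concat(tabs, ignore_index=True)
    shuffled = tab.sample(frac=1.0, random_state=16).reset_index(drop=True)
    for fn in (
        lambda t: binomial_sociality_test(t, "PS", 500, seed=17).table.p_value,
        lambda t: ps_cs_permutation_test(t, "PS", 500, seed=17).table.p_value,
    ):
        pd.testing.assert_series_equal(fn(tab), fn(shuffled))
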