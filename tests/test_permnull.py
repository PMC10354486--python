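import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kitepeck import (
    brood_day_covariates,
    bootstrap_splits,
    daily_directed_counts,
    deviation_table,
    expected_counts_analytic,
    expected_counts_mc,
    filter_observation_window,
    first_peck_filter,
)
from kitepeck.permnull import expected_matrix_analytic, expected_matrix_mc

RANK_IDX = {"S": 0, "M": 1, "J": 2}


def _counts_frame(per_dyad: dict, brood="B1", date=dt.date(2020, 5, 8)):
    rows = []
    for (a, r) in [("S", "M"), ("S", "J"), ("M", "S"), ("M", "J"),
                   ("J", "S"), ("J", "M")]:
        rows.append((brood, date, a, r, per_dyad.get((a, r), 0), False))
    return pd.DataFrame(
        rows, columns=["brood_id", "date", "attacker_rank", "recipient_rank",
                       "count", "zero_day"]
    )


class TestDailyDirectedCounts:
    def test_tabulation(self, tiny_dataset):
        counts = daily_directed_counts(tiny_dataset.pecks)
        day = counts[counts["date"] == dt.date(2020, 5, 8)].set_index(
            ["attacker_rank", "recipient_rank"]
        )["count"]
        assert day[("S", "M")] == 2
        assert day[("S", "J")] == 1
        assert day[("M", "J")] == 1
        assert day.sum() == 4

    def test_conservation(self, tiny_dataset):
        counts = daily_directed_counts(tiny_dataset.pecks)
        assert counts["count"].sum() == len(tiny_dataset.pecks)

    def test_zero_day_flagging(self, tiny_dataset, weights):
        cov = brood_day_covariates(tiny_dataset, weights)
        extra = pd.concat(
            [cov, pd.DataFrame({"brood_id": ["B1"],
                                "date": [dt.date(2020, 5, 11)]})],
            ignore_index=True,
        )
        counts = daily_directed_counts(tiny_dataset.pecks, extra)
        flagged = counts[counts["date"] == dt.date(2020, 5, 11)]
        assert len(flagged) == 6
        assert flagged["zero_day"].all()
        assert (flagged["count"] == 0).all()


class TestExpectedCounts:
    def test_analytic_closed_form(self):
        counts = _counts_frame({("S", "M"): 12, ("M", "S"): 3, ("M", "J"): 1,
                                ("J", "S"): 1})
        expected = expected_counts_analytic(counts).set_index(
            ["attacker_rank", "recipient_rank"]
        )["expected"]
        assert expected[("S", "M")] == expected[("S", "J")] == 6.0
        assert expected[("M", "S")] == expected[("M", "J")] == 2.0
        assert expected[("J", "S")] == expected[("J", "M")] == 0.5

    def test_analytic_matrix_form(self):
        m = np.zeros((3, 3))
        m[RANK_IDX["S"], RANK_IDX["M"]] = 12
        m[RANK_IDX["M"], RANK_IDX["S"]] = 4
        exp = expected_matrix_analytic(m)
        assert exp[0, 1] == exp[0, 2] == 6.0
        assert exp[1, 0] == exp[1, 2] == 2.0
        assert (exp[2] == 0).all()

    def test_mc_matches_analytic_within_3se(self):
        counts = _counts_frame({("S", "M"): 12})
        mc = expected_counts_mc(counts, n_perm=10_000, rng=0)
        se = np.sqrt(12 / 4 / 10_000)
        row = mc[(mc["attacker_rank"] == "S")]
        assert np.all(np.abs(row["expected"] - 6.0) <= 3 * se)

    def test_mc_row_sums_exact(self):
        rng = np.random.default_rng(3)
        per_dyad = {k: int(rng.integers(0, 40))
                    for k in [("S", "M"), ("S", "J"), ("M", "S"), ("M", "J"),
                              ("J", "S"), ("J", "M")]}
        counts = _counts_frame(per_dyad)
        mc = expected_counts_mc(counts, n_perm=200, rng=1)
        obs = mc.groupby("attacker_rank")["count"].sum()
        exp = mc.groupby("attacker_rank")["expected"].sum()
        assert np.allclose(obs.to_numpy(), exp.to_numpy(), atol=0)

    def test_mc_zero_rows_exact(self):
        counts = _counts_frame({})
        mc = expected_counts_mc(counts, n_perm=50, rng=2)
        assert (mc["expected"] == 0).all()

    def test_mc_deterministic_under_seed(self):
        counts = _counts_frame({("S", "M"): 7, ("M", "J"): 5})
        a = expected_counts_mc(counts, n_perm=500, rng=11)
        b = expected_counts_mc(counts, n_perm=500, rng=11)
        pd.testing.assert_frame_equal(a, b)

    def test_nperm_validation(self):
        counts = _counts_frame({("S", "M"): 1})
        with pytest.raises(ValueError):
            expected_counts_mc(counts, n_perm=0)
        with pytest.raises(ValueError):
            expected_matrix_mc(np.zeros((3, 3)), n_perm=-1)


class TestDeviationTable:
    def test_closed_form_deviations(self, tiny_dataset, weights):
        pecks = filter_observation_window(tiny_dataset.pecks)
        cov = brood_day_covariates(tiny_dataset, weights)
        counts = daily_directed_counts(pecks)
        expected = expected_counts_analytic(counts)
        tab = deviation_table(counts, expected, cov, tiny_dataset.broods)
        day = tab[tab["date"] == dt.date(2020, 5, 8)].set_index(
            ["attacker_rank", "recipient_rank"]
        )
        # S made 2 pecks at M and 1 at J: expected 1.5 each
        assert day.loc[("S", "M"), "deviation"] == pytest.approx(0.5)
        assert day.loc[("S", "J"), "deviation"] == pytest.approx(-0.5)
        # delta_days joins the hatch-date difference (S hatched 4 d before J)
        assert day.loc[("S", "J"), "delta_days"] == -4

    def test_attacker_day_deviations_sum_to_zero(self, small_sim_dataset,
                                                 weights):
        pecks = filter_observation_window(small_sim_dataset.pecks)
        cov = brood_day_covariates(small_sim_dataset, weights)
        counts = daily_directed_counts(pecks)
        tab = deviation_table(
            counts, expected_counts_analytic(counts), cov,
            small_sim_dataset.broods,
        )
        sums = tab.groupby(["brood_id", "date", "attacker_rank"])[
            "deviation"
        ].sum()
        assert np.allclose(sums.to_numpy(), 0.0, atol=1e-12)

    def test_event_order_invariance(self, tiny_dataset, weights):
        cov = brood_day_covariates(tiny_dataset, weights)
        shuffled = tiny_dataset.pecks.sample(frac=1, random_state=5)
        a = daily_directed_counts(tiny_dataset.pecks)
        b = daily_directed_counts(shuffled)
        ta = deviation_table(a, expected_counts_analytic(a), cov,
                             tiny_dataset.broods)
        tb = deviation_table(b, expected_counts_analytic(b), cov,
                             tiny_dataset.broods)
        pd.testing.assert_frame_equal(ta, tb)


class TestBootstrapSplits:
    def test_subset_sizes(self, small_sim_dataset):
        pecks = small_sim_dataset.pecks
        n = len(pecks)
        subsets = list(bootstrap_splits(pecks, frac=0.8, n_boot=5, rng=1))
        assert all(len(s) == int(np.floor(0.8 * n)) for s in subsets)

    def test_seeded_reproducibility_and_variation(self, small_sim_dataset):
        pecks = small_sim_dataset.pecks
        a = [s for s in bootstrap_splits(pecks, 0.8, 3, rng=7)]
        b = [s for s in bootstrap_splits(pecks, 0.8, 3, rng=7)]
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)
        assert not a[0].equals(a[1])

    def test_frac_one_returns_everything(self, tiny_dataset):
        (subset,) = bootstrap_splits(tiny_dataset.pecks, frac=1.0, n_boot=1,
                                     rng=0)
        assert len(subset) == len(tiny_dataset.pecks)

    def test_too_few_events(self, tiny_dataset):
        with pytest.raises(ValueError):
            list(bootstrap_splits(tiny_dataset.pecks.iloc[:1], 0.8, 2, rng=0))


def _pecks_at(times_s, dyad=("B1_S", "B1_M"), date=dt.date(2020, 5, 8)):
    return pd.DataFrame(
        {
            "brood_id": "B1",
            "date": date,
            "time": [dt.time(8 + s // 3600, (s % 3600) // 60, s % 60)
                     for s in times_s],
            "attacker_id": dyad[0],
            "recipient_id": dyad[1],
        }
    )


def _brute_force_first_peck(pecks, gap):
    keep = []
    for i, row in pecks.iterrows():
        t_i = (row["date"].toordinal() * 86400
               + row["time"].hour * 3600 + row["time"].minute * 60
               + row["time"].second)
        ok = True
        for j, other in pecks.iterrows():
            if i == j:
                continue
            same = (other["brood_id"], other["attacker_id"],
                    other["recipient_id"]) == (row["brood_id"],
                                               row["attacker_id"],
                                               row["recipient_id"])
            t_j = (other["date"].toordinal() * 86400
                   + other["time"].hour * 3600 + other["time"].minute * 60
                   + other["time"].second)
            if same and 0 < t_i - t_j < gap:
                ok = False
        if ok:
            keep.append(i)
    return pecks.loc[keep].reset_index(drop=True)


class TestFirstPeckFilter:
    def test_battle_example(self):
        pecks = _pecks_at([0, 3, 6, 200])
        kept = first_peck_filter(pecks, battle_gap_seconds=60)
        secs = [t.minute * 60 + t.second for t in kept["time"]]
        assert secs == [0, 200]

    def test_isolated_peck_retained(self):
        kept = first_peck_filter(_pecks_at([100]), 60)
        assert len(kept) == 1

    def test_zero_gap_keeps_all(self):
        pecks = _pecks_at([0, 1, 2])
        assert len(first_peck_filter(pecks, 0)) == 3

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            first_peck_filter(_pecks_at([0]), -1)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 25))
        dyads = [("B1_S", "B1_M"), ("B1_S", "B1_J"), ("B1_M", "B1_S")]
        frames = []
        for k in range(n):
            d = dyads[int(rng.integers(len(dyads)))]
            frames.append(_pecks_at([int(rng.integers(0, 600))], dyad=d))
        pecks = pd.concat(frames, ignore_index=True)
        gap = float(rng.integers(1, 120))
        fast = first_peck_filter(pecks, gap)
        brute = _brute_force_first_peck(pecks, gap)
        assert len(fast) == len(brute)
        pd.testing.assert_frame_equal(
            fast.sort_values(["attacker_id", "recipient_id", "time"])
            .reset_index(drop=True),
            brute.sort_values(["attacker_id", "recipient_id", "time"])
            .reset_index(drop=True),
        )
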