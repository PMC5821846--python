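"""Behavioral statistics versus independent scan oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from revalearn.agent import AgentParams, simulate_agent_session
from revalearn.metrics import (
    cohort_table,
    discounting_rate,
    discounting_summary,
    reversal_summary,
)
from revalearn.task import TaskConfig, run_discounting_session, run_reversal_session

from conftest import make_reversal_log, omniscient_policy_for, random_side_policy


def reversal_oracle(log):
    """Independent O(T) scan of all reversal measures, written separately."""
    df = log.trials
    choice, active = df["choice"].tolist(), df["active"].tolist()
    reward, flags = df["reward"].tolist(), df["reversal"].tolist()
    n = len(df)
    rev_rows = [i for i in range(n) if flags[i]]
    out = {
        "total_reversals": len(rev_rows),
        "trials_to_criterion": rev_rows[0] + 1 if rev_rows else math.nan,
    }
    persev = []
    for i in rev_rows:
        old = active[i]
        j = i + 1
        while j < n and choice[j] == old:
            j += 1
        persev.append(j - i - 1)
    out["perseverative_mean"] = sum(persev) / len(persev) if persev else math.nan
    first = rev_rows[0] if rev_rows else n
    for phase in ("pre", "post"):
        for kind in ("win", "lose"):
            num = den = 0
            for t in range(n - 1):
                in_pre = t <= first
                if (phase == "pre") != in_pre:
                    continue
                if kind == "win" and not (choice[t] == active[t] and reward[t] > 0):
                    continue
                if kind == "lose" and not (choice[t] != active[t] and reward[t] == 0):
                    continue
                den += 1
                num += choice[t + 1] == choice[t]
            out[f"{kind}_stay_{phase}"] = 100 * num / den if den else math.nan
    return out


class TestReversalSummary:
    def test_worked_perseveration_example(self):
        # after a reversal: inactive, inactive, active -> 2 perseverative
        choices = ["left"] * 5 + ["left", "left", "right"]
        summary = reversal_summary(make_reversal_log(choices, "left"))
        assert summary.perseverative_mean == 2.0
        assert summary.total_reversals == 1
        assert summary.trials_to_criterion == 5

    def test_omniscient_session(self):
        # every trial is rewarded; the only non-stays are the (correct)
        # switches right after each reversal, so win-stay sits at the
        # strict-definition ceiling of 4/5 within every criterion run
        session = run_reversal_session(omniscient_policy_for(1), seed=1)
        s = reversal_summary(session)
        assert s.trials_to_criterion == 5
        assert s.win_stay_pre == pytest.approx(100 * 4 / 5)
        assert s.win_stay_post == pytest.approx(100 * 116 / 144)
        assert math.isnan(s.lose_stay_pre) and math.isnan(s.lose_stay_post)
        assert s.perseverative_mean == 0.0

    def test_hand_built_mixed_log_against_oracle(self):
        choices = ["left", "right", "left", "left", "left", "left", "left",
                   "left", "right", "right", "left", "right", "right", "right",
                   "right", "right", "left", "left", "right", "right"]
        log = make_reversal_log(choices, "left", criterion=5)
        s = reversal_summary(log)
        expected = reversal_oracle(log)
        for key, val in expected.items():
            got = getattr(s, key)
            if isinstance(val, float) and math.isnan(val):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(val), key

    @pytest.mark.parametrize("seed", range(30))
    def test_random_sessions_match_oracle(self, seed):
        config = TaskConfig(n_trials=60, criterion_run=3)
        log = run_reversal_session(random_side_policy(seed), config, seed=seed)
        s = reversal_summary(log)
        for key, val in reversal_oracle(log).items():
            got = getattr(s, key)
            if isinstance(val, float) and math.isnan(val):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(val), key

    def test_total_reversals_consistent_with_flags(self):
        log = run_reversal_session(random_side_policy(3), seed=3)
        assert reversal_summary(log).total_reversals == int(
            log.trials["reversal"].sum()
        )

    def test_chance_agent_stays_near_fifty_percent(self):
        config = TaskConfig(n_trials=10_000)
        session = simulate_agent_session(AgentParams(0.5, 0.5, 0.0), config, seed=11)
        s = reversal_summary(session)
        assert s.win_stay_post == pytest.approx(50.0, abs=2.0)
        assert s.lose_stay_post == pytest.approx(50.0, abs=2.0)

    def test_wrong_task_rejected(self):
        session = run_discounting_session(lambda h: "safe", seed=0)
        with pytest.raises(ValueError):
            reversal_summary(session)


class TestDiscountingSummary:
    def test_always_risky_percent_optimal(self):
        session = run_discounting_session(lambda h: "risky", seed=0)
        s = discounting_summary(session)
        # optimal only in block 1: 10 of the 30 scored free trials
        assert s.percent_optimal == pytest.approx(100 * 10 / 30)
        assert s.p_block1 == s.p_block2 == s.p_block3 == s.p_block4 == 100.0

    def test_omniscient_optimal_policy(self):
        def policy(history):
            block = history[-1][2] if history else 1
            return "risky" if block == 1 else "safe"

        session = run_discounting_session(policy, seed=1)
        s = discounting_summary(session)
        assert s.percent_optimal == 100.0

    def test_toy_log_stay_metrics_against_hand_count(self):
        # deterministic alternation: free-trial pairs within each block
        seq = iter(["risky", "safe", "safe", "risky"] * 10)
        session = run_discounting_session(lambda h: next(seq), seed=0)
        df = session.trials
        free_rows = np.flatnonzero(~df["forced"].to_numpy())
        choice, reward = df["choice"].to_numpy(), df["reward"].to_numpy()
        counts = {"win": [0, 0], "lose": [0, 0], "safe": [0, 0]}
        for a, b in zip(free_rows[:-1], free_rows[1:]):
            if b != a + 1:
                continue
            if choice[a] == "risky":
                key = "win" if reward[a] > 0 else "lose"
                counts[key][1] += 1
                counts[key][0] += choice[b] == "risky"
            else:
                counts["safe"][1] += 1
                counts["safe"][0] += choice[b] == "safe"
        s = discounting_summary(session)
        for key, attr in [("win", "win_stay"), ("lose", "lose_stay"), ("safe", "safe_stay")]:
            num, den = counts[key]
            expected = 100 * num / den if den else math.nan
            got = getattr(s, attr)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestDiscountingRate:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ((100, 50, 0, 0), -100 / 3),
            ((60, 60, 60, 60), 0.0),
            ((100, 77, 40, 20), ((30.0) - 100) / 3),
        ],
    )
    def test_direct_evaluation(self, p, expected):
        assert discounting_rate(p) == pytest.approx(expected)

    def test_invariant_to_block2(self):
        assert discounting_rate((80, 0, 40, 20)) == discounting_rate((80, 100, 40, 20))

    def test_linearity_in_each_argument(self):
        base = (50.0, 50.0, 50.0, 50.0)
        for idx in (0, 2, 3):
            lo = list(base)
            hi = list(base)
            lo[idx], hi[idx] = 0.0, 100.0
            mid = list(base)
            mid[idx] = 50.0
            assert discounting_rate(mid) == pytest.approx(
                (discounting_rate(lo) + discounting_rate(hi)) / 2
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discounting_rate((120, 0, 0, 0))


class TestCohortTable:
    def _summaries(self, n):
        return [
            reversal_summary(
                simulate_agent_session(AgentParams(0.6, 0.6, 3.0), seed=i)
            )
            for i in range(n)
        ]

    def test_shape_one_row_per_subject_condition(self):
        summaries = self._summaries(4)
        table = cohort_table(
            summaries, ["control", "control", "treated", "treated"], [1, 2, 1, 2]
        )
        assert len(table) == 4
        assert set(table["condition"]) == {"control", "treated"}

    def test_sentinels_preserved_as_missing(self):
        session = run_reversal_session(omniscient_policy_for(1), seed=1)
        table = cohort_table([reversal_summary(session)], ["control"])
        assert table["lose_stay_pre"].isna().all()

    def test_round_trip_through_csv(self, tmp_path):
        table = cohort_table(self._summaries(3), ["a", "b", "c"])
        path = tmp_path / "cohort.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_mixed_task_kinds_rejected(self):
        rev = reversal_summary(simulate_agent_session(AgentParams(0.5, 0.5, 2.0), seed=0))
        disc = discounting_summary(run_discounting_session(lambda h: "safe", seed=0))
        with pytest.raises(ValueError, match="mixed"):
            cohort_table([rev, disc], ["a", "b"])
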