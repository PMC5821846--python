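"""Behavioral statistics computed from session logs.

Reversal-learning measures
--------------------------
* *trials to criterion* — trial index of the first reversal (the number of
  trials needed to produce the first criterion run of correct responses).
* *perseverative responses* — for each reversal, the number of consecutive
  responses into the formerly active (now inactive) hole immediately after
  the reversal; e.g. the post-reversal sequence inactive-inactive-active
  scores 2.  The summary reports the mean over reversals.
* *win-stay* — percentage of rewarded active-hole trials followed by a
  response into that same hole on the next trial.
* *lose-stay* — percentage of unrewarded inactive-hole trials followed by a
  response into that same hole on the next trial.

Win/lose-stay are reported separately for trials before versus after the
first reversal; the trial completing the first reversal belongs to "pre",
and a transition is scored in the phase of its earlier trial.  A metric
whose denominator is zero (e.g. no pre-reversal losses) is reported as NaN,
never as 0 — real cohorts simply exclude such subjects from that measure.

Probabilistic-discounting measures
----------------------------------
Free-choice trials only.  Risky-choice percentage per block; *percent
optimal* (risky where the risky lever's expected value exceeds the safe
pellet, safe where it is lower; the indifferent block is not scored);
win-/lose-/safe-stay over pairs of consecutive free trials; and the
discounting rate, the average drop in risky choice per block::

    rate (% per block) = ((p_block3 + p_block4) / 2 - p_block1) / 3

Block 2 is omitted because neither lever is economically better there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .task import SessionLog

__all__ = [
    "ReversalSummary",
    "DiscountingSummary",
    "reversal_summary",
    "discounting_summary",
    "discounting_rate",
    "cohort_table",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ReversalSummary:
    total_reversals: int
    trials_to_criterion: float
    perseverative_mean: float
    win_stay_pre: float
    win_stay_post: float
    lose_stay_pre: float
    lose_stay_post: float
    task_kind: str = "reversal"


@dataclass(frozen=True)
class DiscountingSummary:
    p_block1: float
    p_block2: float
    p_block3: float
    p_block4: float
    discounting_rate: float
    percent_optimal: float
    win_stay: float
    lose_stay: float
    safe_stay: float
    task_kind: str = "discounting"


def _pct(numer: int, denom: int) -> float:
    return 100.0 * numer / denom if denom else UNDEFINED


def reversal_summary(session: SessionLog) -> ReversalSummary:
    """Compute all reversal-learning measures for one session."""
    if session.task_kind != "reversal":
        raise ValueError("reversal_summary requires a reversal-task log")
    df = session.trials
    choice = df["choice"].to_numpy()
    active = df["active"].to_numpy()
    reward = df["reward"].to_numpy()
    reversal = df["reversal"].to_numpy()
    n = len(df)

    rev_idx = np.flatnonzero(reversal)  # 0-based rows completing a reversal
    total_reversals = int(len(rev_idx))
    ttc = float(rev_idx[0] + 1) if total_reversals else UNDEFINED

    # Perseveration: run of choices of the formerly active side right after
    # each reversal; a reversal immediately followed by the new active side
    # (or ending the session) contributes 0.
    persev = []
    for i in rev_idx:
        old_active = active[i]
        run = 0
        j = i + 1
        while j < n and choice[j] == old_active:
            run += 1
            j += 1
        persev.append(run)
    persev_mean = float(np.mean(persev)) if persev else UNDEFINED

    # Stay metrics: transition (t, t+1) scored in the phase of trial t; the
    # final trial has no successor and never enters a denominator.
    first_rev = rev_idx[0] if total_reversals else n  # pre = rows <= first_rev
    counts = {k: [0, 0] for k in ("win_pre", "win_post", "lose_pre", "lose_post")}
    for t in range(n - 1):
        phase = "pre" if t <= first_rev else "post"
        correct = choice[t] == active[t]
        if correct and reward[t] > 0:
            key = f"win_{phase}"
        elif (not correct) and reward[t] == 0:
            key = f"lose_{phase}"
        else:  # pragma: no cover - cannot occur under the task contingencies
            continue
        counts[key][1] += 1
        if choice[t + 1] == choice[t]:
            counts[key][0] += 1

    return ReversalSummary(
        total_reversals=total_reversals,
        trials_to_criterion=ttc,
        perseverative_mean=persev_mean,
        win_stay_pre=_pct(*counts["win_pre"]),
        win_stay_post=_pct(*counts["win_post"]),
        lose_stay_pre=_pct(*counts["lose_pre"]),
        lose_stay_post=_pct(*counts["lose_post"]),
    )


def discounting_summary(session: SessionLog) -> DiscountingSummary:
    """Compute all probabilistic-discounting measures for one session."""
    if session.task_kind != "discounting":
        raise ValueError("discounting_summary requires a discounting-task log")
    df = session.trials
    free = df.loc[~df["forced"]]
    odds = session.config.ordered_odds
    big = session.config.reward_risky
    safe = session.config.reward_safe

    p_blocks = []
    for b in range(1, 5):
        blk = free.loc[free["block"] == b, "choice"]
        p_blocks.append(_pct(int((blk == "risky").sum()), len(blk)))

    # Percent optimal: risky where its expected value beats the safe pellet,
    # safe where it falls short; the indifference block is not scored.
    opt_n = opt_k = 0
    for b in range(1, 5):
        ev = float(odds[b - 1]) * big
        if math.isclose(ev, safe):
            continue
        best = "risky" if ev > safe else "safe"
        blk = free.loc[free["block"] == b, "choice"]
        opt_n += len(blk)
        opt_k += int((blk == best).sum())

    # Stay metrics over pairs of consecutive free trials (a free trial whose
    # successor is forced is not scored).
    free_rows = np.flatnonzero(~df["forced"].to_numpy())
    choice = df["choice"].to_numpy()
    reward = df["reward"].to_numpy()
    stays = {k: [0, 0] for k in ("win", "lose", "safe")}
    for a, b in zip(free_rows[:-1], free_rows[1:]):
        if b != a + 1:
            continue
        if choice[a] == "risky":
            key = "win" if reward[a] > 0 else "lose"
            stayed = choice[b] == "risky"
        else:
            key = "safe"
            stayed = choice[b] == "safe"
        stays[key][1] += 1
        stays[key][0] += int(stayed)

    return DiscountingSummary(
        p_block1=p_blocks[0],
        p_block2=p_blocks[1],
        p_block3=p_blocks[2],
        p_block4=p_blocks[3],
        discounting_rate=discounting_rate(p_blocks),
        percent_optimal=_pct(opt_k, opt_n),
        win_stay=_pct(*stays["win"]),
        lose_stay=_pct(*stays["lose"]),
        safe_stay=_pct(*stays["safe"]),
    )


def discounting_rate(p_blocks) -> float:
    """Average change in risky choice per block, in % per block.

    ``p_blocks`` are the four per-block risky-choice percentages; block 2 is
    ignored (no economically best choice there).  Negative values mean the
    subject discounts the risky lever as its odds worsen.
    """
    if len(p_blocks) != 4:
        raise ValueError("expected four per-block percentages")
    p1, _, p3, p4 = (float(p) for p in p_blocks)
    for p in (p1, p3, p4):
        if math.isnan(p):
            return UNDEFINED
        if not 0.0 <= p <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    return ((p3 + p4) / 2.0 - p1) / 3.0


def cohort_table(summaries, conditions, subjects=None) -> pd.DataFrame:
    """Tidy per-subject, per-condition table of summaries.

    One row per (subject, condition); NaN sentinels are preserved as missing
    values, never coerced to 0.  All summaries must come from the same task.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries")
    kinds = {s.task_kind for s in summaries}
    if len(kinds) > 1:
        raise ValueError(f"mixed task kinds in cohort: {sorted(kinds)}")
    conditions = list(conditions)
    if len(conditions) != len(summaries):
        raise ValueError("one condition label per summary required")
    if subjects is None:
        subjects = list(range(1, len(summaries) + 1))
    rows = []
    for subj, cond, s in zip(subjects, conditions, summaries):
        row = {"subject": subj, "condition": cond}
        row.update(
            {f.name: getattr(s, f.name) for f in fields(s) if f.name != "task_kind"}
        )
        rows.append(row)
    return pd.DataFrame(rows)
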