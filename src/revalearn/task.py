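"""Trial-level environments for the three operant tasks.

Three self-paced rodent tasks are simulated at the level of discrete trials:

* **Serial reversal learning** — two response options (left/right); the active
  one always pays one pellet.  After ``criterion_run`` consecutive correct
  responses the contingencies reverse.  Sessions are a fixed number of trials
  (150 by default; the photometry task variant uses a criterion of 8).
* **Probabilistic discounting** — a safe lever always pays 1 pellet; a risky
  lever pays 3 pellets with a probability that changes over four blocks
  (1, 1/3, 1/6, 1/12 in the decreasing variant).  Each block is 6 forced
  risky trials followed by 10 free-choice trials.
* **Punished responding** — responding on the active option pays 1 pellet but
  carries a foot-shock probability that steps up across blocks of 10 trials
  (0, 1/3, 2/3, then 1 from trial 31 on).

All stochasticity flows from a single integer seed per session through a
``numpy.random.Generator`` (PCG64), so a (seed, policy) pair fully determines
a session log.  Timing elements of the real tasks (time-outs, intertrial
intervals, cue lights) are not modelled; every trial receives a response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "SessionLog",
    "ReversalState",
    "reversal_step",
    "run_reversal_session",
    "initial_active_side",
    "discounting_block_probability",
    "run_discounting_session",
    "punishment_shock_probability",
    "run_punishment_session",
    "DECREASING_ODDS",
]

#: Exact large-reward odds of the decreasing discounting schedule, blocks 1-4.
DECREASING_ODDS = (
    Fraction(1),
    Fraction(1, 3),
    Fraction(1, 6),
    Fraction(1, 12),
)

SESSION_COLUMNS = [
    "trial",
    "task",
    "block",
    "forced",
    "choice",
    "active",
    "reward",
    "reversal",
    "shock",
]

_REVERSAL_SIDES = ("left", "right")
_DISCOUNT_CHOICES = ("safe", "risky")
_PUNISH_CHOICES = ("active", "inactive")

#: Default foot-shock schedule: (first trial of range, probability); the last
#: range is open-ended.  Trials 1-10 unpunished, 11-20 one in three, 21-30 two
#: in three, 31 and up always punished.
DEFAULT_SHOCK_SCHEDULE = (
    (1, Fraction(0)),
    (11, Fraction(1, 3)),
    (21, Fraction(2, 3)),
    (31, Fraction(1)),
)


@dataclass(frozen=True)
class TaskConfig:
    """Schedule parameters for one task session.

    Parameters
    ----------
    task_kind
        ``"reversal"``, ``"discounting"`` or ``"punishment"``.
    n_trials
        Session length in trials.  Reversal sessions default to 150; the
        punishment default (40) covers all four shock-probability ranges.
    criterion_run
        Consecutive correct responses triggering a reversal (5; the
        photometry task variant uses 8).
    block_odds
        Large-reward probability per discounting block, in block order.
    variant
        ``"decreasing"`` (default) or ``"increasing"`` block-odds order.
    forced_per_block, free_per_block
        Discounting block structure (6 forced + 10 free).
    reward_safe, reward_risky
        Pellets for the safe lever and for a risky win (1 and 3).
    shock_schedule
        ``(first_trial, probability)`` pairs, increasing in both fields; the
        last range is open-ended.
    """

    task_kind: str = "reversal"
    n_trials: int = 150
    criterion_run: int = 5
    block_odds: tuple = DECREASING_ODDS
    variant: str = "decreasing"
    forced_per_block: int = 6
    free_per_block: int = 10
    reward_safe: int = 1
    reward_risky: int = 3
    shock_schedule: tuple = DEFAULT_SHOCK_SCHEDULE

    def __post_init__(self):
        if self.task_kind not in ("reversal", "discounting", "punishment"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.criterion_run < 1:
            raise ValueError("criterion_run must be >= 1")
        if self.variant not in ("decreasing", "increasing"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for p in self.block_odds:
            if not 0 <= p <= 1:
                raise ValueError("block odds must lie in [0, 1]")
        if self.task_kind == "discounting" and len(self.block_odds) != 4:
            raise ValueError("the discounting task uses exactly 4 blocks")
        prev_t, prev_p = 0, -1.0
        for t, p in self.shock_schedule:
            if t <= prev_t:
                raise ValueError("shock ranges must start at increasing trials")
            if not 0 <= p <= 1 or p < prev_p:
                raise ValueError("shock probabilities must be non-decreasing in [0, 1]")
            prev_t, prev_p = t, p

    @property
    def ordered_odds(self) -> tuple:
        """Block odds in presentation order for the configured variant."""
        odds = tuple(self.block_odds)
        return odds if self.variant == "decreasing" else odds[::-1]


@dataclass
class SessionLog:
    """One simulated (or recorded) session: config, seed and per-trial table.

    ``trials`` has one row per trial with 1-based ``trial`` indices and the
    columns ``task, block, forced, choice, active, reward, reversal, shock``.
    """

    config: TaskConfig
    seed: Optional[int]
    trials: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in SESSION_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session table missing columns: {missing}")

    @property
    def task_kind(self) -> str:
        return self.config.task_kind

    def __len__(self) -> int:
        return len(self.trials)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return (
            self.config == other.config
            and self.seed == other.seed
            and self.trials.reset_index(drop=True).equals(
                other.trials.reset_index(drop=True)
            )
        )


# ---------------------------------------------------------------------------
# Reversal learning
# ---------------------------------------------------------------------------


@dataclass
class ReversalState:
    """Mutable within-session state of the reversal environment."""

    config: TaskConfig
    active: str
    trial_index: int = 1  # 1-based index of the next trial
    run: int = 0  # current consecutive-correct run length

    def finished(self) -> bool:
        return self.trial_index > self.config.n_trials


def reversal_step(state: ReversalState, choice: str):
    """Advance the reversal environment one trial.

    A correct choice (the active side) pays one pellet and extends the
    consecutive-correct run; completing a run of ``criterion_run`` sets the
    reversal flag, swaps the active side and resets the run.  An incorrect
    choice pays nothing and resets the run.

    Returns ``(reward, reversal_flag, state)``; ``state`` is mutated in place
    and returned for convenience.
    """
    if state.finished():
        raise RuntimeError(
            f"session finished: trial {state.trial_index} > {state.config.n_trials}"
        )
    if choice not in _REVERSAL_SIDES:
        raise ValueError(f"invalid side {choice!r}; expected one of {_REVERSAL_SIDES}")
    reversal = False
    if choice == state.active:
        reward = 1
        state.run += 1
        if state.run >= state.config.criterion_run:
            reversal = True
            state.active = "right" if state.active == "left" else "left"
            state.run = 0
    else:
        reward = 0
        state.run = 0
    state.trial_index += 1
    return reward, reversal, state


def initial_active_side(seed: int) -> str:
    """The side a reversal session with this seed will start with.

    The first draw from the session generator assigns the active side
    (counterbalancing across subjects); exposing it lets informed test
    policies and analyses know the ground truth without re-running.
    """
    return _REVERSAL_SIDES[np.random.default_rng(seed).integers(2)]


def run_reversal_session(
    policy: Callable, config: TaskConfig | None = None, seed: int = 0
) -> SessionLog:
    """Run one full reversal-learning session under ``policy``.

    ``policy(history)`` is called once per trial with the observable history,
    a list of ``(choice, reward)`` tuples, and must return a side.  The
    initially active side is drawn from the seeded generator (the real task
    counterbalanced it between animals).
    """
    config = config or TaskConfig(task_kind="reversal")
    if config.task_kind != "reversal":
        raise ValueError("config.task_kind must be 'reversal'")
    rng = np.random.default_rng(seed)
    state = ReversalState(config, active=_REVERSAL_SIDES[rng.integers(2)])
    rows = []
    history: list = []
    for t in range(1, config.n_trials + 1):
        active_before = state.active
        choice = policy(history)
        reward, reversal, state = reversal_step(state, choice)
        history.append((choice, reward))
        rows.append(
            (t, "reversal", 0, False, choice, active_before, reward, reversal, False)
        )
    return SessionLog(config, seed, _frame(rows))


# ---------------------------------------------------------------------------
# Probabilistic discounting
# ---------------------------------------------------------------------------


def discounting_block_probability(
    block_index: int, variant: str = "decreasing", config: TaskConfig | None = None
) -> float:
    """Large-reward probability of the risky lever in a given block (1-based)."""
    odds = (
        config.ordered_odds
        if config is not None
        else (DECREASING_ODDS if variant == "decreasing" else DECREASING_ODDS[::-1])
    )
    if not 1 <= block_index <= len(odds):
        raise ValueError(f"block_index {block_index} out of range 1..{len(odds)}")
    return float(odds[block_index - 1])


def run_discounting_session(
    policy: Callable, config: TaskConfig | None = None, seed: int = 0
) -> SessionLog:
    """Run one probabilistic-discounting session.

    Each block presents ``forced_per_block`` forced risky trials, then
    ``free_per_block`` free-choice trials on which ``policy(history)`` picks
    ``"safe"`` or ``"risky"``.  A risky press pays ``reward_risky`` pellets
    with the block probability, a safe press always pays ``reward_safe``.
    """
    config = config or TaskConfig(task_kind="discounting")
    if config.task_kind != "discounting":
        raise ValueError("config.task_kind must be 'discounting'")
    rng = np.random.default_rng(seed)
    odds = config.ordered_odds
    rows = []
    history: list = []
    t = 0
    for block, p_win in enumerate(odds, start=1):
        p_win = float(p_win)
        for forced in [True] * config.forced_per_block + [False] * config.free_per_block:
            t += 1
            if forced:
                choice = "risky"
            else:
                choice = policy(history)
                if choice not in _DISCOUNT_CHOICES:
                    raise ValueError(
                        f"invalid choice {choice!r}; expected one of {_DISCOUNT_CHOICES}"
                    )
            if choice == "risky":
                reward = config.reward_risky if rng.random() < p_win else 0
            else:
                reward = config.reward_safe
            history.append((choice, reward, block, forced))
            rows.append(
                (t, "discounting", block, forced, choice, str(block), reward, False, False)
            )
    return SessionLog(config, seed, _frame(rows))


# ---------------------------------------------------------------------------
# Punished responding
# ---------------------------------------------------------------------------


def punishment_shock_probability(
    trial_index: int, schedule: Sequence = DEFAULT_SHOCK_SCHEDULE
) -> float:
    """Foot-shock probability on a given trial (1-based step function)."""
    if trial_index < 1:
        raise ValueError("trial_index must be >= 1")
    prob = 0.0
    for start, p in schedule:
        if trial_index >= start:
            prob = float(p)
        else:
            break
    return prob


def run_punishment_session(
    policy: Callable, config: TaskConfig | None = None, seed: int = 0
) -> SessionLog:
    """Run one punished-responding session.

    ``policy(history)`` returns ``"active"``, ``"inactive"`` or ``None`` to
    stop responding (the real session ended after 5 min without an active
    response; the stop rule is delegated to the policy).  An active response
    pays one pellet and risks a shock with the scheduled probability; an
    inactive response has no scheduled consequence.
    """
    config = config or TaskConfig(task_kind="punishment", n_trials=40)
    if config.task_kind != "punishment":
        raise ValueError("config.task_kind must be 'punishment'")
    rng = np.random.default_rng(seed)
    rows = []
    history: list = []
    for t in range(1, config.n_trials + 1):
        choice = policy(history)
        if choice is None:
            break
        if choice not in _PUNISH_CHOICES:
            raise ValueError(
                f"invalid choice {choice!r}; expected one of {_PUNISH_CHOICES}"
            )
        p_shock = punishment_shock_probability(t, config.shock_schedule)
        shock = False
        reward = 0
        if choice == "active":
            reward = 1
            shock = bool(rng.random() < p_shock)
        history.append((choice, reward, shock))
        rows.append(
            (t, "punishment", _shock_block(t, config), False, choice, "active", reward, False, shock)
        )
    return SessionLog(config, seed, _frame(rows))


def _shock_block(trial_index: int, config: TaskConfig) -> int:
    block = 0
    for i, (start, _) in enumerate(config.shock_schedule, start=1):
        if trial_index >= start:
            block = i
    return block


def _frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return df.astype(
        {
            "trial": np.int64,
            "block": np.int64,
            "forced": bool,
            "reward": np.int64,
            "reversal": bool,
            "shock": bool,
        }
    )
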