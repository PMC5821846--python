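"""Dual-learning-rate Rescorla-Wagner agent with softmax choice.

The model maintains one value per spatial response (``Q_left``, ``Q_right``),
both initialised at 0.  After each trial the chosen side's value is updated
by a reward-prediction error (RPE)::

    RPE = outcome - Q_chosen          (outcome coded 1 for a win, 0 for a loss)
    Q_chosen += alpha_win  * RPE      on win trials
    Q_chosen += alpha_lose * RPE      on loss trials

The unchosen side is never updated (no forgetting).  Values map to choice
probabilities through a softmax with inverse temperature ``beta``::

    p(side) = exp(beta * Q_side) / (exp(beta * Q_left) + exp(beta * Q_right))

``beta = 0`` reduces the model to unbiased coin-flip choice (the chance model
used as the likelihood-ratio null).  With outcomes in {0, 1} and learning
rates in [0, 1] the values stay in [0, 1] for any trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .task import ReversalState, SessionLog, TaskConfig, reversal_step, _frame

__all__ = [
    "AgentParams",
    "AgentState",
    "update_value",
    "choice_probabilities",
    "simulate_agent_session",
]


@dataclass(frozen=True)
class AgentParams:
    """Model parameters: learning rates in [0, 1], inverse temperature >= 0."""

    alpha_win: float
    alpha_lose: float
    beta: float

    def __post_init__(self):
        for name in ("alpha_win", "alpha_lose", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.alpha_win <= 1.0:
            raise ValueError("alpha_win must lie in [0, 1]")
        if not 0.0 <= self.alpha_lose <= 1.0:
            raise ValueError("alpha_lose must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")

    def as_tuple(self) -> tuple:
        return (self.alpha_win, self.alpha_lose, self.beta)


@dataclass(frozen=True)
class AgentState:
    """Action values and trial counter; values start at 0."""

    q_left: float = 0.0
    q_right: float = 0.0
    trial: int = 0


def update_value(
    state: AgentState, chosen: str, outcome: int, params: AgentParams
) -> AgentState:
    """Apply one RPE update to the chosen side's value."""
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    if chosen not in ("left", "right"):
        raise ValueError(f"chosen must be 'left' or 'right', got {chosen!r}")
    q = state.q_left if chosen == "left" else state.q_right
    rpe = outcome - q
    alpha = params.alpha_win if outcome == 1 else params.alpha_lose
    q_new = q + alpha * rpe
    if chosen == "left":
        return AgentState(q_new, state.q_right, state.trial + 1)
    return AgentState(state.q_left, q_new, state.trial + 1)


def choice_probabilities(state: AgentState, beta: float) -> tuple:
    """Softmax choice probabilities ``(p_left, p_right)``.

    Numerically stabilised by subtracting the larger exponent; with Q in
    [0, 1] this is belt-and-braces, but beta is unconstrained here.
    """
    if not math.isfinite(beta) or beta < 0:
        raise ValueError("beta must be finite and >= 0")
    xl, xr = beta * state.q_left, beta * state.q_right
    m = max(xl, xr)
    el, er = math.exp(xl - m), math.exp(xr - m)
    z = el + er
    return el / z, er / z


def simulate_agent_session(
    params: AgentParams, config: TaskConfig | None = None, seed: int = 0
) -> SessionLog:
    """Simulate one reversal-learning session generatively.

    On each trial a side is sampled from the softmax probabilities, the
    environment is stepped, and the chosen side's value is updated with the
    delivered outcome.  The resulting log is ready for the behavioral
    metrics and for model fitting.
    """
    config = config or TaskConfig(task_kind="reversal")
    if config.task_kind != "reversal":
        raise ValueError("the agent is defined for the reversal task")
    rng = np.random.default_rng(seed)
    env = ReversalState(config, active=("left", "right")[rng.integers(2)])
    agent = AgentState()
    rows = []
    for t in range(1, config.n_trials + 1):
        p_left, _ = choice_probabilities(agent, params.beta)
        choice = "left" if rng.random() < p_left else "right"
        active_before = env.active
        reward, reversal, env = reversal_step(env, choice)
        agent = update_value(agent, choice, reward, params)
        rows.append(
            (t, "reversal", 0, False, choice, active_before, reward, reversal, False)
        )
    return SessionLog(config, seed, _frame(rows))
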