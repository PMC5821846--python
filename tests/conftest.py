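"""Shared fixtures: informed test policies and hand-built session logs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from revalearn.task import (
    SESSION_COLUMNS,
    SessionLog,
    TaskConfig,
    initial_active_side,
)


class OmniscientPolicy:
    """Always-correct reversal policy: tracks the active side from feedback.

    Needs to be told the initial active side (the real counterbalancing is
    hidden from the animal but not from an oracle policy).
    """

    def __init__(self, initial_active: str, criterion: int = 5):
        self.active = initial_active
        self.criterion = criterion
        self.run = 0

    def __call__(self, history):
        if history:
            _, reward = history[-1]
            assert reward == 1, "omniscient policy should never miss"
            self.run += 1
            if self.run >= self.criterion:
                self.active = "right" if self.active == "left" else "left"
                self.run = 0
        return self.active


def omniscient_policy_for(seed: int, criterion: int = 5) -> OmniscientPolicy:
    return OmniscientPolicy(initial_active_side(seed), criterion)


def make_reversal_log(choices, initial_active: str, criterion: int = 5) -> SessionLog:
    """Build a reversal session log directly from a choice sequence.

    Applies the task contingencies (reward on correct, reversal after a
    criterion run) without going through the engine, so metric tests do not
    depend on the engine being right.
    """
    active = initial_active
    run = 0
    rows = []
    for t, c in enumerate(choices, start=1):
        a = active
        reversal = False
        if c == a:
            reward, run = 1, run + 1
            if run >= criterion:
                reversal = True
                active = "right" if active == "left" else "left"
                run = 0
        else:
            reward, run = 0, 0
        rows.append((t, "reversal", 0, False, c, a, reward, reversal, False))
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS).astype(
        {"trial": np.int64, "block": np.int64, "forced": bool,
         "reward": np.int64, "reversal": bool, "shock": bool}
    )
    config = TaskConfig(task_kind="reversal", n_trials=len(df), criterion_run=criterion)
    return SessionLog(config, None, df)


@pytest.fixture
def reversal_config():
    return TaskConfig(task_kind="reversal")


@pytest.fixture
def discounting_config():
    return TaskConfig(task_kind="discounting")


def random_side_policy(seed: int):
    rng = np.random.default_rng(seed)
    return lambda history: ("left", "right")[rng.integers(2)]
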