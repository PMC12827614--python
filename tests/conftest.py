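import numpy as np
import pandas as pd
import pytest

import adhd_dynamics as ad


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def decay_params():
    return ad.DecayParams(
        initial_level=1.2,
        base_rate=0.08,
        monotony_sensitivity=0.7,
        reward_sensitivity=0.9,
    )


@pytest.fixture
def hyper_params():
    return ad.HyperactivityParams(
        baseline=5.0,
        max_amplitude=3.0,
        cognitive_sensitivity=0.8,
        stillness_sensitivity=0.4,
        calm_reinforcement_sensitivity=0.6,
        angular_frequency=0.21,
        phase=1.3,
    )


@pytest.fixture
def task_schedule():
    """Four 30-minute segments with distinct (monotony, reward) contexts."""
    b = [0.0, 30.0, 60.0, 90.0, 120.0]
    ctxs = [
        ad.TaskContext(monotony=0.0, reward=0.0),
        ad.TaskContext(monotony=1.0, reward=0.2),
        ad.TaskContext(monotony=0.3, reward=1.0),
        ad.TaskContext(monotony=0.8, reward=0.6),
    ]
    return ad.ContextSchedule(
        tuple(ad.Segment(b[j], b[j + 1], ctxs[j]) for j in range(4))
    )


@pytest.fixture
def activity_schedule():
    b = [0.0, 30.0, 60.0, 90.0, 120.0]
    ctxs = [
        ad.ActivityContext(cognitive_demand=0.1, stillness_demand=0.9,
                           calm_reinforcement=0.2),
        ad.ActivityContext(cognitive_demand=0.8, stillness_demand=0.1,
                           calm_reinforcement=0.7),
        ad.ActivityContext(cognitive_demand=0.5, stillness_demand=0.5,
                           calm_reinforcement=0.0),
        ad.ActivityContext(cognitive_demand=0.9, stillness_demand=0.3,
                           calm_reinforcement=0.9),
    ]
    return ad.ContextSchedule(
        tuple(ad.Segment(b[j], b[j + 1], ctxs[j]) for j in range(4))
    )


def session_decay_table(params, conditions, t):
    """Session-style dataset: each condition observed from task onset."""
    rows = []
    for m, r in conditions:
        ctx = ad.TaskContext(monotony=m, reward=r)
        y = ad.decay_level(params, ctx, t)
        rows.append(
            pd.DataFrame({"time": t, "observed_value": y, "monotony": m, "reward": r})
        )
    return pd.concat(rows, ignore_index=True)


@pytest.fixture
def session_table_factory():
    return session_decay_table
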