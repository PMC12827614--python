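"""Synthetic EMA-style cohort generation.

Builds multi-subject datasets with exactly the statistical structure the
symptom models assume: per-subject parameters drawn from group priors,
piecewise-constant context schedules, additive Gaussian observation
noise, Bernoulli choices from the softmax rule, and
missing-completely-at-random (MCAR) deletion of trajectory rows.

The shipped group priors are order-of-magnitude synthetic conventions,
NOT empirical estimates: they encode only the qualitative contrasts the
models are built around — the ADHD-like group has a higher median
baseline attentional decay rate, stronger monotony sensitivity, larger
hyperactive amplitude, and a steeper median discount rate than the
control-like group.

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning, keyed by (subject index, stream),
so any subject's data can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .models_core import (
    ActivityContext,
    ChoicePolicy,
    DecayParams,
    DiscountingParams,
    Facet,
    HyperactivityParams,
    TaskContext,
    TWO_PI,
)
from .simulate import (
    ContextSchedule,
    NoiseSpec,
    Segment,
    simulate_choice_experiment,
    simulate_decay_trajectory,
    simulate_hyperactivity_trajectory,
    standard_choice_battery,
)

__all__ = [
    "ParameterPrior",
    "CohortPriors",
    "SubjectParameters",
    "EmaDesign",
    "sample_subject_parameters",
    "generate_ema_dataset",
    "rebuild_task_schedule",
    "rebuild_activity_schedule",
]

_FACETS = (Facet.SUSTAINED_ATTENTION, Facet.ATTENTION_TO_DETAIL, Facet.EFFORT)


@dataclass(frozen=True)
class ParameterPrior:
    """One parameter's prior: lognormal(median, sigma-of-log), uniform(lo, hi)
    or a fixed point mass."""

    family: Literal["lognormal", "uniform", "fixed"]
    location: float
    scale: float = 0.0

    def __post_init__(self):
        if self.family not in ("lognormal", "uniform", "fixed"):
            raise ConfigError(f"unknown prior family {self.family!r}")
        if self.family == "lognormal" and (self.location <= 0 or self.scale < 0):
            raise ConfigError("lognormal prior needs location > 0 and scale >= 0")
        if self.family == "uniform" and not self.location <= self.scale:
            raise ConfigError("uniform prior needs location <= scale (lo <= hi)")

    def sample(self, rng: np.random.Generator, n: int,
               lo: float = 0.0, hi: float = math.inf) -> np.ndarray:
        if self.family == "fixed":
            out = np.full(n, self.location)
        elif self.family == "uniform":
            out = rng.uniform(self.location, self.scale, n)
        else:  # lognormal parameterized by its median
            out = self.location * np.exp(self.scale * rng.standard_normal(n))
        return np.clip(out, lo, hi)


def _ln(median, sigma):
    return ParameterPrior("lognormal", median, sigma)


@dataclass(frozen=True)
class CohortPriors:
    """Per-parameter priors for one group; keys match the model field names."""

    group: str
    decay: dict
    hyperactivity: dict
    discounting: dict
    policy: dict

    @staticmethod
    def control_like_defaults() -> "CohortPriors":
        return CohortPriors(
            group="control_like",
            decay={
                "initial_level": _ln(1.0, 0.10),
                "base_rate": _ln(0.02, 0.30),        # 1/min
                "monotony_sensitivity": _ln(0.5, 0.30),
                "reward_sensitivity": _ln(0.5, 0.30),
            },
            hyperactivity={
                "baseline": _ln(2.0, 0.20),
                "max_amplitude": _ln(1.0, 0.30),
                "cognitive_sensitivity": _ln(0.5, 0.30),
                "stillness_sensitivity": _ln(0.5, 0.30),
                "calm_reinforcement_sensitivity": _ln(0.5, 0.30),
                "angular_frequency": _ln(TWO_PI / 30.0, 0.20),  # ~30-min cycle
                "phase": ParameterPrior("uniform", 0.0, TWO_PI),
            },
            discounting={"discount_rate": _ln(0.01, 0.50)},      # 1/day
            policy={"consistency": _ln(0.5, 0.30)},
        )

    @staticmethod
    def adhd_like_defaults() -> "CohortPriors":
        return CohortPriors(
            group="adhd_like",
            decay={
                "initial_level": _ln(1.0, 0.10),
                "base_rate": _ln(0.06, 0.30),        # faster attentional decay
                "monotony_sensitivity": _ln(1.0, 0.30),
                "reward_sensitivity": _ln(1.0, 0.30),
            },
            hyperactivity={
                "baseline": _ln(3.0, 0.20),
                "max_amplitude": _ln(3.0, 0.30),
                "cognitive_sensitivity": _ln(0.5, 0.30),
                "stillness_sensitivity": _ln(0.5, 0.30),
                "calm_reinforcement_sensitivity": _ln(0.5, 0.30),
                "angular_frequency": _ln(TWO_PI / 30.0, 0.20),
                "phase": ParameterPrior("uniform", 0.0, TWO_PI),
            },
            discounting={"discount_rate": _ln(0.05, 0.50)},      # steeper discounting
            policy={"consistency": _ln(0.5, 0.30)},
        )


@dataclass(frozen=True)
class SubjectParameters:
    subject_id: str
    group: str
    decay: dict  # Facet -> DecayParams
    hyperactivity: HyperactivityParams
    discounting: DiscountingParams
    policy: ChoicePolicy


# bounds applied when truncating prior draws to the model types' domains
_POSITIVE = (1e-9, math.inf)
_NONNEG = (0.0, math.inf)
_PRIOR_BOUNDS = {
    "initial_level": _POSITIVE,
    "base_rate": _POSITIVE,
    "angular_frequency": _POSITIVE,
    "phase": (0.0, TWO_PI * (1 - 1e-12)),
}


def _draw_block(priors: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, prior in priors.items():
        if not isinstance(prior, ParameterPrior):
            raise ConfigError(f"prior for {name!r} is not a ParameterPrior")
        lo, hi = _PRIOR_BOUNDS.get(name, _NONNEG)
        out[name] = float(prior.sample(rng, 1, lo, hi)[0])
    return out


def sample_subject_parameters(
    priors: CohortPriors, n: int, seed: int | np.random.SeedSequence
) -> list[SubjectParameters]:
    """Draw ``n`` invariant-valid per-subject parameter sets.

    Each inattention facet gets an independent draw from the shared decay
    priors.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    subjects = []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        decay = {
            facet: DecayParams(facet=facet, **_draw_block(priors.decay, rng))
            for facet in _FACETS
        }
        hyper = HyperactivityParams(**_draw_block(priors.hyperactivity, rng))
        disc = DiscountingParams(**_draw_block(priors.discounting, rng))
        policy = ChoicePolicy(**_draw_block(priors.policy, rng))
        subjects.append(
            SubjectParameters(
                subject_id=f"{priors.group}_{i:04d}",
                group=priors.group,
                decay=decay,
                hyperactivity=hyper,
                discounting=disc,
                policy=policy,
            )
        )
    return subjects


@dataclass(frozen=True)
class EmaDesign:
    """Sampling design for one synthetic EMA wave.

    Segment boundaries are shared across subjects; each subject draws its
    own per-segment context covariates uniformly on [0, 1].  The grid
    samples every ``dt`` minutes across the schedule span.
    """

    n_subjects_per_group: int = 20
    segment_durations: tuple = (30.0, 30.0, 30.0, 30.0)  # minutes
    dt: float = 1.0                                      # minutes
    noise: NoiseSpec = field(default_factory=lambda: NoiseSpec("gaussian", 0.05))
    missingness_rate: float = 0.0
    n_delays: int = 6
    n_amount_ratios: int = 5
    units: str = "minutes"

    def __post_init__(self):
        if not 0 <= self.missingness_rate < 1:
            raise ConfigError("missingness_rate must be in [0, 1)")
        if self.dt <= 0 or min(self.segment_durations) <= 0:
            raise ConfigError("dt and segment durations must be positive")
        if self.dt > min(self.segment_durations):
            raise ConfigError("dt must not exceed the shortest segment")

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.segment_durations)])

    @property
    def times(self) -> np.ndarray:
        end = float(self.boundaries[-1])
        n = int(round(end / self.dt))
        # end-exclusive so the last grid point stays inside the last segment
        return np.arange(n) * self.dt


def _schedules_for_subject(design: EmaDesign, rng: np.random.Generator):
    b = design.boundaries
    nseg = len(design.segment_durations)
    task_ctx = rng.random((nseg, 2))
    act_ctx = rng.random((nseg, 3))
    task = ContextSchedule(
        tuple(
            Segment(b[j], b[j + 1], TaskContext(monotony=task_ctx[j, 0],
                                                reward=task_ctx[j, 1]))
            for j in range(nseg)
        ),
        units=design.units,
    )
    act = ContextSchedule(
        tuple(
            Segment(
                b[j], b[j + 1],
                ActivityContext(
                    cognitive_demand=act_ctx[j, 0],
                    stillness_demand=act_ctx[j, 1],
                    calm_reinforcement=act_ctx[j, 2],
                ),
            )
            for j in range(nseg)
        ),
        units=design.units,
    )
    return task, act


def _subject_row(sp: SubjectParameters) -> dict:
    row = {"subject_id": sp.subject_id, "group": sp.group}
    for facet, p in sp.decay.items():
        for name in ("initial_level", "base_rate", "monotony_sensitivity",
                     "reward_sensitivity"):
            row[f"{facet.value}_{name}"] = getattr(p, name)
    for name in ("baseline", "max_amplitude", "cognitive_sensitivity",
                 "stillness_sensitivity", "calm_reinforcement_sensitivity",
                 "angular_frequency", "phase"):
        row[f"hyperactivity_{name}"] = getattr(sp.hyperactivity, name)
    row["discount_rate"] = sp.discounting.discount_rate
    row["consistency"] = sp.policy.consistency
    return row


def generate_ema_dataset(
    design: EmaDesign,
    priors_by_group: dict[str, CohortPriors],
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(subject_table, trajectory_table, choice_table)``; the
    tables cross-reference by ``subject_id``.  Per subject, the three
    inattention facets share one task schedule, hyperactivity has its own
    activity schedule, and everyone answers the same deterministic choice
    battery.  MCAR deletion is applied to trajectory rows only.
    """
    master = np.random.SeedSequence(seed)
    group_seeds = master.spawn(len(priors_by_group) + 1)
    battery = standard_choice_battery(design.n_delays, design.n_amount_ratios)
    times = design.times

    subj_rows, traj_parts, choice_parts = [], [], []
    for (gname, priors), gseed in zip(sorted(priors_by_group.items()), group_seeds):
        if priors.group != gname:
            raise ConfigError(
                f"priors labelled {priors.group!r} registered under key {gname!r}"
            )
        param_ss, data_ss = gseed.spawn(2)
        subjects = sample_subject_parameters(priors, design.n_subjects_per_group,
                                             param_ss)
        subject_streams = data_ss.spawn(design.n_subjects_per_group)
        for sp, sseed in zip(subjects, subject_streams):
            # fixed stream order: schedule, 3 facets, hyperactivity,
            # choices, missingness
            streams = sseed.spawn(7)
            subj_rows.append(_subject_row(sp))
            task_sched, act_sched = _schedules_for_subject(
                design, np.random.default_rng(streams[0])
            )
            parts = []
            for j, facet in enumerate(_FACETS):
                parts.append(
                    simulate_decay_trajectory(
                        sp.decay[facet], task_sched, times, design.noise,
                        seed=streams[1 + j], subject_id=sp.subject_id,
                    )
                )
            parts.append(
                simulate_hyperactivity_trajectory(
                    sp.hyperactivity, act_sched, times, design.noise,
                    seed=streams[4], subject_id=sp.subject_id,
                )
            )
            traj = pd.concat(parts, ignore_index=True)
            if design.missingness_rate > 0:
                keep = (
                    np.random.default_rng(streams[6]).random(len(traj))
                    >= design.missingness_rate
                )
                traj = traj.loc[keep].reset_index(drop=True)
            traj_parts.append(traj)
            choice_parts.append(
                simulate_choice_experiment(
                    battery, sp.discounting, sp.policy,
                    seed=streams[5], subject_id=sp.subject_id,
                )
            )

    subject_table = pd.DataFrame(subj_rows)
    trajectory_table = pd.concat(traj_parts, ignore_index=True)
    choice_table = pd.concat(choice_parts, ignore_index=True)
    return subject_table, trajectory_table, choice_table


def _segments_from_rows(design: EmaDesign, rows: pd.DataFrame, ctx_cls, cols):
    b = design.boundaries
    segs = []
    for j in range(len(design.segment_durations)):
        seg_rows = rows.loc[rows["context_segment_id"] == j, cols]
        if seg_rows.empty:
            raise ConfigError(
                f"segment {j} has no surviving rows; cannot rebuild its context"
            )
        vals = seg_rows.iloc[0]
        segs.append(Segment(b[j], b[j + 1], ctx_cls(**vals.to_dict())))
    return ContextSchedule(tuple(segs), units=design.units)


def rebuild_task_schedule(design: EmaDesign, rows: pd.DataFrame) -> ContextSchedule:
    """Reconstruct a subject's task schedule from its trajectory rows."""
    return _segments_from_rows(design, rows, TaskContext, ["monotony", "reward"])


def rebuild_activity_schedule(design: EmaDesign, rows: pd.DataFrame) -> ContextSchedule:
    """Reconstruct a subject's activity schedule from its trajectory rows."""
    return _segments_from_rows(
        design, rows, ActivityContext,
        ["cognitive_demand", "stillness_demand", "calm_reinforcement"],
    )
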