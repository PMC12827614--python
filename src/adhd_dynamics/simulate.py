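"""Trajectory and choice simulation under piecewise-constant context.

Symptom context (task monotony/reward, or the activity constraints) is
held constant within schedule segments and switches at segment
boundaries.  Decay dynamics are state-continuous across boundaries: the
level carries over and only the effective rate changes, which is the
solution of ``dA/dt = -rate(t) * A`` with a piecewise-constant rate and
reduces exactly to the closed form on a single segment.  A segment may
instead be flagged ``reset=True`` to model a fresh task start, snapping
the level back to ``initial_level`` at the segment's start.

The hyperactivity oscillation keeps a global phase ``w*t + phi``; only
the amplitude switches with context.

Observation noise is additive i.i.d. Gaussian on top of the latent
signal, with an optional clamp at zero for observed activity counts.
Every stochastic operation takes an explicit seed and uses its own
`numpy.random.Generator`; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ScheduleCoverageError
from .models_core import (
    ActivityContext,
    ChoicePolicy,
    DecayParams,
    DiscountingParams,
    RewardProspect,
    TaskContext,
    choice_probability,
    effective_amplitude,
    effective_decay_rate,
)

__all__ = [
    "Segment",
    "ContextSchedule",
    "NoiseSpec",
    "TRAJECTORY_COLUMNS",
    "CHOICE_COLUMNS",
    "piecewise_decay_level",
    "piecewise_hyperactivity_level",
    "simulate_decay_trajectory",
    "simulate_hyperactivity_trajectory",
    "simulate_choice_experiment",
    "standard_choice_battery",
]

# Canonical column orders for the two tabular interchange formats.
TRAJECTORY_COLUMNS = [
    "subject_id",
    "facet_or_stream",
    "time",
    "context_segment_id",
    "latent_value",
    "observed_value",
]
CHOICE_COLUMNS = [
    "subject_id",
    "trial_id",
    "ssr_amount",
    "ssr_delay",
    "llr_amount",
    "llr_delay",
    "true_probability",
    "choice",
]

_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant context interval [start, end)."""

    start: float
    end: float
    context: TaskContext | ActivityContext
    reset: bool = False

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"segment start ({self.start}) must be < end ({self.end})")


@dataclass(frozen=True)
class ContextSchedule:
    """Gap-free, ordered sequence of context segments plus a time-unit label."""

    segments: tuple[Segment, ...]
    units: str = "minutes"

    def __post_init__(self):
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("schedule needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if abs(b.start - a.end) > _BOUNDARY_TOL:
                raise ValueError(
                    f"segments must be contiguous: gap/overlap between "
                    f"t={a.end} and t={b.start}"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    def segment_indices(self, times: np.ndarray) -> np.ndarray:
        """Map each time to its segment index; error on uncovered times."""
        times = np.asarray(times, dtype=float)
        lo, hi = self.start, self.end
        bad = (times < lo - _BOUNDARY_TOL) | (times > hi + _BOUNDARY_TOL)
        if np.any(bad):
            t0 = float(times[bad][0])
            raise ScheduleCoverageError(
                f"time {t0} outside schedule coverage [{lo}, {hi}]"
            )
        starts = np.array([s.start for s in self.segments])
        idx = np.searchsorted(starts, times, side="right") - 1
        return np.clip(idx, 0, len(self.segments) - 1)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive observation noise: none, or zero-mean Gaussian with sd."""

    family: str = "none"
    sd: float = 0.0
    clamp_at_zero: bool = False

    def __post_init__(self):
        if self.family not in ("none", "gaussian"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.family == "none" and self.sd != 0:
            raise ValueError("family 'none' requires sd = 0")

    @property
    def active(self) -> bool:
        return self.family == "gaussian" and self.sd > 0


def _sorted_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D grid")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return t


def piecewise_decay_level(
    params: DecayParams, schedule: ContextSchedule, times
) -> tuple[np.ndarray, np.ndarray]:
    """Latent decay level on a grid under a piecewise-constant schedule.

    Returns ``(latent, segment_index)``.  The level enters segment j at
    the value it left segment j-1 with (or ``initial_level`` if the
    segment is a reset) and decays at that segment's effective rate.
    """
    times = _sorted_times(times)
    idx = schedule.segment_indices(times)
    rates = np.array(
        [effective_decay_rate(params, s.context) for s in schedule.segments]
    )
    # entry level of each segment, chained from the schedule start
    entry = np.empty(len(schedule.segments))
    level = params.initial_level
    for j, seg in enumerate(schedule.segments):
        if seg.reset:
            level = params.initial_level
        entry[j] = level
        level = level * np.exp(-rates[j] * (seg.end - seg.start))
    starts = np.array([s.start for s in schedule.segments])
    latent = entry[idx] * np.exp(-rates[idx] * (times - starts[idx]))
    return latent, idx


def piecewise_hyperactivity_level(
    params, schedule: ContextSchedule, times
) -> tuple[np.ndarray, np.ndarray]:
    """Latent oscillation on a grid; amplitude per segment, phase global."""
    times = _sorted_times(times)
    idx = schedule.segment_indices(times)
    amps = np.array(
        [effective_amplitude(params, s.context) for s in schedule.segments]
    )
    latent = params.baseline + amps[idx] * np.sin(
        params.angular_frequency * times + params.phase
    )
    return latent, idx


def _observe(latent: np.ndarray, noise: NoiseSpec, rng: np.random.Generator):
    observed = latent.copy()
    if noise.active:
        observed = observed + rng.normal(0.0, noise.sd, size=latent.shape)
    if noise.clamp_at_zero:
        observed = np.maximum(observed, 0.0)
    return observed


def _context_columns(schedule: ContextSchedule, idx: np.ndarray) -> dict:
    cols: dict[str, np.ndarray] = {}
    sample = schedule.segments[0].context
    for name in type(sample).model_fields:
        vals = np.array([getattr(s.context, name) for s in schedule.segments])
        cols[name] = vals[idx]
    return cols


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_decay_trajectory(
    params: DecayParams,
    schedule: ContextSchedule,
    times,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    subject_id: str = "s000",
    include_context: bool = True,
) -> pd.DataFrame:
    """Simulate one inattention-facet trajectory.

    Returns a trajectory table with latent and observed values; with
    ``include_context`` the per-row monotony/reward covariates are
    appended (needed by the fitting routines).
    """
    latent, idx = piecewise_decay_level(params, schedule, times)
    rng = _as_rng(seed)
    observed = _observe(latent, noise, rng)
    data = {
        "subject_id": subject_id,
        "facet_or_stream": params.facet.value,
        "time": np.asarray(times, dtype=float),
        "context_segment_id": idx,
        "latent_value": latent,
        "observed_value": observed,
    }
    if include_context:
        data.update(_context_columns(schedule, idx))
    return pd.DataFrame(data)


def simulate_hyperactivity_trajectory(
    params,
    schedule: ContextSchedule,
    times,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    subject_id: str = "s000",
    include_context: bool = True,
) -> pd.DataFrame:
    """Simulate a hyperactivity trajectory (amplitude modulated per segment)."""
    latent, idx = piecewise_hyperactivity_level(params, schedule, times)
    rng = _as_rng(seed)
    observed = _observe(latent, noise, rng)
    data = {
        "subject_id": subject_id,
        "facet_or_stream": "hyperactivity",
        "time": np.asarray(times, dtype=float),
        "context_segment_id": idx,
        "latent_value": latent,
        "observed_value": observed,
    }
    if include_context:
        data.update(_context_columns(schedule, idx))
    return pd.DataFrame(data)


def simulate_choice_experiment(
    trials: list[tuple[RewardProspect, RewardProspect]],
    disc: DiscountingParams,
    policy: ChoicePolicy,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    subject_id: str = "s000",
) -> pd.DataFrame:
    """Simulate Bernoulli choices over (SSR, LLR) prospect pairs.

    ``choice`` is 1 when the smaller-sooner reward was taken; the softmax
    probability of that event is recorded alongside each draw.
    """
    if not trials:
        raise EmptyInputError("empty trial list")
    rng = _as_rng(seed)
    probs = np.array(
        [choice_probability(ssr, llr, disc, policy) for ssr, llr in trials]
    )
    choices = (rng.random(len(trials)) < probs).astype(int)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial_id": np.arange(len(trials)),
            "ssr_amount": [s.amount for s, _ in trials],
            "ssr_delay": [s.delay for s, _ in trials],
            "llr_amount": [l.amount for _, l in trials],
            "llr_delay": [l.delay for _, l in trials],
            "true_probability": probs,
            "choice": choices,
        }
    )


def standard_choice_battery(
    n_delays: int = 6,
    n_amount_ratios: int = 5,
    ssr_amount: float = 10.0,
    delay_range: tuple[float, float] = (1.0, 180.0),
    ratio_range: tuple[float, float] = (1.5, 4.0),
) -> list[tuple[RewardProspect, RewardProspect]]:
    """Deterministic SSR/LLR grid over delays x amount ratios.

    The smaller-sooner option is always immediate (delay 0).  Delays are
    geometrically spaced over ``delay_range`` (days, default 1-180) and
    the larger-later amount is ``ssr_amount`` times a ratio linearly
    spaced over ``ratio_range`` (default 1.5-4).
    """
    if n_delays < 1 or n_amount_ratios < 1:
        raise ValueError("n_delays and n_amount_ratios must be >= 1")
    delays = np.geomspace(delay_range[0], delay_range[1], n_delays)
    ratios = np.linspace(ratio_range[0], ratio_range[1], n_amount_ratios)
    battery = []
    for d in delays:
        for r in ratios:
            ssr = RewardProspect(amount=ssr_amount, delay=0.0)
            llr = RewardProspect(amount=ssr_amount * float(r), delay=float(d))
            battery.append((ssr, llr))
    return battery
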