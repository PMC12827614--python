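"""Core symptom-dynamics equations.

Three interpretable model families describe how ADHD core symptoms evolve
in time and respond to context:

* **Inattention facets** (sustained attention, attention to detail, effort)
  decay exponentially from an initial level.  The effective decay rate is
  the baseline rate accelerated by perceived task monotony and protected
  by perceived reward:  ``rate = base * (1 + k_M*M) / (1 + k_R*R)``.

* **Hyperactivity** oscillates around a baseline motor-activity level.
  Contextual constraints (cognitive demand, demands for stillness,
  reinforcement of calm behaviour) suppress the oscillation amplitude:
  ``H(t) = baseline + amplitude(context) * sin(w*t + phi)`` with
  ``amplitude = H_max / (1 + k_C*C + k_E*E + k_RC*R_C)``.

* **Impulsive choice** combines hyperbolic delay discounting
  ``V = A / (1 + k*D)`` with a softmax (logistic) rule mapping the
  subjective-value difference between a larger-later and a smaller-sooner
  reward to the probability of taking the sooner one.

Everything here is pure and stateless: parameter containers are frozen,
validated pydantic models, and each operation is a plain function of its
arguments.  Time-like arguments accept scalars or numpy arrays.

Units are conventions, not conversions: task/hyperactivity time is in
minutes, reward delay in days; context covariates are dimensionless with
[0, 1] the recommended working range (sensitivities absorb any rescaling).
"""

from __future__ import annotations

import enum
import math

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .exceptions import NumericalError

__all__ = [
    "Facet",
    "DecayParams",
    "TaskContext",
    "HyperactivityParams",
    "ActivityContext",
    "RewardProspect",
    "DiscountingParams",
    "ChoicePolicy",
    "effective_decay_rate",
    "decay_level",
    "effective_amplitude",
    "hyperactivity_level",
    "subjective_value",
    "choice_probability",
]

TWO_PI = 2.0 * math.pi

# exp() overflows IEEE doubles just above 709; clip the logistic exponent
# symmetrically well inside that.
_EXP_CLIP = 700.0


class Facet(str, enum.Enum):
    """Inattention facet labels; the functional form is shared."""

    SUSTAINED_ATTENTION = "sustained_attention"
    ATTENTION_TO_DETAIL = "attention_to_detail"
    EFFORT = "effort"


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class DecayParams(_Frozen):
    """Parameters of one inattention facet's modulated exponential decay.

    ``initial_level`` is in normalized symptom units, ``base_rate`` in
    1/minute; the two sensitivities are dimensionless.
    """

    facet: Facet = Facet.SUSTAINED_ATTENTION
    initial_level: float = Field(gt=0)
    base_rate: float = Field(gt=0)
    monotony_sensitivity: float = Field(default=0.0, ge=0)
    reward_sensitivity: float = Field(default=0.0, ge=0)


class TaskContext(_Frozen):
    """Task characteristics modulating inattention decay (dimensionless)."""

    monotony: float = Field(default=0.0, ge=0)
    reward: float = Field(default=0.0, ge=0)


class HyperactivityParams(_Frozen):
    """Parameters of the context-modulated motor-activity oscillation.

    ``baseline`` and ``max_amplitude`` are in activity units,
    ``angular_frequency`` in radians/minute; ``phase`` is normalized to
    [0, 2*pi) on construction.
    """

    baseline: float = Field(ge=0)
    max_amplitude: float = Field(ge=0)
    cognitive_sensitivity: float = Field(default=0.0, ge=0)
    stillness_sensitivity: float = Field(default=0.0, ge=0)
    calm_reinforcement_sensitivity: float = Field(default=0.0, ge=0)
    angular_frequency: float = Field(gt=0)
    phase: float = 0.0

    @field_validator("phase")
    @classmethod
    def _normalize_phase(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("phase must be finite")
        return float(np.mod(v, TWO_PI))


class ActivityContext(_Frozen):
    """Contextual constraints suppressing hyperactive oscillation."""

    cognitive_demand: float = Field(default=0.0, ge=0)
    stillness_demand: float = Field(default=0.0, ge=0)
    calm_reinforcement: float = Field(default=0.0, ge=0)


class RewardProspect(_Frozen):
    """A reward option: amount (reward units) available after a delay (days)."""

    amount: float = Field(gt=0)
    delay: float = Field(default=0.0, ge=0)


class DiscountingParams(_Frozen):
    """Hyperbolic discount rate k (1/day); higher k = steeper discounting."""

    discount_rate: float = Field(ge=0)


class ChoicePolicy(_Frozen):
    """Softmax consistency; 0 = fully random, large = near-deterministic."""

    consistency: float = Field(ge=0)


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return t


def effective_decay_rate(params: DecayParams, ctx: TaskContext) -> float:
    """Baseline decay rate accelerated by monotony, protected by reward.

    Returns ``base_rate * (1 + k_M * M) / (1 + k_R * R)``; strictly
    positive, nondecreasing in monotony, nonincreasing in reward.
    """
    return (
        params.base_rate
        * (1.0 + params.monotony_sensitivity * ctx.monotony)
        / (1.0 + params.reward_sensitivity * ctx.reward)
    )


def decay_level(params: DecayParams, ctx: TaskContext, t):
    """Facet level at time ``t`` (minutes): ``initial * exp(-rate * t)``.

    ``t`` may be a scalar or array; negative times raise ``ValueError``.
    """
    t = _check_time(t)
    rate = effective_decay_rate(params, ctx)
    out = params.initial_level * np.exp(-rate * t)
    return float(out) if out.ndim == 0 else out


def effective_amplitude(params: HyperactivityParams, ctx: ActivityContext) -> float:
    """Oscillation amplitude after contextual suppression.

    ``H_max / (1 + k_C*C + k_E*E + k_RC*R_C)``: equals ``max_amplitude``
    in a zero-demand context and shrinks monotonically as any covariate
    grows.
    """
    denom = (
        1.0
        + params.cognitive_sensitivity * ctx.cognitive_demand
        + params.stillness_sensitivity * ctx.stillness_demand
        + params.calm_reinforcement_sensitivity * ctx.calm_reinforcement
    )
    return params.max_amplitude / denom


def hyperactivity_level(params: HyperactivityParams, ctx: ActivityContext, t):
    """Latent motor-activity level ``baseline + amplitude * sin(w*t + phi)``.

    The value is a latent level and is returned unclamped: it can dip
    below zero when the amplitude exceeds the baseline.  Observation-side
    clamping lives in the simulation layer.
    """
    t = _check_time(t)
    amp = effective_amplitude(params, ctx)
    out = params.baseline + amp * np.sin(params.angular_frequency * t + params.phase)
    return float(out) if out.ndim == 0 else out


def subjective_value(prospect: RewardProspect, disc: DiscountingParams) -> float:
    """Hyperbolically discounted value ``A / (1 + k*D)``.

    Equals the amount at zero delay or zero discount rate, and exactly
    half the amount at delay ``1/k``.
    """
    return prospect.amount / (1.0 + disc.discount_rate * prospect.delay)


def choice_probability(
    ssr: RewardProspect,
    llr: RewardProspect,
    disc: DiscountingParams,
    policy: ChoicePolicy,
) -> float:
    """Softmax probability of choosing the smaller-sooner reward.

    ``P(SSR) = 1 / (1 + exp(beta * (V_LLR - V_SSR)))`` with the exponent
    clipped to +/-700 so the logistic never overflows; the result is
    exactly 0 or 1 only in the clipped regime.  Swapping the two
    prospects yields the complementary probability.
    """
    v_ssr = subjective_value(ssr, disc)
    v_llr = subjective_value(llr, disc)
    if not (math.isfinite(v_ssr) and math.isfinite(v_llr)):
        raise NumericalError("non-finite subjective value in choice_probability")
    z = policy.consistency * (v_llr - v_ssr)
    if not math.isfinite(z):
        raise NumericalError("non-finite logistic argument in choice_probability")
    z = min(max(z, -_EXP_CLIP), _EXP_CLIP)
    return 1.0 / (1.0 + math.exp(z))
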