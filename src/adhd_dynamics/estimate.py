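"""Parameter estimation and parameter-recovery validation.

Trajectory models are fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`), choice data by Bernoulli maximum
likelihood with an analytic gradient (`scipy.optimize.minimize`,
L-BFGS-B).  All multi-start grids are fixed and documented, so a fit is
deterministic given the data.

Identifiability is policed rather than glossed over: the decay
sensitivities require variation in the matching context covariate across
distinct (monotony, reward) conditions, and a deficient design raises
``IdentifiabilityError`` instead of returning unstable estimates.  The
hyperactivity fit collapses to a single free amplitude when contexts do
not vary, and says so in its result.

``parameter_recovery`` is the package's validation surface: simulate
data from known parameters, fit, and report per-parameter bias and RMSE.

Design conventions the fitters assume
-------------------------------------
``fit_decay`` accepts either session-style data (each distinct condition
observed from task onset, so the level starts at ``initial_level`` within
every condition; the default) or schedule-style data (one continuous
piecewise run; pass the ``schedule``, and the level chains across
segments exactly as in the simulator).

Parameter bounds: rates and the discount rate in [1e-6, 1e3];
sensitivities and choice consistency in [0, 1e3]; the angular frequency
is searched between one cycle per observation span and the Nyquist limit
of the sampling grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import DataError, EmptyInputError, IdentifiabilityError
from .models_core import (
    DecayParams,
    Facet,
    HyperactivityParams,
    TWO_PI,
)
from .simulate import (
    ContextSchedule,
    NoiseSpec,
    piecewise_decay_level,
    simulate_choice_experiment,
    simulate_decay_trajectory,
    simulate_hyperactivity_trajectory,
)

__all__ = [
    "DecayFitResult",
    "HyperactivityFitResult",
    "DiscountFitResult",
    "RecoveryReport",
    "DecayDesign",
    "HyperactivityDesign",
    "ChoiceDesign",
    "fit_decay",
    "fit_hyperactivity",
    "fit_discounting",
    "choice_log_likelihood",
    "parameter_recovery",
]

RATE_BOUNDS = (1e-6, 1e3)
SENS_BOUNDS = (0.0, 1e3)
CONSISTENCY_BOUNDS = (0.0, 1e3)
LEVEL_BOUNDS = (1e-9, 1e9)
_PROB_FLOOR = 1e-12
_LS_TOL = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14)


# --------------------------------------------------------------------------
# result containers


@dataclass
class DecayFitResult:
    estimates: DecayParams
    residual_sum_of_squares: float
    n_observations: int
    n_conditions: int
    converged: bool
    condition_design_rank: int


@dataclass
class HyperactivityFitResult:
    estimates: HyperactivityParams
    residual_sum_of_squares: float
    converged: bool
    cycles_observed: float
    collapsed_to_single_amplitude: bool = False
    unreliable: bool = False  # set when under one full cycle was observed


@dataclass
class DiscountFitResult:
    discount_rate_estimate: float
    consistency_estimate: float
    log_likelihood: float
    converged: bool
    degenerate_pattern: str = "none"  # none | all_ssr | all_llr
    at_boundary: bool = False


@dataclass
class RecoveryReport:
    """Bias/RMSE per parameter from repeated simulate-then-fit runs."""

    table: pd.DataFrame  # parameter, true_value, mean_estimate, bias, relative_bias, rmse
    n_replicates: int
    seed: int
    design_summary: str
    n_failed: int = 0
    failures: list = dc_field(default_factory=list)


# --------------------------------------------------------------------------
# decay fitting


def _decay_arrays(data: pd.DataFrame):
    for col in ("time", "observed_value", "monotony", "reward"):
        if col not in data.columns:
            raise DataError(f"fit_decay requires column {col!r}")
    t = data["time"].to_numpy(float)
    y = data["observed_value"].to_numpy(float)
    m = data["monotony"].to_numpy(float)
    r = data["reward"].to_numpy(float)
    return t, y, m, r


def _condition_rate_estimates(t, y, m, r, floor):
    """Per-(M, R)-condition log-linear slope and intercept estimates."""
    conds = {}
    keys = list(zip(np.round(m, 12), np.round(r, 12)))
    for key in dict.fromkeys(keys):
        sel = np.array([k == key for k in keys])
        tc, yc = t[sel], np.maximum(y[sel], floor)
        if tc.size >= 2 and np.ptp(tc) > 0:
            slope, intercept = np.polyfit(tc, np.log(yc), 1)
        else:
            slope, intercept = -0.05, math.log(max(float(np.max(yc)), floor))
        conds[key] = (max(-slope, 1e-8), intercept)
    return conds


def fit_decay(
    data: pd.DataFrame,
    facet: Facet | str = Facet.SUSTAINED_ATTENTION,
    schedule: ContextSchedule | None = None,
    fix_monotony_sensitivity: float | None = None,
    fix_reward_sensitivity: float | None = None,
) -> DecayFitResult:
    """Fit the modulated exponential decay by bounded least squares.

    Free parameters are ``initial_level``, ``base_rate`` and the two
    context sensitivities; either sensitivity can be fixed.  With all
    four free, the data must span at least three distinct (monotony,
    reward) conditions with variation in both covariates.

    Initialization: a log-linear regression per condition gives
    per-condition rate estimates; the rate identity
    ``rate = b + b*k_M*M - k_R*R*rate`` is linear in ``(b, b*k_M, k_R)``
    and is solved by ordinary least squares to seed the optimizer.
    """
    if data.empty:
        raise EmptyInputError("empty trajectory table")
    facet = Facet(facet)
    t, y, m, r = _decay_arrays(data)
    if np.all(y <= 0):
        raise DataError("all observations are <= 0; cannot fit a decay level")

    cond_keys = list(dict.fromkeys(zip(np.round(m, 12), np.round(r, 12))))
    n_conditions = len(cond_keys)
    cm = np.array([k[0] for k in cond_keys])
    cr = np.array([k[1] for k in cond_keys])
    design = np.column_stack([np.ones(n_conditions), cm, cr])
    design_rank = int(np.linalg.matrix_rank(design))

    free_m = fix_monotony_sensitivity is None
    free_r = fix_reward_sensitivity is None
    if free_m and free_r:
        if n_conditions < 3 or np.unique(cm).size < 2 or np.unique(cr).size < 2:
            raise IdentifiabilityError(
                "both sensitivities free requires >= 3 distinct (monotony, "
                "reward) conditions with variation in each covariate; "
                f"got {n_conditions} conditions "
                f"({np.unique(cm).size} monotony levels, "
                f"{np.unique(cr).size} reward levels)"
            )
    elif free_m and np.unique(cm).size < 2:
        raise IdentifiabilityError("monotony does not vary; fix monotony_sensitivity")
    elif free_r and np.unique(cr).size < 2:
        raise IdentifiabilityError("reward does not vary; fix reward_sensitivity")

    floor = max(float(np.max(y)) * 1e-9, 1e-300)
    conds = _condition_rate_estimates(t, y, m, r, floor)
    rates0 = np.array([conds[k][0] for k in cond_keys])
    intercepts0 = np.array([conds[k][1] for k in cond_keys])
    a0_init = float(np.exp(np.median(intercepts0)))

    # linear solve of the rate identity for the initializer
    X = np.column_stack([np.ones_like(rates0), cm, -cr * rates0])
    cols = [True, free_m, free_r]
    beta, *_ = np.linalg.lstsq(X[:, cols], rates0, rcond=None)
    b0 = float(np.clip(beta[0], *RATE_BOUNDS))
    j = 1
    if free_m:
        km0 = float(np.clip(beta[j] / b0, *SENS_BOUNDS))
        j += 1
    else:
        km0 = fix_monotony_sensitivity
    kr0 = float(np.clip(beta[j], *SENS_BOUNDS)) if free_r else fix_reward_sensitivity

    def unpack(theta):
        a0, b = theta[0], theta[1]
        i = 2
        if free_m:
            km = theta[i]
            i += 1
        else:
            km = fix_monotony_sensitivity
        kr = theta[i] if free_r else fix_reward_sensitivity
        return a0, b, km, kr

    def model(theta):
        a0, b, km, kr = unpack(theta)
        p = DecayParams(
            facet=facet,
            initial_level=max(a0, LEVEL_BOUNDS[0]),
            base_rate=max(b, RATE_BOUNDS[0]),
            monotony_sensitivity=max(km, 0.0),
            reward_sensitivity=max(kr, 0.0),
        )
        if schedule is not None:
            latent, _ = piecewise_decay_level(p, schedule, t)
            return latent
        rate = b * (1.0 + km * m) / (1.0 + kr * r)
        return a0 * np.exp(-rate * t)

    def residuals(theta):
        return y - model(theta)

    x0 = [max(a0_init, LEVEL_BOUNDS[0]), b0]
    lo, hi = [LEVEL_BOUNDS[0], RATE_BOUNDS[0]], [LEVEL_BOUNDS[1], RATE_BOUNDS[1]]
    if free_m:
        x0.append(km0)
        lo.append(SENS_BOUNDS[0])
        hi.append(SENS_BOUNDS[1])
    if free_r:
        x0.append(kr0)
        lo.append(SENS_BOUNDS[0])
        hi.append(SENS_BOUNDS[1])
    x0 = np.clip(np.asarray(x0, float), lo, hi)

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), **_LS_TOL)
    a0, b, km, kr = unpack(res.x)
    estimates = DecayParams(
        facet=facet,
        initial_level=float(a0),
        base_rate=float(b),
        monotony_sensitivity=float(km),
        reward_sensitivity=float(kr),
    )
    return DecayFitResult(
        estimates=estimates,
        residual_sum_of_squares=float(np.sum(res.fun**2)),
        n_observations=int(len(y)),
        n_conditions=n_conditions,
        converged=bool(res.success and np.all(np.isfinite(res.x))),
        condition_design_rank=design_rank,
    )


# --------------------------------------------------------------------------
# hyperactivity fitting


def _hyper_arrays(data: pd.DataFrame):
    cols = ("time", "observed_value", "cognitive_demand", "stillness_demand",
            "calm_reinforcement")
    for col in cols:
        if col not in data.columns:
            raise DataError(f"fit_hyperactivity requires column {col!r}")
    return tuple(data[c].to_numpy(float) for c in cols)


def _dominant_frequency(t, resid, w_lo, w_hi, n_grid=4000):
    """Dominant angular frequency of the mean-removed series.

    Uses a Lomb-Scargle scan so irregular grids work, then parabolic
    interpolation around the discrete peak.
    """
    from scipy.signal import lombscargle

    omegas = np.linspace(w_lo, w_hi, n_grid)
    power = lombscargle(t, resid, omegas)
    k = int(np.argmax(power))
    if 0 < k < n_grid - 1:
        y0, y1, y2 = power[k - 1 : k + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            k = k + 0.5 * (y0 - y2) / denom
    return float(np.interp(k, np.arange(n_grid), omegas))


def _sincos_solve(t, y, omega, weights=None):
    """Least-squares (offset, a, b) for y ~ c + a sin(wt) + b cos(wt)."""
    X = np.column_stack([np.ones_like(t), np.sin(omega * t), np.cos(omega * t)])
    if weights is not None:
        X = X * weights[:, None]
        y = y * weights
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def fit_hyperactivity(data: pd.DataFrame) -> HyperactivityFitResult:
    """Fit the context-modulated sinusoid by bounded least squares.

    Initialization: baseline from the sample mean; angular frequency from
    the dominant spectral peak of the mean-removed series; a global
    sine/cosine regression gives amplitude and phase (refined from eight
    equispaced phase starts).  When any context covariate varies,
    per-segment amplitudes are inverted through the suppression law
    ``1/A_j = (1 + sum_k k_x * x_j) / H_max`` — linear in the scaled
    sensitivities — to seed ``H_max`` and the sensitivities; covariates
    that do not vary have their sensitivity fixed at zero and the result
    is flagged as collapsed to a single amplitude when none vary.
    """
    if data.empty:
        raise EmptyInputError("empty trajectory table")
    t, y, C, E, RC = _hyper_arrays(data)
    if len(t) < 8:
        raise DataError("need at least 8 observations to fit the oscillation")
    order = np.argsort(t)
    t, y, C, E, RC = t[order], y[order], C[order], E[order], RC[order]

    span = float(np.ptp(t))
    dt_min = float(np.min(np.diff(np.unique(t))))
    w_lo = max(TWO_PI / span * 0.5, 1e-6)
    w_hi = math.pi / dt_min
    baseline0 = float(np.mean(y))
    resid = y - baseline0
    omega0 = _dominant_frequency(t, resid, w_lo, w_hi)

    cov = {"cognitive": C, "stillness": E, "calm": RC}
    varying = {k: np.unique(np.round(v, 12)).size > 1 for k, v in cov.items()}
    any_varying = any(varying.values())

    # global amplitude/phase seed
    c0, a_s, b_c = _sincos_solve(t, y, omega0)
    amp0 = float(np.hypot(a_s, b_c))
    if amp0 < 1e-12:
        amp0 = math.sqrt(2.0) * float(np.std(resid))
    phase0 = float(np.mod(math.atan2(b_c, a_s), TWO_PI))

    hmax0, kc0, ke0, krc0 = amp0, 0.0, 0.0, 0.0
    if any_varying:
        # per-context-condition amplitude -> linear inversion of 1/A
        keys = list(zip(np.round(C, 12), np.round(E, 12), np.round(RC, 12)))
        uniq = list(dict.fromkeys(keys))
        amps, rows = [], []
        for key in uniq:
            sel = np.array([k == key for k in keys])
            if sel.sum() < 4:
                continue
            _, aj, bj = _sincos_solve(t[sel], y[sel] - c0, omega0)
            aamp = float(np.hypot(aj, bj))
            if aamp > 1e-9:
                amps.append(aamp)
                rows.append([1.0, key[0], key[1], key[2]])
        if len(amps) >= 2:
            A = np.asarray(rows)
            coef, *_ = np.linalg.lstsq(A, 1.0 / np.asarray(amps), rcond=None)
            if coef[0] > 1e-12:
                hmax0 = float(np.clip(1.0 / coef[0], 1e-9, 1e9))
                kc0, ke0, krc0 = (
                    float(np.clip(c / coef[0], *SENS_BOUNDS)) for c in coef[1:]
                )

    free = ["baseline", "hmax", "omega", "phase"]
    free += [k for k, v in (("kc", varying["cognitive"]),
                            ("ke", varying["stillness"]),
                            ("krc", varying["calm"])) if v]

    def unpack(theta):
        d = dict(zip(free, theta))
        return (
            d["baseline"], d["hmax"], d.get("kc", 0.0), d.get("ke", 0.0),
            d.get("krc", 0.0), d["omega"], d["phase"],
        )

    def residuals(theta):
        base, hmax, kc, ke, krc, omega, phase = unpack(theta)
        amp = hmax / (1.0 + kc * C + ke * E + krc * RC)
        return y - (base + amp * np.sin(omega * t + phase))

    start = {"baseline": baseline0, "hmax": hmax0, "omega": omega0,
             "phase": phase0, "kc": kc0, "ke": ke0, "krc": krc0}
    lower = {"baseline": 0.0, "hmax": 0.0, "omega": w_lo, "phase": -TWO_PI,
             "kc": 0.0, "ke": 0.0, "krc": 0.0}
    upper = {"baseline": 1e9, "hmax": 1e9, "omega": w_hi, "phase": 2 * TWO_PI,
             "kc": SENS_BOUNDS[1], "ke": SENS_BOUNDS[1], "krc": SENS_BOUNDS[1]}
    lo = [lower[k] for k in free]
    hi = [upper[k] for k in free]

    # eight equispaced phase starts besides the regression seed
    phase_starts = [phase0] + [j * TWO_PI / 8 for j in range(8)]
    best = None
    for ph in phase_starts:
        x0 = np.clip([start[k] if k != "phase" else ph for k in free], lo, hi)
        res = optimize.least_squares(residuals, x0, bounds=(lo, hi), **_LS_TOL)
        if best is None or res.cost < best.cost - 1e-15:
            best = res

    base, hmax, kc, ke, krc, omega, phase = unpack(best.x)
    estimates = HyperactivityParams(
        baseline=float(max(base, 0.0)),
        max_amplitude=float(max(hmax, 0.0)),
        cognitive_sensitivity=float(kc),
        stillness_sensitivity=float(ke),
        calm_reinforcement_sensitivity=float(krc),
        angular_frequency=float(omega),
        phase=float(np.mod(phase, TWO_PI)),
    )
    cycles = float(omega * span / TWO_PI)
    return HyperactivityFitResult(
        estimates=estimates,
        residual_sum_of_squares=float(np.sum(best.fun**2)),
        converged=bool(best.success and np.all(np.isfinite(best.x))),
        cycles_observed=cycles,
        collapsed_to_single_amplitude=not any_varying,
        unreliable=cycles < 1.0,
    )


# --------------------------------------------------------------------------
# discounting fitting


def _choice_arrays(trials: pd.DataFrame):
    cols = ("ssr_amount", "ssr_delay", "llr_amount", "llr_delay")
    for col in cols:
        if col not in trials.columns:
            raise DataError(f"fit_discounting requires column {col!r}")
    return tuple(trials[c].to_numpy(float) for c in cols)


def _nll_and_grad(k, beta, a_s, d_s, a_l, d_l, y):
    """Negative Bernoulli log-likelihood of the softmax choice model.

    ``y`` may be fractional: using the true choice probabilities as the
    response turns the fit into a cross-entropy minimization whose
    optimum is the generating parameters exactly.
    """
    den_s = 1.0 + k * d_s
    den_l = 1.0 + k * d_l
    v_s = a_s / den_s
    v_l = a_l / den_l
    dv = v_l - v_s  # choosing SSR has logistic argument -beta*dv
    z = np.clip(-beta * dv, -700.0, 700.0)
    p = 1.0 / (1.0 + np.exp(-z))  # P(choose SSR)
    pc = np.clip(p, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    ll = np.sum(y * np.log(pc) + (1.0 - y) * np.log1p(-pc))
    # d ll / dz = sum (y - p); z = -beta*dv
    resid = y - p
    ddv_dk = -a_l * d_l / den_l**2 + a_s * d_s / den_s**2
    dll_dk = np.sum(resid * (-beta) * ddv_dk)
    dll_dbeta = np.sum(resid * (-dv))
    return -ll, np.array([-dll_dk, -dll_dbeta])


def choice_log_likelihood(trials: pd.DataFrame, discount_rate: float,
                          consistency: float, response: str = "choice") -> float:
    """Bernoulli log-likelihood of the trial table at fixed parameters."""
    a_s, d_s, a_l, d_l = _choice_arrays(trials)
    y = trials[response].to_numpy(float)
    nll, _ = _nll_and_grad(discount_rate, consistency, a_s, d_s, a_l, d_l, y)
    return -float(nll)


# fixed multi-start grid: log-spaced discount rates x consistency decades
_K_STARTS = tuple(np.geomspace(1e-4, 10.0, 6))
_BETA_STARTS = (0.01, 0.1, 1.0)


def fit_discounting(trials: pd.DataFrame, response: str = "choice") -> DiscountFitResult:
    """Maximum-likelihood fit of (discount_rate, consistency).

    ``response="choice"`` fits the recorded binary choices;
    ``response="true_probability"`` fits the softmax probabilities
    themselves (the noise-free limit, used for exact-recovery checks).
    Datasets where every trial went the same way have no interior
    optimum; they are flagged via ``degenerate_pattern`` and the bounded
    boundary estimate is returned rather than presented as interior.
    """
    if trials is None or len(trials) == 0:
        raise EmptyInputError("empty choice-trial table")
    if response not in trials.columns:
        raise DataError(f"fit_discounting requires column {response!r}")
    a_s, d_s, a_l, d_l = _choice_arrays(trials)
    pairs = set(zip(a_s, d_s, a_l, d_l))
    if len(pairs) < 2:
        raise IdentifiabilityError(
            "need >= 2 distinct prospect pairs to identify both parameters"
        )
    y = trials[response].to_numpy(float)

    degenerate = "none"
    if response == "choice":
        if np.all(y == 1):
            degenerate = "all_ssr"
        elif np.all(y == 0):
            degenerate = "all_llr"

    bounds = [RATE_BOUNDS, CONSISTENCY_BOUNDS]

    best = None
    for k0 in _K_STARTS:
        for b0 in _BETA_STARTS:
            res = optimize.minimize(
                lambda x: _nll_and_grad(x[0], x[1], a_s, d_s, a_l, d_l, y),
                x0=np.array([k0, b0]),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res

    k_hat, beta_hat = float(best.x[0]), float(best.x[1])
    at_boundary = (
        k_hat <= RATE_BOUNDS[0] * (1 + 1e-6)
        or k_hat >= RATE_BOUNDS[1] * (1 - 1e-6)
        or beta_hat >= CONSISTENCY_BOUNDS[1] * (1 - 1e-6)
    )
    return DiscountFitResult(
        discount_rate_estimate=k_hat,
        consistency_estimate=beta_hat,
        log_likelihood=-float(best.fun),
        converged=bool(best.success and degenerate == "none" and not at_boundary),
        degenerate_pattern=degenerate,
        at_boundary=at_boundary or degenerate != "none",
    )


# --------------------------------------------------------------------------
# parameter recovery


@dataclass(frozen=True)
class DecayDesign:
    schedule: ContextSchedule
    times: tuple
    noise: NoiseSpec = NoiseSpec()


@dataclass(frozen=True)
class HyperactivityDesign:
    schedule: ContextSchedule
    times: tuple
    noise: NoiseSpec = NoiseSpec()


@dataclass(frozen=True)
class ChoiceDesign:
    trials: tuple  # of (ssr, llr) RewardProspect pairs
    response: str = "choice"


def _decay_true_and_fit(true_params, design, rng):
    table = simulate_decay_trajectory(
        true_params, design.schedule, np.asarray(design.times), design.noise, seed=rng
    )
    fit = fit_decay(table, facet=true_params.facet, schedule=design.schedule)
    names = ["initial_level", "base_rate", "monotony_sensitivity", "reward_sensitivity"]
    return names, [getattr(fit.estimates, n) for n in names]


def _hyper_true_and_fit(true_params, design, rng):
    table = simulate_hyperactivity_trajectory(
        true_params, design.schedule, np.asarray(design.times), design.noise, seed=rng
    )
    fit = fit_hyperactivity(table)
    names = [
        "baseline", "max_amplitude", "cognitive_sensitivity",
        "stillness_sensitivity", "calm_reinforcement_sensitivity",
        "angular_frequency", "phase",
    ]
    return names, [getattr(fit.estimates, n) for n in names]


def _choice_true_and_fit(true_params, design, rng):
    disc, policy = true_params
    table = simulate_choice_experiment(list(design.trials), disc, policy, seed=rng)
    fit = fit_discounting(table, response=design.response)
    return (
        ["discount_rate", "consistency"],
        [fit.discount_rate_estimate, fit.consistency_estimate],
    )


def _true_values(true_params, names):
    if isinstance(true_params, tuple):
        disc, policy = true_params
        lookup = {"discount_rate": disc.discount_rate, "consistency": policy.consistency}
        return [lookup[n] for n in names]
    return [getattr(true_params, n) for n in names]


def parameter_recovery(
    true_params,
    design: DecayDesign | HyperactivityDesign | ChoiceDesign,
    n_replicates: int,
    seed: int,
) -> RecoveryReport:
    """Simulate-then-fit validation loop.

    ``true_params`` is a ``DecayParams``, ``HyperactivityParams``, or a
    ``(DiscountingParams, ChoicePolicy)`` tuple matching the design.
    Each replicate gets a child generator spawned deterministically from
    ``seed``; fit failures are recorded per replicate, never raised.
    Phase estimates are compared on the circle (wrapped difference).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    runner = {
        DecayDesign: _decay_true_and_fit,
        HyperactivityDesign: _hyper_true_and_fit,
        ChoiceDesign: _choice_true_and_fit,
    }[type(design)]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    names = None
    rows = []
    failures = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            names, values = runner(true_params, design, rng)
            rows.append(values)
        except Exception as exc:  # record, do not propagate
            failures.append((rep, repr(exc)))
    if names is None:
        raise DataError(f"every replicate failed; first error: {failures[0][1]}")

    est = np.asarray(rows, dtype=float)
    true = np.asarray(_true_values(true_params, names), dtype=float)

    # phase lives on a circle: compare via wrapped differences
    if "phase" in (names or []):
        j = names.index("phase")
        d = np.mod(est[:, j] - true[j] + math.pi, TWO_PI) - math.pi
        est[:, j] = true[j] + d

    mean_est = est.mean(axis=0)
    bias = mean_est - true
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_bias = np.where(true != 0, bias / true, np.nan)
    rmse = np.sqrt(np.mean((est - true[None, :]) ** 2, axis=0))
    table = pd.DataFrame(
        {
            "parameter": names,
            "true_value": true,
            "mean_estimate": mean_est,
            "bias": bias,
            "relative_bias": rel_bias,
            "rmse": rmse,
        }
    )
    return RecoveryReport(
        table=table,
        n_replicates=n_replicates,
        seed=seed,
        design_summary=type(design).__name__,
        n_failed=len(failures),
        failures=failures,
    )
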