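"""Restricted/repetitive-behaviour submodels.

Four mechanisms:

* entropy-modulated oscillatory stereotypies, optionally organised into
  bouts whose onsets follow a non-homogeneous Poisson process;
* precision-weighted sigmoid distress in response to routine deviations,
  including an equifinality diagnostic separating high-precision,
  low-threshold and high-severity routes to the same distress level;
* restricted-interest engagement with a persistent floor and
  reward-modulated exponential decay;
* cumulative sensory load as the integral of an exponentially
  habituating (or sensitising) response, with the three analytic branches
  joined continuously through a series expansion near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .params import InterestParams, MovementParams, RoutineParams, SensoryStimulusParams

__all__ = [
    "EntropySignal",
    "ArousalSignal",
    "BoutSequence",
    "effective_amplitude",
    "movement_intensity",
    "simulate_bouts",
    "deviation_distress",
    "total_sameness",
    "equifinality_profiles",
    "interest_engagement",
    "habituation_rate",
    "cumulative_impact",
    "total_sensory_load",
    "DELTA_BRANCH_EPS",
]

#: Width of the series branch around delta = 0 (hour^-1). Narrow enough to
#: honour the explicit delta = 0 analytic branch, wide enough to avoid
#: catastrophic cancellation in (1 - exp(-delta T)) / delta.
DELTA_BRANCH_EPS = 1e-8


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------


@dataclass
class EntropySignal:
    """Environmental entropy (bits) plus engagement and alternative-behaviour
    availability on a common, strictly increasing hour grid."""

    t: np.ndarray
    H_env: np.ndarray
    E_engage: np.ndarray = None
    Phi_alt: np.ndarray = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size == 0:
            raise ValueError("entropy grid must be non-empty")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("entropy grid must be strictly increasing")
        self.H_env = np.broadcast_to(np.asarray(self.H_env, dtype=float), self.t.shape).copy()
        if np.any(self.H_env < 0):
            raise ValueError("H_env must be nonnegative")
        for name in ("E_engage", "Phi_alt"):
            v = getattr(self, name)
            v = np.zeros_like(self.t) if v is None else np.broadcast_to(
                np.asarray(v, dtype=float), self.t.shape).copy()
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, v)

    @classmethod
    def constant(cls, t, H_env, E_engage=0.0, Phi_alt=0.0) -> "EntropySignal":
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return cls(t=t, H_env=np.full_like(t, H_env),
                   E_engage=np.full_like(t, E_engage),
                   Phi_alt=np.full_like(t, Phi_alt))

    def at(self, tq):
        tq = np.asarray(tq, dtype=float)
        return (np.interp(tq, self.t, self.H_env),
                np.interp(tq, self.t, self.E_engage),
                np.interp(tq, self.t, self.Phi_alt))


@dataclass
class ArousalSignal:
    """Arousal/anxiety level on an hour grid; nonnegative."""

    t: np.ndarray
    Xi: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.Xi = np.broadcast_to(np.asarray(self.Xi, dtype=float), self.t.shape).copy()
        if np.any(self.Xi < 0):
            raise ValueError("Xi must be nonnegative")


@dataclass
class BoutSequence:
    """Bout onsets (hours) with durations; non-overlapping after truncation."""

    onsets: np.ndarray
    durations: np.ndarray
    oscillation: MovementParams = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.onsets.size:
            if not np.all(np.diff(self.onsets) > 0):
                raise ValueError("bout onsets must be strictly increasing")
            if np.any(self.durations <= 0):
                raise ValueError("bout durations must be positive")

    def __len__(self) -> int:
        return int(self.onsets.size)


# ---------------------------------------------------------------------------
# Stereotypies
# ---------------------------------------------------------------------------


def effective_amplitude(p: MovementParams, H_env, E_engage=0.0, Phi_alt=0.0):
    """Saturating entropy-driven amplitude.

    ``Gamma_max * H/(H + k_H) * 1/(1 + k_engage E + k_alt Φ)``; bounded in
    [0, Gamma_max).
    """
    H = np.asarray(H_env, dtype=float)
    if np.any(H < 0):
        raise ValueError("environmental entropy must be nonnegative")
    sat = H / (H + p.k_H)
    damp = 1.0 + p.k_engage * np.asarray(E_engage, dtype=float) + p.k_alt * np.asarray(Phi_alt, dtype=float)
    out = p.Gamma_max * sat / damp
    return out if out.ndim else float(out)


def movement_intensity(p: MovementParams, signals: EntropySignal, t, clamp: bool = False):
    """Oscillatory stereotypy intensity ``M0 + Gamma_eff(t) sin(omega t + phi)``.

    ``t`` in hours (scalar or array), interpolated within the signal grid.
    The optional nonnegativity clamp is off by default — the mechanistic
    form is allowed to dip below baseline.
    """
    t = np.asarray(t, dtype=float)
    H, E, Phi = signals.at(t)
    gamma = effective_amplitude(p, H, E, Phi)
    out = p.M0 + gamma * np.sin(p.omega * t + p.phi)
    if clamp:
        out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def _duration_sampler(duration_dist, rng):
    """Build a duration sampler from a spec dict or callable."""
    if callable(duration_dist):
        return lambda n: np.asarray(duration_dist(n, rng), dtype=float)
    kind = duration_dist.get("kind", "lognormal")
    if kind == "lognormal":
        mu = duration_dist.get("mean_log", math.log(0.05))
        sd = duration_dist.get("sd_log", 0.5)
        if sd <= 0 or not np.isfinite(mu) or not np.isfinite(sd):
            raise ValueError("lognormal duration spec requires finite mean_log and sd_log > 0")
        return lambda n: rng.lognormal(mu, sd, size=n)
    if kind == "fixed":
        v = float(duration_dist["value"])
        if v <= 0:
            raise ValueError("fixed duration must be positive")
        return lambda n: np.full(n, v)
    if kind == "exponential":
        scale = float(duration_dist.get("scale", 0.05))
        if scale <= 0:
            raise ValueError("exponential duration scale must be positive")
        return lambda n: rng.exponential(scale, size=n)
    raise ValueError(f"unknown duration distribution kind: {kind!r}")


def simulate_bouts(p: MovementParams, signals: EntropySignal, rate_scale: float,
                   duration_dist=None, seed: int = 0, horizon: float = None,
                   rate_fn=None) -> BoutSequence:
    """Sample bout onsets by thinning a non-homogeneous Poisson process.

    The default onset rate reuses the amplitude's saturating entropy
    nonlinearity, ``λ(t) = rate_scale * H(t)/(H(t) + k_H)`` (hour⁻¹); any
    callable ``rate_fn(t)`` may replace it. Within-bout behaviour follows
    the oscillatory intensity model. Durations default to log-normal and
    are truncated so bouts never overlap. Fully reproducible given ``seed``.
    """
    if rate_scale < 0:
        raise ValueError("rate_scale must be nonnegative")
    rng = np.random.default_rng(seed)
    horizon = float(signals.t[-1] if horizon is None else horizon)
    if rate_fn is None:
        def rate_fn(tq):
            H, _, _ = signals.at(tq)
            return rate_scale * H / (H + p.k_H)
    dense = np.linspace(0.0, horizon, 2049)
    lam_max = float(np.max(rate_fn(dense)))
    if lam_max <= 0 or horizon <= 0:
        return BoutSequence(onsets=np.empty(0), durations=np.empty(0), oscillation=p)
    # thinning: homogeneous candidates at lam_max, accept w.p. lambda(t)/lam_max
    onsets = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t > horizon:
            break
        if rng.uniform() * lam_max <= float(rate_fn(t)):
            onsets.append(t)
    onsets = np.asarray(onsets)
    sampler = _duration_sampler(duration_dist or {"kind": "lognormal"}, rng)
    durations = sampler(onsets.size)
    if onsets.size:
        gaps = np.append(np.diff(onsets), horizon - onsets[-1])
        durations = np.minimum(durations, gaps)  # truncate at next onset
    return BoutSequence(onsets=onsets, durations=durations, oscillation=p)


# ---------------------------------------------------------------------------
# Insistence on sameness
# ---------------------------------------------------------------------------


def deviation_distress(r: RoutineParams, x_current):
    """Sigmoid distress for one routine at the current state.

    ``s_max / (1 + exp(-r_base π (|x - x̄| - θ)))`` — the steepness is the
    baseline steepness scaled by the Bayesian precision assigned to this
    routine's prediction errors. The value at zero deviation,
    ``s_max/(1+exp(rθ))``, is retained as the functional form's small floor.
    """
    x = np.asarray(x_current, dtype=float)
    dev = np.abs(x - r.x_expected)
    rk = r.r_base * r.pi_precision
    with np.errstate(over="ignore"):
        out = r.s_max / (1.0 + np.exp(-rk * (dev - r.theta)))
    return out if out.ndim else float(out)


def total_sameness(routines, states) -> float:
    """Summed distress over routines; ``states`` aligned with ``routines``."""
    if len(routines) != len(states):
        raise ValueError("routines and states must have equal length")
    return float(sum(deviation_distress(r, x) for r, x in zip(routines, states)))


def _solve_route(S_target, deviation_ref, s_max, theta, pi_precision, label):
    # closed-form steepness placing the anchor on the curve:
    # S = s/(1+exp(-r(d-theta)))  =>  r = -ln(s/S - 1)/(d - theta)
    ratio = s_max / S_target
    if not (1.0 < ratio < 2.0) or deviation_ref <= theta:
        raise ValueError("infeasible equifinality target for route " + label)
    r_eff = -math.log(ratio - 1.0) / (deviation_ref - theta)
    return RoutineParams(label=label, s_max=s_max, r_base=r_eff / pi_precision,
                         pi_precision=pi_precision, theta=theta, x_expected=0.0)


def equifinality_profiles(S_target: float, deviation_ref: float, s_cap: float = 1.0):
    """Three mechanistically distinct routines producing identical distress.

    Returns (high-precision, low-threshold, high-severity) configurations,
    each satisfying ``S(deviation_ref) = S_target`` to closed-form accuracy
    while disagreeing at ``deviation_ref / 2`` — the diagnostic signature
    that superficially similar presentations have different parameter
    origins. Raises for targets outside the achievable range
    ``0 < S_target < s_cap``.
    """
    if not (0.0 < S_target < s_cap):
        raise ValueError(
            f"S_target={S_target} infeasible: must lie strictly inside (0, {s_cap})")
    if deviation_ref <= 0:
        raise ValueError("deviation_ref must be positive")

    def capped(f):
        return min(s_cap, f * S_target)

    routes = [
        _solve_route(S_target, deviation_ref, capped(1.5), deviation_ref / 2.0, 4.0,
                     "high_precision"),
        _solve_route(S_target, deviation_ref, capped(1.5), deviation_ref / 6.0, 1.0,
                     "low_threshold"),
        _solve_route(S_target, deviation_ref, capped(1.9), 0.75 * deviation_ref, 1.0,
                     "high_severity"),
    ]
    anchors = [deviation_distress(r, deviation_ref) for r in routes]
    if any(abs(a - S_target) > 1e-6 for a in anchors):
        raise ValueError("equifinality solve failed to hit the anchor")
    return routes


# ---------------------------------------------------------------------------
# Restricted interests
# ---------------------------------------------------------------------------


def interest_engagement(p: InterestParams, t):
    """Engagement intensity ``I0 + Σ b_l exp(-λ_l Δt_l)`` at time t (months).

    Each interest's clock starts at its own acquisition time; terms not yet
    acquired contribute nothing. ``b_l = b_base R_int/R_norm`` and
    ``λ_l = λ_base (1 - P_acc)``, so perfectly predictable interests
    (P_acc = 1) never decay.
    """
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(p.I0))
    for term in p.interests:
        if term.R_norm == 0:
            raise ValueError("R_norm must be nonzero")
        b = term.b_base * term.R_int / term.R_norm
        lam = term.lambda_base * (1.0 - term.P_acc)
        dt = t - term.t_acquired
        out = out + np.where(dt >= 0, b * np.exp(-lam * np.maximum(dt, 0.0)), 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Sensory load
# ---------------------------------------------------------------------------


def habituation_rate(p: SensoryStimulusParams, Xi):
    """Net habituation rate ``delta_base * gaba_ratio - k_sens * Xi`` (hour⁻¹).

    Negative values are the sensitisation regime: arousal has pushed the
    response into growth rather than decay.
    """
    Xi = np.asarray(Xi, dtype=float)
    if np.any(Xi < 0):
        raise ValueError("arousal must be nonnegative")
    out = p.delta_base * p.gaba_ratio - p.k_sens * Xi
    return out if out.ndim else float(out)


def cumulative_impact(sigma: float, delta: float, T: float) -> float:
    """Cumulative impact ``∫₀ᵀ σ exp(-δ t) dt`` of one stimulus exposure.

    Three analytic branches: bounded saturation for δ > 0, linear
    accumulation (habituation failure) for δ ≈ 0, exponential escalation
    (sensitisation) for δ < 0. Near zero a second-order series keeps the
    branches continuous to well below 1e-6·σT.
    """
    if T < 0:
        raise ValueError("exposure duration must be nonnegative")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if T == 0.0 or sigma == 0.0:
        return 0.0
    if abs(delta) <= DELTA_BRANCH_EPS:
        dT = delta * T
        return sigma * T * (1.0 - dT / 2.0 + dT * dT / 6.0)
    if delta > 0:
        return (sigma / delta) * (1.0 - math.exp(-delta * T))
    a = abs(delta)
    return (sigma / a) * (math.exp(a * T) - 1.0)


def total_sensory_load(stimuli) -> float:
    """Total load ``Σ_s P(s)`` over (params, exposure duration, arousal)
    triples; the (lagged) arousal supplied per stimulus sets its net
    habituation rate."""
    total = 0.0
    for p, T, Xi in stimuli:
        if T < 0:
            raise ValueError("exposures must be nonnegative")
        total += cumulative_impact(p.sigma, habituation_rate(p, Xi), T)
    return total
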