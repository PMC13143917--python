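"""Synthetic ground truth and EMA-style observation generator.

No empirical dataset exists for this framework, so everything downstream
is exercised on synthetic data: population draws of individual parameter
profiles, stochastic environment tracks, and noisy, irregularly sampled
observations that emulate ecological momentary assessment — a handful of
prompted self-reports per day, jittered in time, with additive Gaussian
noise clipped to each variable's valid range. Each observation carries the
identifiability tier of its data stream (1 = EMA-observable in daily life,
2 = structured observation) so fitting experiments can restrict themselves
to realistically observable channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import TrajectoryBundle
from .params import (IndividualProfile, InterestParams, InterestTerm,
                     validate_profile)

__all__ = [
    "EMADataset",
    "sample_profile",
    "generate_environment",
    "EnvironmentTrack",
    "observe",
    "DEFAULT_POPULATION_SPEC",
    "DEFAULT_DESIGN",
    "VARIABLE_TIERS",
    "VARIABLE_RANGES",
    "PARAMETER_TIERS",
]

#: Identifiability tier of each observable data stream. Reciprocity,
#: stereotypy, distress, interest engagement and sensory load are
#: EMA-observable (tier 1); nonverbal effectiveness and relationship quality
#: require structured observation (tier 2).
VARIABLE_TIERS = {"R": 1, "M": 1, "S": 1, "I": 1, "P_total": 1, "Xi": 1,
                  "Lambda_s": 1, "A": 1, "N": 2, "C": 2}

#: Valid range for clipping noisy observations (None = unbounded side).
VARIABLE_RANGES = {"R": (0.0, 1.0), "N": (0.0, None), "C": (0.0, None),
                   "M": (0.0, None), "S": (0.0, None), "I": (0.0, None),
                   "P_total": (0.0, None), "Xi": (0.0, None),
                   "Lambda_s": (0.0, 1.0), "A": (0.0, 1.0)}

#: Which data source each *parameter* needs: 1 EMA, 2 lab/structured tasks,
#: 3 neuroimaging-informed, 4 population priors only.
PARAMETER_TIERS = {
    "beta_eff": 1, "omega": 1, "s_max": 1, "r_k": 1, "I0": 1, "b": 1,
    "lambda": 1, "alpha_R0": 1,
    "eta": 2, "R_sal": 2, "theta": 2, "w_norm": 2,
    "delta_s": 3, "beta_base": 3, "pi_precision": 3,
    "gaba_ratio": 4, "sigma_scaling": 4,
}

#: Population ranges for profile sampling. Uniform ranges follow the
#: plausible parameter ranges stated alongside each submodel (e.g. baseline
#: depletion 0.1–0.5 hour⁻¹); everything not listed keeps its profile
#: default via a point mass.
DEFAULT_POPULATION_SPEC = {
    "reciprocity.R0": ("uniform", 0.5, 1.0),
    "reciprocity.alpha": ("point", 1.0),
    "reciprocity.beta_base": ("uniform", 0.1, 0.5),
    "reciprocity.k_Lambda": ("uniform", 0.5, 2.0),
    "reciprocity.M_social": ("uniform", 0.2, 1.0),
    "reciprocity.I_align": ("uniform", 0.0, 0.9),
    "movement.M0": ("uniform", 0.2, 1.0),
    "movement.Gamma_max": ("uniform", 0.3, 1.2),
    "movement.omega": ("uniform", 2.0, 12.0),
    "movement.k_H": ("uniform", 1.0, 6.0),
    "routine.s_max": ("uniform", 0.5, 1.0),
    "routine.r_base": ("uniform", 1.0, 4.0),
    "routine.pi_precision": ("uniform", 1.0, 6.0),
    "routine.theta": ("uniform", 0.1, 0.5),
    "interest.I0": ("uniform", 0.1, 0.5),
    "interest.b_base": ("uniform", 0.4, 1.0),
    "interest.lambda_base": ("uniform", 0.02, 0.3),
    "interest.P_acc": ("uniform", 0.3, 0.95),
    "stimulus.sigma": ("uniform", 0.3, 1.2),
    "stimulus.delta_base": ("uniform", 0.0, 0.2),
    "stimulus.gaba_ratio": ("uniform", 0.5, 1.0),
    "stimulus.k_sens": ("point", 0.0),
}

#: Default EMA sampling design: six prompts per day with ±30 min jitter.
DEFAULT_DESIGN = {"prompts_per_day": 6, "jitter_minutes": 30.0,
                  "variables": ("R", "M", "S", "I", "P_total")}

_REQUIRED_SPEC_KEYS = tuple(DEFAULT_POPULATION_SPEC)


@dataclass
class EnvironmentTrack:
    """Exogenous environment: piecewise-linear entropy, exposure intervals,
    and a Poisson stream of routine-deviation events."""

    t: np.ndarray  # knot times (hours)
    H_env: np.ndarray  # entropy at knots (bits)
    exposures: list = field(default_factory=list)
    deviation_events: list = field(default_factory=list)
    horizon: float = 0.0


@dataclass
class EMADataset:
    """Noisy momentary observations with full provenance of the truth."""

    observations: pd.DataFrame  # subject, time, variable, value, tier
    design: dict
    noise: dict
    truth: dict  # profile dict, scenario/bundle metadata, seeds


def _draw(rng: np.random.Generator, spec):
    kind = spec[0]
    if kind == "point":
        return float(spec[1])
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "lognormal":
        return float(rng.lognormal(spec[1], spec[2]))
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_profile(rng_seed: int, population_spec: dict = None) -> IndividualProfile:
    """Draw a valid individual profile from the population specification.

    The spec maps dotted parameter paths to distribution tuples
    (``("point", v)``, ``("uniform", lo, hi)``, ``("lognormal", mu, sd)``)
    and must cover every required parameter; draws are reproducible by
    seed and always pass profile validation.
    """
    spec = DEFAULT_POPULATION_SPEC if population_spec is None else population_spec
    missing = [k for k in _REQUIRED_SPEC_KEYS if k not in spec]
    if missing:
        raise KeyError(f"population spec missing parameters: {missing}")
    rng = np.random.default_rng(rng_seed)
    # draw in fixed key order for reproducibility
    vals = {k: _draw(rng, spec[k]) for k in _REQUIRED_SPEC_KEYS}
    prof = IndividualProfile()
    prof.reciprocity = replace(
        prof.reciprocity,
        R0=vals["reciprocity.R0"], alpha=vals["reciprocity.alpha"],
        beta_base=vals["reciprocity.beta_base"],
        k_Lambda=vals["reciprocity.k_Lambda"],
        M_social=vals["reciprocity.M_social"],
        I_align=vals["reciprocity.I_align"])
    prof.movement = replace(
        prof.movement, M0=vals["movement.M0"],
        Gamma_max=vals["movement.Gamma_max"], omega=vals["movement.omega"],
        k_H=vals["movement.k_H"])
    prof.routines = [replace(
        prof.routines[0], s_max=vals["routine.s_max"],
        r_base=vals["routine.r_base"],
        pi_precision=vals["routine.pi_precision"], theta=vals["routine.theta"])]
    prof.interests = InterestParams(
        I0=vals["interest.I0"],
        interests=[InterestTerm(b_base=vals["interest.b_base"],
                                lambda_base=vals["interest.lambda_base"],
                                P_acc=vals["interest.P_acc"])])
    prof.stimuli = [replace(
        prof.stimuli[0], sigma=vals["stimulus.sigma"],
        delta_base=vals["stimulus.delta_base"],
        gaba_ratio=vals["stimulus.gaba_ratio"], k_sens=vals["stimulus.k_sens"])]
    problems = validate_profile(prof)
    if problems:  # population spec outside admissible ranges
        raise ValueError("sampled profile invalid: " + "; ".join(problems))
    return prof


def generate_environment(rng_seed: int, spec: dict = None) -> EnvironmentTrack:
    """Generate a stochastic environment track.

    Spec keys (all optional): ``horizon_hours``, ``entropy_base`` (bits),
    ``entropy_sd`` (random-walk innovation per knot), ``knot_hours``,
    ``exposure_rate`` (episodes/hour), ``exposure_mean_hours``,
    ``event_rate`` (deviation events/hour), ``event_magnitude`` (lo, hi).
    Entropy is a reflected (nonnegative) piecewise-linear random walk;
    deviation events form a seeded homogeneous Poisson stream.
    """
    spec = spec or {}
    horizon = float(spec.get("horizon_hours", 12.0))
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    base = float(spec.get("entropy_base", 3.0))
    sd = float(spec.get("entropy_sd", 0.5))
    knot = float(spec.get("knot_hours", 1.0))
    exp_rate = float(spec.get("exposure_rate", 0.3))
    exp_mean = float(spec.get("exposure_mean_hours", 1.0))
    ev_rate = float(spec.get("event_rate", 0.1))
    mag_lo, mag_hi = spec.get("event_magnitude", (0.2, 0.8))
    if min(exp_rate, ev_rate) < 0:
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    tk = np.arange(0.0, horizon + knot / 2, knot)
    H = np.abs(base + np.cumsum(rng.normal(0.0, sd, size=tk.size)) - 0.0)
    H[0] = base
    exposures = []
    if exp_rate > 0:
        n_exp = rng.poisson(exp_rate * horizon)
        starts = np.sort(rng.uniform(0, horizon, size=n_exp))
        for s in starts:
            dur = rng.exponential(exp_mean)
            exposures.append({"stimulus": "stimulus",
                              "t_start": float(s),
                              "t_end": float(min(s + dur, horizon))})
    events = []
    if ev_rate > 0:
        n_ev = rng.poisson(ev_rate * horizon)
        times = np.sort(rng.uniform(0, horizon, size=n_ev))
        mags = rng.uniform(mag_lo, mag_hi, size=n_ev)
        events = [{"t": float(ti), "routine": "routine", "magnitude": float(m)}
                  for ti, m in zip(times, mags)]
    return EnvironmentTrack(t=tk, H_env=H, exposures=exposures,
                            deviation_events=events, horizon=horizon)


def _prompt_times(design: dict, horizon: float, unit_minutes: float,
                  rng: np.random.Generator) -> np.ndarray:
    if "times" in design:
        times = np.asarray(design["times"], dtype=float)
    else:
        per_day = int(design.get("prompts_per_day", 6))
        jitter = float(design.get("jitter_minutes", 30.0)) / unit_minutes
        day = 24.0 * 60.0 / unit_minutes
        anchors = []
        d = 0.0
        while d < horizon:
            within = np.linspace(day / (2 * per_day), day - day / (2 * per_day), per_day)
            anchors.extend(d + within)
            d += day
        anchors = np.asarray([a for a in anchors if a <= horizon])
        times = anchors + rng.uniform(-jitter, jitter, size=anchors.size)
        times = np.sort(np.clip(times, 0.0, horizon))
    if np.any(times < 0) or np.any(times > horizon):
        raise ValueError("design times outside the truth horizon")
    return times


def observe(truth: TrajectoryBundle, design: dict = None, noise: dict = None,
            rng_seed: int = 0, subject: str = "s01") -> EMADataset:
    """Sample noisy EMA observations from a simulated trajectory.

    Values are the nearest-grid truth plus Gaussian noise, clipped to the
    variable's valid range; each row carries the variable's identifiability
    tier. Unknown variable names are rejected.
    """
    design = {**DEFAULT_DESIGN, **(design or {})}
    noise = noise or {"sd": 0.05}
    variables = list(design["variables"])
    for v in variables:
        if v not in truth.series or v not in VARIABLE_TIERS:
            raise KeyError(f"unknown observation variable {v!r}")
    rng = np.random.default_rng(rng_seed)
    unit_minutes = 1.0 if truth.metadata.get("time_unit") == "minute" else 60.0
    times = _prompt_times(design, float(truth.t[-1]), unit_minutes, rng)
    idx = np.searchsorted(truth.t, times)
    idx = np.clip(idx, 0, truth.t.size - 1)
    left = np.clip(idx - 1, 0, truth.t.size - 1)
    idx = np.where(np.abs(truth.t[left] - times) < np.abs(truth.t[idx] - times),
                   left, idx)  # nearest neighbour
    sd_map = noise.get("sd", 0.05)
    rows = []
    for v in variables:
        sd = sd_map.get(v, 0.0) if isinstance(sd_map, dict) else float(sd_map)
        vals = truth.series[v][idx] + rng.normal(0.0, sd, size=idx.size)
        lo, hi = VARIABLE_RANGES[v]
        vals = np.clip(vals, lo if lo is not None else -np.inf,
                       hi if hi is not None else np.inf)
        for ti, val in zip(times, vals):
            rows.append((subject, float(ti), v, float(val), VARIABLE_TIERS[v]))
    obs = pd.DataFrame(rows, columns=["subject", "time", "variable", "value", "tier"])
    obs = obs.sort_values(["time", "variable"], kind="stable").reset_index(drop=True)
    return EMADataset(observations=obs, design=design, noise=noise,
                      truth={"metadata": dict(truth.metadata), "seed": rng_seed})
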