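"""Social-communication submodels: reciprocity depletion, nonverbal
effectiveness, and sigmoid relationship development.

Reciprocity is a depletable resource: ``R(t) = alpha R0 exp(-∫ beta_eff dτ)``.
With constant loads the integrated hazard collapses to the constant-rate
exponential ``alpha R0 exp(-beta_eff t)``. Nonverbal effectiveness is a
weighted channel sum; relationship quality is a sum of logistic growth
curves whose asymptote and rate are modulated by social motivation, reward
salience and prediction-error variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .params import NonverbalChannel, ReciprocityParams, RelationshipParams

__all__ = [
    "SocialContextSignal",
    "effective_depletion_rate",
    "reciprocity_trajectory",
    "nonverbal_effectiveness",
    "relationship_quality",
]


@dataclass
class SocialContextSignal:
    """Time-indexed exogenous loads entering the depletion rate.

    Time grid in hours, strictly increasing; executive, instantaneous
    sensory, and predictive-processing loads are dimensionless and
    nonnegative.
    """

    t: np.ndarray
    E_exec: np.ndarray
    Lambda_s: np.ndarray
    Pi_load: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size == 0:
            raise ValueError("context grid must be non-empty")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("context grid must be strictly increasing")
        for name in ("E_exec", "Lambda_s", "Pi_load"):
            sig = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), self.t.shape).copy()
            if np.any(sig < 0):
                raise ValueError(f"context signal {name} must be nonnegative")
            setattr(self, name, sig)

    @classmethod
    def constant(cls, t, E_exec=0.0, Lambda_s=0.0, Pi_load=0.0) -> "SocialContextSignal":
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return cls(t=t, E_exec=np.full_like(t, E_exec),
                   Lambda_s=np.full_like(t, Lambda_s),
                   Pi_load=np.full_like(t, Pi_load))


def effective_depletion_rate(p: ReciprocityParams, E_exec, Lambda_s, Pi_load):
    """Effective depletion rate (hour⁻¹) under the given loads.

    ``beta_base * (1 + k_E E + k_Lambda Λ + k_P Π) / (1 + k_M M + k_Pr Pr + k_I I)``.
    Loads may be scalars or arrays; negative loads are rejected.
    """
    E = np.asarray(E_exec, dtype=float)
    L = np.asarray(Lambda_s, dtype=float)
    Pi = np.asarray(Pi_load, dtype=float)
    if np.any(E < 0) or np.any(L < 0) or np.any(Pi < 0):
        raise ValueError("loads must be nonnegative")
    num = 1.0 + p.k_E * E + p.k_Lambda * L + p.k_P * Pi
    den = 1.0 + p.k_M * p.M_social + p.k_Pr * p.Pr_env + p.k_I * p.I_align
    out = p.beta_base * num / den
    return out if out.ndim else float(out)


def reciprocity_trajectory(p: ReciprocityParams, context: SocialContextSignal) -> np.ndarray:
    """Reciprocity level R at every point of the context grid.

    Uses the integrated-hazard generalisation
    ``R(t) = alpha R0 exp(-∫₀ᵗ beta_eff(τ) dτ)`` accumulated by the
    trapezoid rule; with constant loads this equals the constant-rate
    closed form at machine precision.
    """
    beta = np.atleast_1d(effective_depletion_rate(p, context.E_exec, context.Lambda_s, context.Pi_load))
    hazard = cumulative_trapezoid(beta, context.t, initial=0.0)
    return p.alpha * p.R0 * np.exp(-hazard)


def nonverbal_effectiveness(channels) -> float:
    """Weighted multi-channel effectiveness ``N = Σ w_norm_i η_i x_i``."""
    if not channels:
        raise ValueError("channel list must be non-empty")
    return float(sum(c.w_norm * c.eta * c.x for c in channels))


def relationship_quality(relationships, t):
    """Total relationship quality C(t) and per-relationship components.

    Each relationship contributes ``a_j / (1 + exp(-k_j (t - t_j)))`` with
    ``a_j = a_max (M_soc/M_norm)`` and ``k_j = k_base (R_sal/R_norm)(1-P_var)``.
    ``t`` in months, scalar or array. A degenerate rate ``k_j = 0`` (e.g.
    P_var = 1) yields the analytic limit a_j / 2.

    Returns ``(C, components)`` where components has one row per
    relationship.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    comps = []
    for r in relationships:
        if r.M_norm == 0 or r.R_norm == 0:
            raise ValueError("normative levels M_norm and R_norm must be nonzero")
        a_j = r.a_max * (r.M_soc / r.M_norm)
        k_j = r.k_base * (r.R_sal / r.R_norm) * (1.0 - r.P_var)
        comps.append(a_j * expit(k_j * (t - r.t_infl)))
    components = np.array(comps)
    C = components.sum(axis=0) if comps else np.zeros_like(t)
    if t.ndim == 0:
        return float(C), components.reshape(len(comps))
    return C, components
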