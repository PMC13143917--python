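"""Normalised composite symptom index.

The seven raw components are mapped to the unit interval with recorded
bounds, oriented so that larger values always mean greater symptom
expression, and combined as a weighted sum A(t) ∈ [0, 1]. The index is a
descriptive summary: it is never fed back into the mechanistic equations,
and the acknowledged partial redundancy (cumulative sensory load appearing
both directly and through the depletion rate) is retained by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .params import COMPONENT_NAMES, CompositeWeights, WEIGHT_SUM_TOL

__all__ = [
    "ComponentVector",
    "CompositeResult",
    "normalise",
    "composite_index",
    "weights_from_alpha_beta",
    "DEFAULT_ORIENTATIONS",
]

log = logging.getLogger(__name__)

#: Orientation of each component in the severity index. Higher reciprocity,
#: nonverbal effectiveness and relationship quality indicate better
#: functioning, so those three are reflected (z <- 1 - z) before weighting.
DEFAULT_ORIENTATIONS = {
    "R": -1, "N": -1, "C": -1, "M": +1, "S": +1, "I": +1, "P_total": +1,
}


@dataclass
class ComponentVector:
    """Raw values of the seven components at one time point."""

    R: float
    N: float
    C: float
    M: float
    S: float
    I: float
    P_total: float
    t: float = 0.0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in COMPONENT_NAMES}


@dataclass
class CompositeResult:
    A: float
    z: dict
    contributions: dict
    metadata: dict = field(default_factory=dict)


def normalise(x, x_min: float, x_max: float):
    """Min-max map to [0, 1], clipping out-of-range values with a warning."""
    if x_max <= x_min:
        raise ValueError("normalisation requires x_max > x_min")
    z = (np.asarray(x, dtype=float) - x_min) / (x_max - x_min)
    if np.any(z < 0) or np.any(z > 1):
        log.warning("normalise: value outside [%s, %s] clipped", x_min, x_max)
        z = np.clip(z, 0.0, 1.0)
    return z if z.ndim else float(z)


def composite_index(v: ComponentVector, w: CompositeWeights,
                    orientations: dict = None) -> CompositeResult:
    """Weighted severity index ``A = Σ w_i z_i`` with per-component output.

    Components with negative orientation enter as ``1 - z``. Weights must
    be valid (nonnegative, summing to one).
    """
    problems = w.check()
    if problems:
        raise ValueError("invalid composite weights: " + "; ".join(problems))
    orientations = {**DEFAULT_ORIENTATIONS, **(orientations or {})}
    z = {}
    contributions = {}
    for name in COMPONENT_NAMES:
        lo, hi = w.bounds[name]
        zi = normalise(getattr(v, name), lo, hi)
        if orientations[name] < 0:
            zi = 1.0 - zi
        z[name] = zi
        contributions[name] = w.w[name] * zi
    A = float(sum(contributions.values()))
    meta = {
        "bounds": dict(w.bounds),
        "orientations": orientations,
        "note": "descriptive summary; not fed back into mechanistic equations",
    }
    return CompositeResult(A=A, z=z, contributions=contributions, metadata=meta)


def weights_from_alpha_beta(alphas, betas, bounds: dict = None) -> CompositeWeights:
    """Build unified weights from the two-domain (α₁..α₃, β₁..β₄) form.

    The mapping is positional: α weights attach to the social-communication
    components (R, N, C) and β weights to the restricted-repetitive
    components (M, S, I, P_total).
    """
    if len(alphas) != 3 or len(betas) != 4:
        raise ValueError("expected 3 alpha and 4 beta weights")
    w = dict(zip(COMPONENT_NAMES, list(alphas) + list(betas)))
    cw = CompositeWeights(w=w) if bounds is None else CompositeWeights(w=w, bounds=bounds)
    if abs(sum(w.values()) - 1.0) > WEIGHT_SUM_TOL:
        raise ValueError("alpha/beta weights must sum to 1")
    return cw
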