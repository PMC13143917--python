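"""Typed parameter structures, unit bookkeeping and profile validation.

Every symbol of the framework's notation table lives in exactly one field
here (or in an engine/synthetic container); ``symbol_concordance`` prints
the mapping. Validation never raises for scientific violations — it returns
human-readable messages so callers can aggregate them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

__all__ = [
    "ReciprocityParams",
    "NonverbalChannel",
    "RelationshipParams",
    "MovementParams",
    "RoutineParams",
    "InterestTerm",
    "InterestParams",
    "SensoryStimulusParams",
    "CompositeWeights",
    "ArousalParams",
    "RegulationParams",
    "IndividualProfile",
    "UnitTag",
    "dimensional_check",
    "validate_profile",
    "default_channels",
    "symbol_concordance",
    "COMPONENT_NAMES",
    "NONVERBAL_CHANNEL_NAMES",
    "TABLE_VALID_UNIT_ROWS",
    "WEIGHT_SUM_TOL",
]

#: Names of the seven composite components, in canonical order.
COMPONENT_NAMES = ("R", "N", "C", "M", "S", "I", "P_total")

#: The six canonical nonverbal channels.
NONVERBAL_CHANNEL_NAMES = (
    "gaze",
    "facial_expression",
    "gesture",
    "posture",
    "paralinguistics",
    "proxemics",
)

#: Tolerance for the composite-weight normalisation constraint.
WEIGHT_SUM_TOL = 1e-12


# ---------------------------------------------------------------------------
# Unit bookkeeping
# ---------------------------------------------------------------------------

# Base dimensions tracked for dimensional analysis. Radians are treated as
# dimensionless angles; "deviation" is the context-dependent routine scale.
_TOKEN_DIMS = {
    "dimensionless": {},
    "radians": {},
    "radian": {},
    "rad": {},
    "hour": {"hour": 1},
    "hours": {"hour": 1},
    "hour^-1": {"hour": -1},
    "minute": {"hour": 1},
    "minutes": {"hour": 1},
    "minute^-1": {"hour": -1},
    "month": {"month": 1},
    "months": {"month": 1},
    "month^-1": {"month": -1},
    "bits": {"bit": 1},
    "bit": {"bit": 1},
    "bits^-1": {"bit": -1},
    "deviation": {"deviation": 1},
    "deviation^-1": {"deviation": -1},
}


@dataclass(frozen=True)
class UnitTag:
    """A quantity name together with its unit expression.

    Unit expressions are whitespace/``*``/``·``-separated products of tokens
    from the closed vocabulary (``hour^-1``, ``bits``, ``radians``,
    ``months``, ``deviation``, ``dimensionless`` and inverses).
    """

    quantity: str
    unit: str


def _parse_unit(expr: str) -> dict:
    dims: dict = {}
    for tok in expr.replace("·", " ").replace("*", " ").split():
        try:
            d = _TOKEN_DIMS[tok.lower()]
        except KeyError:
            raise ValueError(f"unknown unit token: {tok!r}") from None
        for k, v in d.items():
            dims[k] = dims.get(k, 0) + v
    return {k: v for k, v in dims.items() if v != 0}


def dimensional_check(quantity_product: Iterable, strict: bool = False) -> bool:
    """True iff the product of unit expressions reduces to dimensionless.

    ``strict`` keeps hour and month as distinct time dimensions (so a
    ``hour^-1 × months`` product is flagged); the default permissive mode
    collapses all time units before reduction, mirroring how the loader
    converts mixed-unit scenario files.
    """
    total: dict = {}
    for item in quantity_product:
        expr = item.unit if isinstance(item, UnitTag) else str(item)
        for k, v in _parse_unit(expr).items():
            total[k] = total.get(k, 0) + v
    if not strict:
        total["hour"] = total.get("hour", 0) + total.pop("month", 0)
    return all(v == 0 for v in total.values())


#: Unit products that must reduce to dimensionless — one row per exponent,
#: sinusoid argument or ratio appearing in the framework's equations.
TABLE_VALID_UNIT_ROWS: tuple = (
    ("beta_eff * t", ["hour^-1", "hour"]),
    ("load sensitivities * loads", ["dimensionless", "dimensionless"]),
    ("omega * t", ["radians hour^-1", "hour"]),
    ("phi", ["radians"]),
    ("H_env / (H_env + k_H)", ["bits", "bits^-1"]),
    ("r_k * (|x - xbar| - theta)", ["deviation^-1", "deviation"]),
    ("lambda_l * t", ["month^-1", "months"]),
    ("sigma_s integrand * dt", ["dimensionless hour^-1", "hour"]),
    ("delta_s * t", ["hour^-1", "hour"]),
    ("sigma_s / delta_s", ["dimensionless hour^-1", "hour"]),
    ("weights * normalised components", ["dimensionless", "dimensionless"]),
)


# ---------------------------------------------------------------------------
# Per-submodel parameter types
# ---------------------------------------------------------------------------


@dataclass
class ReciprocityParams:
    """Social-reciprocity depletion parameters.

    ``R(t) = alpha * R0 * exp(-∫ beta_eff)`` with the effective rate
    ``beta_eff = beta_base * (1 + k_E E + k_Lambda Λ_s + k_P Π) /
    (1 + k_M M + k_Pr Pr + k_I I)``. Loads are dimensionless indices;
    ``beta_base`` is hour⁻¹.
    """

    R0: float = 0.85
    alpha: float = 1.0
    beta_base: float = 0.3
    k_E: float = 1.0
    k_Lambda: float = 1.0
    k_P: float = 1.0
    k_M: float = 1.0
    k_Pr: float = 1.0
    k_I: float = 1.0
    M_social: float = 0.6
    Pr_env: float = 0.0
    I_align: float = 0.3

    def check(self) -> list:
        msgs = []
        for name in ("k_E", "k_Lambda", "k_P", "k_M", "k_Pr", "k_I"):
            if getattr(self, name) < 0:
                msgs.append(f"reciprocity: sensitivity {name} must be >= 0")
        if self.beta_base < 0:
            msgs.append("reciprocity: beta_base must be >= 0")
        if not (0.0 <= self.alpha * self.R0 <= 1.0):
            msgs.append("reciprocity: alpha*R0 must lie in [0, 1]")
        for name in ("M_social", "Pr_env", "I_align"):
            if getattr(self, name) < 0:
                msgs.append(f"reciprocity: protective level {name} must be >= 0")
        return msgs


@dataclass
class NonverbalChannel:
    """One nonverbal channel with normative weight and processing efficiency.

    The channel's effective weight is ``w_norm * eta``.
    """

    name: str
    w_norm: float
    eta: float = 1.0
    x: float = 1.0

    def check(self) -> list:
        msgs = []
        if self.w_norm < 0:
            msgs.append(f"channel {self.name}: w_norm must be >= 0")
        if not (0.0 <= self.eta <= 1.0):
            msgs.append(f"channel {self.name}: eta must lie in [0, 1]")
        return msgs


def default_channels() -> list:
    """The six canonical channels with normative weights summing to one.

    The normative weights are package defaults (gaze and facial expression
    weighted highest, consistent with their early developmental salience);
    any channel list is accepted by the effectiveness operation.
    """
    weights = {
        "gaze": 0.25,
        "facial_expression": 0.25,
        "gesture": 0.15,
        "posture": 0.10,
        "paralinguistics": 0.15,
        "proxemics": 0.10,
    }
    return [NonverbalChannel(name=n, w_norm=weights[n]) for n in NONVERBAL_CHANNEL_NAMES]


@dataclass
class RelationshipParams:
    """Sigmoid relationship-development parameters (slow tier, months).

    Asymptote ``a = a_max * M_soc / M_norm``; growth rate
    ``k = k_base * (R_sal / R_norm) * (1 - P_var)``.
    """

    a_max: float = 1.0
    M_soc: float = 1.0
    M_norm: float = 1.0
    k_base: float = 0.5
    R_sal: float = 1.0
    R_norm: float = 1.0
    P_var: float = 0.2
    t_infl: float = 6.0

    def check(self) -> list:
        msgs = []
        if not (0.0 <= self.P_var <= 1.0):
            msgs.append("relationship: P_var must lie in [0, 1]")
        if self.M_norm <= 0 or self.R_norm <= 0:
            msgs.append("relationship: norms M_norm and R_norm must be strictly positive")
        if self.a_max <= 0:
            msgs.append("relationship: a_max must be > 0")
        if self.k_base <= 0:
            msgs.append("relationship: k_base must be > 0")
        return msgs


@dataclass
class MovementParams:
    """Entropy-modulated oscillatory stereotypy parameters.

    ``M(t) = M0 + Gamma_eff * sin(omega t + phi)`` with
    ``Gamma_eff = Gamma_max * H/(H + k_H) / (1 + k_engage E + k_alt Φ)``.
    ``k_engage``/``k_alt`` are this submodel's engagement and
    alternative-behaviour sensitivities (namespaced to avoid colliding with
    the reciprocity submodel's executive-load sensitivity).
    """

    M0: float = 0.5
    Gamma_max: float = 1.0
    omega: float = 2 * math.pi  # radians per hour
    phi: float = 0.0
    k_H: float = 2.0  # bits
    k_engage: float = 1.0
    k_alt: float = 1.0

    def check(self) -> list:
        msgs = []
        if self.k_H <= 0:
            msgs.append("movement: entropy half-saturation k_H must be positive")
        if self.Gamma_max < 0:
            msgs.append("movement: Gamma_max must be >= 0")
        if self.M0 < 0:
            msgs.append("movement: M0 must be >= 0")
        for name in ("k_engage", "k_alt"):
            if getattr(self, name) < 0:
                msgs.append(f"movement: {name} must be >= 0")
        return msgs


@dataclass
class RoutineParams:
    """Precision-weighted sameness-distress parameters for one routine.

    Distress follows ``s_max / (1 + exp(-r (|x - x_expected| - theta)))``
    with steepness ``r = r_base * pi_precision``.
    """

    label: str = "routine"
    s_max: float = 0.9
    r_base: float = 2.0
    pi_precision: float = 1.0
    theta: float = 0.3
    x_expected: float = 0.0

    def check(self) -> list:
        msgs = []
        if self.s_max < 0:
            msgs.append(f"routine {self.label}: s_max must be >= 0")
        if self.r_base <= 0:
            msgs.append(f"routine {self.label}: r_base must be > 0")
        if self.theta < 0:
            msgs.append(f"routine {self.label}: theta must be >= 0")
        if self.pi_precision < 0:
            msgs.append(f"routine {self.label}: pi_precision must be >= 0")
        return msgs


@dataclass
class InterestTerm:
    """One restricted interest: ``b * exp(-lambda * Δt)`` since acquisition.

    ``b = b_base * R_int / R_norm``; ``lambda = lambda_base * (1 - P_acc)``.
    """

    b_base: float = 0.8
    R_int: float = 1.0
    R_norm: float = 1.0
    lambda_base: float = 0.1  # month^-1
    P_acc: float = 0.5
    t_acquired: float = 0.0  # months

    def check(self, idx: int = 0) -> list:
        msgs = []
        if not (0.0 <= self.P_acc <= 1.0):
            msgs.append(f"interest {idx}: P_acc must lie in [0, 1]")
        if self.lambda_base < 0:
            msgs.append(f"interest {idx}: lambda_base must be >= 0")
        if self.b_base < 0:
            msgs.append(f"interest {idx}: b_base must be >= 0")
        if self.R_norm <= 0 or self.R_int <= 0:
            msgs.append(f"interest {idx}: reward values must be > 0")
        return msgs


@dataclass
class InterestParams:
    """Restricted-interest engagement: persistent floor plus decaying terms."""

    I0: float = 0.2
    interests: list = field(default_factory=lambda: [InterestTerm()])

    def check(self) -> list:
        msgs = [] if self.I0 >= 0 else ["interests: I0 must be >= 0"]
        for i, term in enumerate(self.interests):
            msgs.extend(term.check(i))
        return msgs


@dataclass
class SensoryStimulusParams:
    """Per-stimulus sensory sensitivity and habituation parameters.

    The habituation/sensitisation rate is
    ``delta = delta_base * gaba_ratio - k_sens * Xi`` and may go negative
    (sensitisation) under high arousal.
    """

    label: str = "stimulus"
    sigma: float = 0.8
    delta_base: float = 0.1
    gaba_ratio: float = 1.0
    k_sens: float = 0.0

    def check(self) -> list:
        msgs = []
        if self.sigma < 0:
            msgs.append(f"stimulus {self.label}: sigma must be >= 0")
        if self.gaba_ratio < 0:
            msgs.append(f"stimulus {self.label}: gaba_ratio must be >= 0")
        if self.k_sens < 0:
            msgs.append(f"stimulus {self.label}: k_sens must be >= 0")
        return msgs


@dataclass
class CompositeWeights:
    """Weights and normalisation bounds for the seven-component index."""

    w: dict = field(
        default_factory=lambda: {name: 1.0 / 7.0 for name in COMPONENT_NAMES}
    )
    bounds: dict = field(
        default_factory=lambda: {
            "R": (0.0, 1.0),
            "N": (0.0, 1.0),
            "C": (0.0, 3.0),
            "M": (-1.0, 2.0),
            "S": (0.0, 1.0),
            "I": (0.0, 1.5),
            "P_total": (0.0, 100.0),
        }
    )

    def renormalised(self) -> "CompositeWeights":
        total = sum(self.w.values())
        if total <= 0:
            raise ValueError("composite weights must have a positive sum")
        return replace(self, w={k: v / total for k, v in self.w.items()})

    def check(self) -> list:
        msgs = []
        if set(self.w) != set(COMPONENT_NAMES):
            msgs.append("composite: weights must name exactly the seven components")
            return msgs
        if any(v < 0 for v in self.w.values()):
            msgs.append("composite: all weights must be >= 0")
        if abs(sum(self.w.values()) - 1.0) > WEIGHT_SUM_TOL:
            msgs.append("composite: weights must sum to 1 (weight normalisation)")
        for name, (lo, hi) in self.bounds.items():
            if hi <= lo:
                msgs.append(f"composite: bounds for {name} must satisfy x_max > x_min")
        return msgs


@dataclass
class ArousalParams:
    """Coefficients of the lagged arousal recursion used by the engine.

    ``Xi[n+1] = max(0, decay * Xi[n] + gain_load * Lambda_s + gain_distress * S)``
    per reference fast step (one minute).
    """

    decay: float = 0.8
    gain_load: float = 0.5
    gain_distress: float = 0.5
    xi0: float = 0.0

    def check(self) -> list:
        msgs = []
        if not (0.0 <= self.decay <= 1.0):
            msgs.append("arousal: decay must lie in [0, 1]")
        if self.gain_load < 0 or self.gain_distress < 0 or self.xi0 < 0:
            msgs.append("arousal: gains and initial level must be >= 0")
        return msgs


@dataclass
class RegulationParams:
    """Regulatory capacity: withdrawal threshold and sensory-social coupling."""

    threshold: float = 70.0  # P_total level triggering withdrawal
    coupling_capacity: float = 30.0  # half-saturation of P_total -> Lambda_s
    clearance_rate: float = 0.0  # optional first-order P_total decay (per hour)

    def check(self) -> list:
        msgs = []
        if self.coupling_capacity <= 0:
            msgs.append("regulation: coupling_capacity must be > 0")
        if self.clearance_rate < 0:
            msgs.append("regulation: clearance_rate must be >= 0")
        return msgs


@dataclass
class IndividualProfile:
    """The full per-person parameter set across all seven submodels."""

    reciprocity: ReciprocityParams = field(default_factory=ReciprocityParams)
    channels: list = field(default_factory=default_channels)
    relationships: list = field(default_factory=lambda: [RelationshipParams()])
    movement: MovementParams = field(default_factory=MovementParams)
    routines: list = field(default_factory=lambda: [RoutineParams()])
    interests: InterestParams = field(default_factory=InterestParams)
    stimuli: list = field(default_factory=lambda: [SensoryStimulusParams()])
    composite: CompositeWeights = field(default_factory=CompositeWeights)
    arousal: ArousalParams = field(default_factory=ArousalParams)
    regulation: RegulationParams = field(default_factory=RegulationParams)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IndividualProfile":
        kw = {}
        if "reciprocity" in d:
            kw["reciprocity"] = ReciprocityParams(**d["reciprocity"])
        if "channels" in d:
            kw["channels"] = [NonverbalChannel(**c) for c in d["channels"]]
        if "relationships" in d:
            kw["relationships"] = [RelationshipParams(**r) for r in d["relationships"]]
        if "movement" in d:
            kw["movement"] = MovementParams(**d["movement"])
        if "routines" in d:
            kw["routines"] = [RoutineParams(**r) for r in d["routines"]]
        if "interests" in d:
            terms = [InterestTerm(**t) for t in d["interests"].get("interests", [])]
            kw["interests"] = InterestParams(I0=d["interests"].get("I0", 0.0), interests=terms)
        if "stimuli" in d:
            kw["stimuli"] = [SensoryStimulusParams(**s) for s in d["stimuli"]]
        if "composite" in d:
            c = dict(d["composite"])
            if "bounds" in c:
                c["bounds"] = {k: tuple(v) for k, v in c["bounds"].items()}
            kw["composite"] = CompositeWeights(**c)
        if "arousal" in d:
            kw["arousal"] = ArousalParams(**d["arousal"])
        if "regulation" in d:
            kw["regulation"] = RegulationParams(**d["regulation"])
        return cls(**kw)


def validate_profile(profile: IndividualProfile) -> list:
    """Collect every invariant violation in ``profile``.

    Returns an empty list iff all type invariants and dimensional rules
    hold; never raises for scientific violations.
    """
    msgs = []
    msgs.extend(profile.reciprocity.check())
    for ch in profile.channels:
        msgs.extend(ch.check())
    for rel in profile.relationships:
        msgs.extend(rel.check())
    msgs.extend(profile.movement.check())
    for r in profile.routines:
        msgs.extend(r.check())
    msgs.extend(profile.interests.check())
    for s in profile.stimuli:
        msgs.extend(s.check())
    msgs.extend(profile.composite.check())
    msgs.extend(profile.arousal.check())
    msgs.extend(profile.regulation.check())
    # dimensional sanity of the model's own unit table
    for label, row in TABLE_VALID_UNIT_ROWS:
        if not dimensional_check(row):
            msgs.append(f"dimensional analysis: product '{label}' is not dimensionless")
    return msgs


# ---------------------------------------------------------------------------
# Symbol concordance
# ---------------------------------------------------------------------------

#: Printed-symbol -> package-field concordance. Name collisions in the source
#: notation (the reciprocity submodel's executive-load sensitivity vs the
#: movement submodel's engagement sensitivity; the instantaneous sensory load
#: vs per-routine distress vs cumulative load) are resolved by namespaced
#: field names.
_SYMBOL_MAP = {
    "R(t)": "domain_a.reciprocity_trajectory (output)",
    "R_0": "ReciprocityParams.R0",
    "alpha": "ReciprocityParams.alpha",
    "beta_base": "ReciprocityParams.beta_base",
    "beta_eff": "domain_a.effective_depletion_rate (output)",
    "k_E (reciprocity)": "ReciprocityParams.k_E",
    "k_Lambda": "ReciprocityParams.k_Lambda",
    "k_P": "ReciprocityParams.k_P",
    "k_M": "ReciprocityParams.k_M",
    "k_Pr": "ReciprocityParams.k_Pr",
    "k_I": "ReciprocityParams.k_I",
    "E(t) (executive load)": "SocialContextSignal.E_exec",
    "M (social motivation)": "ReciprocityParams.M_social",
    "Pr (predictability)": "ReciprocityParams.Pr_env",
    "I (interest alignment)": "ReciprocityParams.I_align",
    "Pi_load(t)": "SocialContextSignal.Pi_load",
    "Lambda_s(t)": "SocialContextSignal.Lambda_s",
    "N": "domain_a.nonverbal_effectiveness (output)",
    "x_i": "NonverbalChannel.x",
    "w_i": "NonverbalChannel.w_norm * NonverbalChannel.eta (derived)",
    "w_norm,i": "NonverbalChannel.w_norm",
    "eta_i": "NonverbalChannel.eta",
    "C(t)": "domain_a.relationship_quality (output)",
    "a_j": "RelationshipParams.a_max * M_soc/M_norm (derived)",
    "a_max,j": "RelationshipParams.a_max",
    "k_j": "RelationshipParams.k_base * (R_sal/R_norm)*(1-P_var) (derived)",
    "k_base,j": "RelationshipParams.k_base",
    "t_j": "RelationshipParams.t_infl",
    "M_soc": "RelationshipParams.M_soc",
    "M_norm": "RelationshipParams.M_norm",
    "R_sal": "RelationshipParams.R_sal",
    "R_norm (relationships)": "RelationshipParams.R_norm",
    "P_var": "RelationshipParams.P_var",
    "M(t)": "domain_b.movement_intensity (output)",
    "M_0": "MovementParams.M0",
    "Gamma_eff": "domain_b.effective_amplitude (output)",
    "Gamma_max": "MovementParams.Gamma_max",
    "omega": "MovementParams.omega",
    "phi": "MovementParams.phi",
    "H_env(t)": "EntropySignal.H_env",
    "k_H": "MovementParams.k_H",
    "E(t) (engagement)": "EntropySignal.E_engage",
    "Phi_alt(t)": "EntropySignal.Phi_alt",
    "k_E (movement engagement)": "MovementParams.k_engage",
    "k_Phi": "MovementParams.k_alt",
    "S_k": "domain_b.deviation_distress (output)",
    "S": "domain_b.total_sameness (output)",
    "s_k": "RoutineParams.s_max",
    "r_k": "RoutineParams.r_base * pi_precision (derived)",
    "r_base,k": "RoutineParams.r_base",
    "pi_k": "RoutineParams.pi_precision",
    "theta_k": "RoutineParams.theta",
    "x_k": "engine deviation event state (current routine state)",
    "xbar_k": "RoutineParams.x_expected",
    "I(t)": "domain_b.interest_engagement (output)",
    "I_0": "InterestParams.I0",
    "g": "len(InterestParams.interests)",
    "b_l": "InterestTerm.b_base * R_int/R_norm (derived)",
    "b_base,l": "InterestTerm.b_base",
    "lambda_l": "InterestTerm.lambda_base * (1 - P_acc) (derived)",
    "lambda_base,l": "InterestTerm.lambda_base",
    "R_int,l": "InterestTerm.R_int",
    "R_norm (interests)": "InterestTerm.R_norm",
    "P_acc,l": "InterestTerm.P_acc",
    "P(s)": "domain_b.cumulative_impact (output)",
    "P_total": "domain_b.total_sensory_load (output)",
    "T": "exposure duration argument of cumulative_impact",
    "sigma_s": "SensoryStimulusParams.sigma",
    "delta_s": "domain_b.habituation_rate (output)",
    "delta_base,s": "SensoryStimulusParams.delta_base",
    "GABA_func/GABA_norm": "SensoryStimulusParams.gaba_ratio",
    "k_sens": "SensoryStimulusParams.k_sens",
    "Xi(t)": "ArousalSignal.Xi / engine arousal state",
    "A(t)": "composite.composite_index (output)",
    "alpha_1..alpha_3, beta_1..beta_4": "CompositeWeights.w (unified w_1..w_7)",
    "z_i(t)": "composite.normalise (output)",
}


def symbol_concordance() -> dict:
    """Mapping from each printed model symbol to the field or operation
    that houses it. Emitted verbatim into the documentation."""
    return dict(_SYMBOL_MAP)
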