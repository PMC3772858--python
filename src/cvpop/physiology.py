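"""Algebraic relations of the lumped cardiovascular model.

The model couples four submodels -- blood-flow autoregulation, the
baroreceptor reflex, renal control of fluid volume, and cardiac
integration (Guyton's venous-return / cardiac-output equilibrium) --
through a handful of saturating response curves and linear couplings.

Every response curve is a logistic sigmoid

    y(x) = low + (high - low) / (1 + exp(-m * (x - S) / w))

with half-maximal response at the set point ``S``, dimensionless
sensitivity ``m`` and an input-scale width ``w``.  Sensitivities and set
points are tabulated best-fit values; the widths are transcription
constants of this implementation, identified once from the model's
published operating point (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

__all__ = [
    "SigmoidSpec",
    "ModelParameters",
    "sigmoid",
    "sigmoid_inverse",
    "sigmoid_slope",
    "effective_tpr",
    "map_from_flow",
    "afferent_signal",
    "sympathetic_multiplier",
    "urine_output",
    "blood_volume",
    "blood_volume_inverse",
    "blood_volume_slope",
    "mcfp",
    "elastance",
    "rvr",
    "venous_return",
    "starling_co",
    "starling_rap",
    "load_parameters",
    "save_parameters",
]


@dataclass(frozen=True)
class SigmoidSpec:
    """A bounded monotone response curve.

    Attributes
    ----------
    low, high:
        Asymptotic floor and ceiling of the response (same units).
    sensitivity:
        Dimensionless slope factor ``m``.
    setpoint:
        Input value of half-maximal response.
    width:
        Input-units scale over which the transition unfolds.
    """

    low: float
    high: float
    sensitivity: float
    setpoint: float
    width: float

    def validate(self) -> "SigmoidSpec":
        if not self.high > self.low:
            raise ConfigurationError(
                f"sigmoid 'high' ({self.high}) must exceed 'low' ({self.low})"
            )
        if not self.sensitivity > 0:
            raise ConfigurationError(
                f"sigmoid 'sensitivity' must be positive, got {self.sensitivity}"
            )
        if not self.width > 0:
            raise ConfigurationError(f"sigmoid 'width' must be positive, got {self.width}")
        return self


def sigmoid(x, spec: SigmoidSpec):
    """Evaluate the logistic response curve; bounded in (low, high)."""
    spec.validate()
    z = spec.sensitivity * (np.asarray(x, dtype=float) - spec.setpoint) / spec.width
    z = np.clip(z, -500.0, 500.0)
    out = spec.low + (spec.high - spec.low) / (1.0 + np.exp(-z))
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def sigmoid_inverse(y, spec: SigmoidSpec):
    """Input value at which the curve attains ``y`` (low < y < high)."""
    spec.validate()
    y = np.asarray(y, dtype=float)
    f = (y - spec.low) / (spec.high - spec.low)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise DomainError(f"sigmoid_inverse: value outside open range ({spec.low}, {spec.high})")
    out = spec.setpoint + spec.width / spec.sensitivity * np.log(f / (1.0 - f))
    return float(out) if out.ndim == 0 else out


def sigmoid_slope(x, spec: SigmoidSpec):
    """Analytic derivative dy/dx of the response curve."""
    y = sigmoid(x, spec)
    f = (y - spec.low) / (spec.high - spec.low)
    return (spec.high - spec.low) * f * (1.0 - f) * spec.sensitivity / spec.width


# Parameter names as printed in the coefficient tables, with units.
_TABLE_FIELDS = {
    # autoregulation
    "A_auto": "maximal autoregulation resistance (mmHg min/mL)",
    "m_auto": "sensitivity of autoregulation",
    "S_auto": "set point of autoregulation (mL/min)",
    "k_auto": "delay constant of autoregulation (1/min)",
    # baroreceptor reflex
    "k_adapt": "delay constant of baroreceptor adaptation (1/min)",
    "A_aff": "maximal afferent outflow",
    "m_aff": "sensitivity of afferent response",
    "S_aff": "set point of afferent response (mmHg)",
    "sna_max": "maximum increase in sympathetic outflow",
    "sna_min": "minimal sympathetic outflow",
    "m_sna": "sensitivity of sympathetic outflow",
    "S_sna": "set point of sympathetic response to afferent activity",
    # renal / fluid homeostasis
    "intake": "water intake (mL/min)",
    "k_uo": "slope constant in the urine equation (1/mmHg)",
    "BV_max": "maximal blood volume (mL)",
    "m_BV": "sensitivity of blood volume to ECFV",
    "S_BV": "set point of the BV-ECFV relationship (mL)",
    # cardiac integration
    "V0": "unstressed blood volume (mL)",
    "r_lin": "linear term of the TPR -> RVR coupling",
    "r_const": "constant term of the TPR -> RVR coupling (mmHg min/mL)",
    "CO_max": "maximum cardiac output (mL/min)",
    "m_starling": "sensitivity of the Starling curve",
    "S_starling": "set point of the Starling curve (mmHg)",
    "e_lin": "linear part of the elastance response to SNA (mmHg/mL)",
    "e_const": "constant part of the elastance response to SNA (mmHg/mL)",
}

# Transcription constants (not tabulated in the source model; see docs/methods.md).
_TRANSCRIPTION_FIELDS = {
    "w_aff": "width of the afferent response to the pressure deficit (mmHg)",
    "w_sna": "width of the sympathetic response to afferent activity",
    "w_starling": "width of the Starling curve (mmHg)",
    "w_BV": "width of the BV-ECFV partition (mL)",
    "p_vc": "venous collapse pressure: RAP floor of the venous-return curve (mmHg)",
    "map_baseline": "normotensive arterial pressure anchoring the renal set point (mmHg)",
}


@dataclass
class ModelParameters:
    """Best-fit coefficients of the four submodels: one virtual patient's identity.

    Field names mirror the published coefficient tables (``A_auto``,
    ``k_adapt``, ``BV_max``, ...).  ``p_renal`` is the renal pressure set
    point; it is not tabulated and is back-solved once so that urine
    output equals intake at the normotensive baseline (``resolve``).
    """

    # Table: autoregulation
    A_auto: float = 0.0453
    m_auto: float = 10.86
    S_auto: float = 5126.0
    k_auto: float = 0.00048
    # Table: baroreceptor reflex
    k_adapt: float = 0.0007
    A_aff: float = 2.067
    m_aff: float = 3.787
    S_aff: float = 39.235
    sna_max: float = 1.0041
    sna_min: float = 0.9333
    m_sna: float = 3.6046
    S_sna: float = 0.5349
    # Table: fluid homeostasis
    intake: float = 1.0
    k_uo: float = 0.05
    BV_max: float = 7900.0
    m_BV: float = 3.58
    S_BV: float = 15570.0
    # Table: cardiac integration
    V0: float = 3500.0
    r_lin: float = 0.0296
    r_const: float = 0.000839
    CO_max: float = 15230.0
    m_starling: float = 1.876
    S_starling: float = 2.85
    e_lin: float = 0.002408
    e_const: float = 0.004543
    # transcription constants
    w_aff: float = 90.0
    w_sna: float = 0.3
    w_starling: float = 10.0
    w_BV: float = 9000.0
    p_vc: float = -2.2
    map_baseline: float = 100.0
    # derived (resolved at load time)
    p_renal: float = field(default=None, repr=False)  # type: ignore[assignment]

    # -- response-curve specs ------------------------------------------------

    def autoregulation_spec(self) -> SigmoidSpec:
        """Delayed resistance target as a function of cardiac output."""
        return SigmoidSpec(0.0, self.A_auto, self.m_auto, self.S_auto, self.S_auto)

    def afferent_spec(self) -> SigmoidSpec:
        """Afferent activity as a function of the pressure deficit (p_adapt - MAP)."""
        return SigmoidSpec(0.0, self.A_aff, self.m_aff, self.S_aff, self.w_aff)

    def sna_spec(self) -> SigmoidSpec:
        """Sympathetic multiplier as a function of afferent activity."""
        return SigmoidSpec(
            self.sna_min, self.sna_min + self.sna_max, self.m_sna, self.S_sna, self.w_sna
        )

    def bv_spec(self) -> SigmoidSpec:
        """Blood volume as a function of extracellular fluid volume."""
        return SigmoidSpec(0.0, self.BV_max, self.m_BV, self.S_BV, self.w_BV)

    def starling_spec(self) -> SigmoidSpec:
        """Cardiac output as a function of right atrial pressure."""
        return SigmoidSpec(0.0, self.CO_max, self.m_starling, self.S_starling, self.w_starling)

    # -- lifecycle ------------------------------------------------------------

    def validate(self) -> "ModelParameters":
        for name in _TABLE_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ConfigurationError(f"parameter '{name}' must be a finite number, got {v!r}")
        for name in _TABLE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter '{name}' must be strictly positive")
        if not 0 < self.sna_min < 1 < self.sna_min + self.sna_max:
            raise ConfigurationError(
                "SNA multiplier range must satisfy 0 < sna_min < 1 < sna_min + sna_max"
            )
        if not self.V0 < self.BV_max:
            raise ConfigurationError("unstressed volume V0 must be below BV_max")
        if self.p_vc >= 0:
            raise ConfigurationError("venous collapse pressure p_vc must be negative")
        for spec in (
            self.autoregulation_spec(),
            self.afferent_spec(),
            self.sna_spec(),
            self.bv_spec(),
            self.starling_spec(),
        ):
            spec.validate()
        return self

    def resolve(self) -> "ModelParameters":
        """Back-solve the renal pressure set point and return self.

        The kidney is an infinite-gain controller: at steady state urine
        output equals intake, which pins MAP to the SNA-modulated renal
        set point.  The set point scale is chosen once so the best-fit
        baseline sits at ``map_baseline`` (normotensive, 100 mmHg).
        """
        self.validate()
        sna0 = sympathetic_multiplier(afferent_signal(self.map_baseline, self.map_baseline, self), self)
        self.p_renal = self.map_baseline / sna0
        return self

    def replace(self, **changes) -> "ModelParameters":
        new = replace(self, **changes)
        new.p_renal = self.p_renal
        return new

    def as_dict(self, include_transcription: bool = True) -> dict:
        names = list(_TABLE_FIELDS) + (list(_TRANSCRIPTION_FIELDS) if include_transcription else [])
        return {n: getattr(self, n) for n in names}


def default_parameters() -> ModelParameters:
    """The best-fit virtual patient, with the renal set point resolved."""
    return ModelParameters().resolve()


def load_parameters(path) -> ModelParameters:
    """Read a flat key/value parameter file (YAML or JSON).

    Keys mirror the coefficient-table names exactly.  Unknown keys are
    rejected with a message naming them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {path} must hold a flat mapping")
    known = set(_TABLE_FIELDS) | set(_TRANSCRIPTION_FIELDS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"unknown parameter keys: {', '.join(unknown)}")
    params = ModelParameters(**raw)
    return params.resolve()


def save_parameters(params: ModelParameters, path) -> None:
    data = params.as_dict()
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


# -- operations ---------------------------------------------------------------


def effective_tpr(r_auto: float, sna: float) -> float:
    """Total peripheral resistance: the autoregulated resistance scaled by SNA."""
    if r_auto <= 0 or sna <= 0:
        raise DomainError("effective_tpr requires positive resistance and SNA multiplier")
    return r_auto * sna


def map_from_flow(co: float, tpr: float) -> float:
    """Mean arterial pressure as the product of cardiac output and TPR."""
    if co < 0:
        raise DomainError("cardiac output must be non-negative")
    if tpr <= 0:
        raise DomainError("TPR must be positive")
    return co * tpr


def afferent_signal(map_mmHg: float, p_adapt: float, params: ModelParameters) -> float:
    """Baroreceptor afferent activity.

    The afferent arm senses the deficit of current pressure below the
    slowly adapting reference: activity rises as pressure falls, so the
    efferent multiplier below increases in hypotension.
    """
    return sigmoid(p_adapt - map_mmHg, params.afferent_spec())


def sympathetic_multiplier(afferent: float, params: ModelParameters) -> float:
    """Single efferent multiplier acting on resistance, kidney and compliance."""
    return sigmoid(afferent, params.sna_spec())


def urine_output(map_mmHg: float, sna: float, params: ModelParameters) -> float:
    """Pressure diuresis, exponential in MAP and suppressed by sympathetic tone.

    Equals intake exactly when MAP sits at the SNA-modulated renal set
    point ``p_renal * sna`` -- the infinite-gain closure that pins
    long-term arterial pressure.
    """
    if map_mmHg < 0:
        raise DomainError("MAP must be non-negative")
    if params.p_renal is None:
        raise ConfigurationError("parameters not resolved: call resolve() first")
    z = np.clip(params.k_uo * (map_mmHg - params.p_renal * sna), -500, 500)
    return params.intake * float(np.exp(z))


def blood_volume(ecfv: float, params: ModelParameters) -> float:
    """Sigmoidal partition of extracellular fluid into the vascular compartment."""
    if np.any(np.asarray(ecfv) <= 0):
        raise DomainError("ECFV must be positive")
    return sigmoid(ecfv, params.bv_spec())


def blood_volume_inverse(bv: float, params: ModelParameters) -> float:
    return sigmoid_inverse(bv, params.bv_spec())


def blood_volume_slope(ecfv: float, params: ModelParameters) -> float:
    """d(BV)/d(ECFV); strictly below 1, so blood bears only part of a fluid deficit."""
    return sigmoid_slope(ecfv, params.bv_spec())


def elastance(sna: float, params: ModelParameters) -> float:
    """Whole-circulation elastance, stiffened by sympathetic tone (affine in SNA)."""
    return params.e_lin * sna + params.e_const


def mcfp(bv: float, sna: float, params: ModelParameters):
    """Mean circulatory filling pressure from the stressed volume.

    Returns ``(mcfp, stressed_volume, elastance)``.  Stressed volume is
    blood volume above the unstressed volume V0; when it is exhausted
    MCFP clamps at zero (the caller flags the collapse).
    """
    if bv <= 0:
        raise DomainError("blood volume must be positive")
    sv = bv - params.V0
    e = elastance(sna, params)
    return max(0.0, sv * e), sv, e


def rvr(tpr: float, params: ModelParameters) -> float:
    """Resistance to venous return, linear in TPR (about half of it is fixed)."""
    if tpr <= 0:
        raise DomainError("TPR must be positive")
    return params.r_lin * tpr + params.r_const


def venous_return(mcfp_mmHg: float, rap: float, rvr_value: float, p_vc: float = -2.2) -> float:
    """Guyton venous return: flow down the MCFP-to-RAP gradient.

    MCFP is the RAP-intercept of the venous-return line with slope
    -1/RVR.  Venous return is bounded above: once RAP falls to the
    venous collapse pressure ``p_vc`` the great veins collapse and the
    curve plateaus at (MCFP - p_vc)/RVR.
    """
    if rvr_value <= 0:
        raise DomainError("RVR must be positive")
    return (mcfp_mmHg - max(rap, p_vc)) / rvr_value


def starling_co(rap: float, params: ModelParameters) -> float:
    """Cardiac output on the Starling curve, saturating at CO_max."""
    return sigmoid(rap, params.starling_spec())


def starling_rap(co: float, params: ModelParameters) -> float:
    """Right atrial pressure required for a given cardiac output (Starling inverse)."""
    return sigmoid_inverse(co, params.starling_spec())
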