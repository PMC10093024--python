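"""Henssge double-exponential model of post-mortem rectal cooling.

The model describes the fall of rectal temperature ``Tr`` after death as a
normalized cooling fraction

    Q(t) = (Tr - Ta) / (T0 - Ta)

where ``Ta`` is the (constant) ambient temperature and ``T0 = 37.2`` degC the
rectal temperature assumed at death.  Q is a linear combination of two
exponentials whose amplitude ``A`` depends on the ambient-temperature regime
and whose rate ``B`` (per hour, negative) depends on the effective body
weight, i.e. body weight times a dimensionless correction factor encoding
clothing and environment:

    Ta <= 23.2 degC:  Q(t) = 1.25 exp(B t) - 0.25 exp(5 B t)
    Ta >= 23.3 degC:  Q(t) = 1.11 exp(B t) - 0.11 exp(10 B t)

    B(m) = -1.2815 m^-0.625 + 0.0284        [1/h, m in kg]

Q(0) = 1 and Q'(0) = 0, which reproduces the initial "plateau phase" of the
sigmoidal cooling curve, and Q decreases strictly to 0, so the forward map
t -> Tr is invertible.  :func:`estimate_pmi_classical` performs that
inversion numerically (the digital counterpart of Henssge's nomogram).

All temperatures are in degC, times in hours, weights in kg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "T0",
    "CF_MIN",
    "CF_MAX",
    "HenssgeError",
    "InvalidAmbientError",
    "InvalidWeightError",
    "UnsupportedCorrectionError",
    "InvalidTimeError",
    "InvalidMeasurementError",
    "UnsolvableError",
    "PlateauWarning",
    "CoolingParams",
    "coefficient_a",
    "coefficient_b",
    "adjusted_weight",
    "cooling_fraction",
    "rectal_temperature",
    "estimate_pmi_classical",
]

#: Rectal temperature at the moment of death, degC.
T0 = 37.2

#: Supported correction-factor range.  Larger factors require a
#: weight-dependent adjustment of the factor itself, which this model does
#: not implement.
CF_MIN = 0.7
CF_MAX = 1.4

# Ambient threshold between the two amplitude regimes.  The published table
# leaves (23.2, 23.3) undefined; inputs in the gap are split at the midpoint.
_TA_SPLIT = 23.25


class HenssgeError(ValueError):
    """Base class for invalid cooling-model inputs."""


class InvalidAmbientError(HenssgeError):
    """Ambient temperature is non-finite or not below 37.2 degC."""


class InvalidWeightError(HenssgeError):
    """Body weight is not a positive finite number."""


class UnsupportedCorrectionError(HenssgeError):
    """Correction factor outside the supported [0.7, 1.4] range."""


class InvalidTimeError(HenssgeError):
    """Negative post-mortem interval."""


class InvalidMeasurementError(HenssgeError):
    """Rectal temperature above 37.2 degC."""


class UnsolvableError(HenssgeError):
    """No post-mortem interval in the search bracket explains the input."""


class PlateauWarning(UserWarning):
    """Inversion attempted in the flat early part of the cooling curve.

    At Tr = 37.2 degC the curve has zero slope, so the estimate t = 0 is
    ill-conditioned: any interval inside the plateau phase is consistent
    with the measurement.
    """


@dataclass(frozen=True)
class CoolingParams:
    """Resolved parameters of one cooling curve.

    Attributes
    ----------
    t0 : float
        Rectal temperature at death, always 37.2 degC.
    a : float
        Amplitude parameter, 1.25 (Ta <= 23.2) or 1.11 (Ta >= 23.3).
    b : float
        Rate parameter in 1/h; negative for physiological weights.
    ta : float
        Ambient temperature, degC.
    m_eff : float
        Effective (correction-adjusted) body weight, kg.
    """

    a: float
    b: float
    ta: float
    m_eff: float
    t0: float = T0


def coefficient_a(ta: float) -> float:
    """Amplitude parameter A for ambient temperature `ta` (degC).

    Returns 1.25 for ta <= 23.2 and 1.11 for ta >= 23.3; the undefined gap
    in between is split at 23.25.
    """
    ta = float(ta)
    if not np.isfinite(ta) or ta >= T0:
        raise InvalidAmbientError(
            f"ambient temperature must be finite and below {T0} degC, got {ta!r}"
        )
    return 1.25 if ta <= _TA_SPLIT else 1.11


def coefficient_b(m_eff: float) -> float:
    """Rate parameter B (1/h) for effective body weight `m_eff` (kg).

    B = -1.2815 m^-0.625 + 0.0284; strictly increasing in the weight and
    negative over the whole supported range.
    """
    m_eff = float(m_eff)
    if not np.isfinite(m_eff) or m_eff <= 0:
        raise InvalidWeightError(f"effective weight must be positive, got {m_eff!r}")
    return -1.2815 * m_eff ** -0.625 + 0.0284


def adjusted_weight(m: float, cf: float) -> float:
    """Effective weight cf * m (kg) for correction factor `cf` in [0.7, 1.4]."""
    m = float(m)
    cf = float(cf)
    if not np.isfinite(m) or m <= 0:
        raise InvalidWeightError(f"body weight must be positive, got {m!r}")
    if not np.isfinite(cf) or not (CF_MIN <= cf <= CF_MAX):
        raise UnsupportedCorrectionError(
            f"correction factor must lie in [{CF_MIN}, {CF_MAX}], got {cf!r}; "
            "larger factors need a weight-dependent adjustment this model "
            "does not support"
        )
    return cf * m


def cooling_params(m: float, cf: float, ta: float) -> CoolingParams:
    """Resolve (m, cf, Ta) into the parameters of one cooling curve."""
    m_eff = adjusted_weight(m, cf)
    return CoolingParams(a=coefficient_a(ta), b=coefficient_b(m_eff), ta=float(ta), m_eff=m_eff)


def cooling_fraction(t, a: float, b: float):
    """Normalized cooling fraction Q(t) = (Tr - Ta)/(T0 - Ta).

    Uses the published operational exponents: the second exponential decays
    at 5B for A = 1.25 and at 10B for A = 1.11.  Accepts scalar or array t.
    """
    t = np.asarray(t, dtype=float)
    k = 5.0 if a == 1.25 else 10.0
    return a * np.exp(b * t) - (a - 1.0) * np.exp(k * b * t)


def rectal_temperature(t, m: float, cf: float, ta: float):
    """Forward model: rectal temperature (degC) after `t` hours.

    Parameters
    ----------
    t : float or array
        Post-mortem interval in hours, >= 0.
    m, cf, ta : float
        Body weight (kg), correction factor, ambient temperature (degC).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 0):
        raise InvalidTimeError("post-mortem interval must be finite and >= 0")
    p = cooling_params(m, cf, ta)
    tr = p.ta + (T0 - p.ta) * cooling_fraction(t_arr, p.a, p.b)
    return tr if isinstance(t, np.ndarray) else float(tr)


def _rectal_temperature_grid(t, b: float, a: float, ta: float):
    # fast path for the generator: parameters already resolved/validated
    return ta + (T0 - ta) * cooling_fraction(t, a, b)


def estimate_pmi_classical(
    tr: float,
    ta: float,
    m: float,
    cf: float,
    t_max: float = 72.0,
    xtol: float = 1e-10,
) -> float:
    """Invert the cooling model: hours since death for a measured `tr`.

    Performs a bracketed root search on [0, `t_max`] hours; the root is
    unique because the forward curve is strictly decreasing.  A measurement
    exactly at 37.2 degC returns 0.0 and emits :class:`PlateauWarning`
    because the flat start of the curve makes the inverse ill-conditioned
    there.

    Raises
    ------
    UnsolvableError
        If tr <= ta (cooling complete or inconsistent input) or the
        temperature is not reached within `t_max` hours.
    InvalidMeasurementError
        If tr exceeds 37.2 degC.
    """
    tr = float(tr)
    if not np.isfinite(tr) or tr > T0:
        raise InvalidMeasurementError(
            f"rectal temperature must be finite and <= {T0} degC, got {tr!r}"
        )
    p = cooling_params(m, cf, ta)  # validates ta/m/cf
    if tr <= p.ta:
        raise UnsolvableError(
            f"rectal temperature {tr} degC is not above ambient {p.ta} degC: "
            "cooling is complete and the interval cannot be resolved"
        )
    if tr == T0:
        warnings.warn(
            "measurement at 37.2 degC lies on the initial plateau; "
            "returning 0 h but the true interval is unresolved",
            PlateauWarning,
            stacklevel=2,
        )
        return 0.0

    def f(t: float) -> float:
        return p.ta + (T0 - p.ta) * cooling_fraction(t, p.a, p.b) - tr

    if f(t_max) > 0.0:
        raise UnsolvableError(
            f"temperature {tr} degC is not reached within {t_max} h; "
            "outside the supported estimation range"
        )
    return float(brentq(f, 0.0, t_max, xtol=xtol))
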