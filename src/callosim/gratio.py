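"""Volume-fraction algebra: MVF, AVF, g-ratio, and conduction velocity.

The g-ratio is the inner-to-outer diameter ratio of the myelinated axon,

    g = sqrt( 1 / (1 + MVF/AVF) ),

computed from the myelin volume fraction (calibrated from MTSat,
MVF = 0.11 x MTSat) and the axonal volume fraction (from the CHARMED
restricted fraction, AVF = (1 - MVF) FR, or from the NODDI fractions,
AVF = (1 - MVF)(1 - v_iso) v_ic).  The predicted conduction velocity is

    cv = p * d_a * sqrt(-ln g),   p = 16.99  (m/s per um),

whose natural-log form yields the classical conduction-optimal g-ratio
e^(-1/2) ~ 0.61 when the outer diameter is held fixed.

All functions are voxel-wise and vectorized; aggregate (e.g. take region
medians) only after the voxel-wise algebra.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

MVF_CALIBRATION = 0.11
CV_PROPORTIONALITY = 16.99


class CalibrationError(ValueError):
    """MVF calibration produced a physically impossible volume fraction."""


def mvf(mtsat, calibration=MVF_CALIBRATION):
    """Myelin volume fraction from MTSat (p.u.): MVF = 0.11 x MTSat."""
    mtsat = np.asarray(mtsat, dtype=float)
    if np.any(mtsat < 0):
        raise ValueError("MTSat must be >= 0")
    out = calibration * mtsat
    if np.any(out >= 1.0):
        raise CalibrationError("MVF >= 1: calibration invalid for this input")
    return out if out.ndim else float(out)


def avf_charmed(mvf_val, fr):
    """Axonal volume fraction from the restricted signal fraction:
    AVF = (1 - MVF) x FR."""
    out = (1.0 - np.asarray(mvf_val, dtype=float)) * np.asarray(fr, dtype=float)
    return out if out.ndim else float(out)


def avf_noddi(mvf_val, v_iso, v_ic):
    """Axonal volume fraction from NODDI fractions:
    AVF = (1 - MVF)(1 - v_iso) v_ic."""
    out = ((1.0 - np.asarray(mvf_val, dtype=float))
           * (1.0 - np.asarray(v_iso, dtype=float))
           * np.asarray(v_ic, dtype=float))
    return out if out.ndim else float(out)


def g_ratio(mvf_val, avf_val):
    """g = sqrt(1 / (1 + MVF/AVF)); NaN (with a warning) where AVF = 0."""
    mvf_val = np.asarray(mvf_val, dtype=float)
    avf_val = np.asarray(avf_val, dtype=float)
    if np.any(mvf_val < 0) or np.any(avf_val < 0):
        raise ValueError("volume fractions must be >= 0")
    zero = avf_val == 0
    if np.any(zero):
        warnings.warn("g-ratio undefined where AVF = 0; returning NaN",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(1.0 / (1.0 + mvf_val / avf_val))
    out = np.where(zero, np.nan, out)
    return out if out.ndim else float(out)


def conduction_velocity(d_a, g, p=CV_PROPORTIONALITY):
    """Predicted conduction velocity cv = p d_a sqrt(-ln g), in m/s.

    Natural logarithm; g must lie in (0, 1] (NaN passes through).
    """
    d_a = np.asarray(d_a, dtype=float)
    g = np.asarray(g, dtype=float)
    valid = np.isnan(g) | ((g > 0) & (g <= 1.0))
    if not np.all(valid):
        raise ValueError("g-ratio must lie in (0, 1]")
    if np.any(d_a < 0):
        raise ValueError("d_a must be >= 0")
    with np.errstate(invalid="ignore"):
        out = p * d_a * np.sqrt(-np.log(g))
    return out if out.ndim else float(out)


def optimal_g(outer_diameter=1.0, p=CV_PROPORTIONALITY):
    """Numerically maximize cv over g at fixed outer diameter D.

    With d_a = g D, cv(g) = p g D sqrt(-ln g); the argmax is e^(-1/2)
    (~0.61, i.e. 0.6 to one decimal), independent of D and p.
    """
    res = minimize_scalar(
        lambda g: -conduction_velocity(g * outer_diameter, g, p),
        bounds=(0.01, 0.999),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
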