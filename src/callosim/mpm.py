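"""Multi-parametric FLASH forward simulation and MTSat estimation.

The magnetization-transfer saturation (MTSat) is a semi-quantitative,
T1- and amplitude-corrected index of the fractional longitudinal
saturation deposited by the off-resonance MT pulse each TR, expressed in
percent units (p.u.).  It is estimated from three spoiled gradient-echo
(FLASH) contrasts — T1-weighted, PD-weighted, and MT-weighted — acquired
with different TR / flip-angle combinations, via the standard small-angle
rational estimators:

    R1_app = (1/2) (S_T1 a_T1/TR_T1 - S_PD a_PD/TR_PD)
             / (S_PD/a_PD - S_T1/a_T1)
    A_app  = S_PD S_T1 (TR_PD a_T1/a_PD - TR_T1 a_PD/a_T1)
             / (S_T1 TR_PD a_T1 - S_PD TR_T1 a_PD)
    MTSat  = (A_app a_MT / S_MT - 1) R1_app TR_MT - a_MT^2 / 2

with flip angles in radians and TR in seconds inside the estimator.
The estimator is invariant to a global scaling of all three signals, which
makes it insensitive to the receive field.
"""

from __future__ import annotations

import numpy as np

from callosim.schemes import MPMProtocol


def flash_signal(A, R1, alpha_deg, tr_ms):
    """Steady-state spoiled gradient-echo signal.

    S = A sin(a) (1 - E) / (1 - E cos(a)),  E = exp(-TR * R1).

    A is the effective amplitude (a.u.), R1 in 1/s, flip angle in degrees,
    TR in ms.
    """
    A = np.asarray(A, dtype=float)
    alpha = np.deg2rad(alpha_deg)
    if np.any(alpha <= 0) or np.any(alpha > np.pi / 2):
        raise ValueError("flip angle must lie in (0, 90] degrees")
    if np.any(np.asarray(tr_ms) <= 0):
        raise ValueError("TR must be > 0")
    E = np.exp(-np.asarray(tr_ms) * 1e-3 * np.asarray(R1))
    out = A * np.sin(alpha) * (1.0 - E) / (1.0 - E * np.cos(alpha))
    return out if out.ndim else float(out)


def mt_flash_signal(A, R1, alpha_deg, tr_ms, mtsat_pu):
    """FLASH signal with an MT pulse saturating a fraction delta of the
    longitudinal magnetization once per TR (delta = mtsat_pu / 100).

    The instantaneous saturation is placed mid-TR (relaxation split evenly
    around it), the discretization consistent with the rational MTSat
    estimator; the steady state is

    S = A sin(a) [(1 - Eh)(1 - delta) Eh + (1 - Eh)]
        / [1 - (1 - delta) Eh^2 cos(a)],   Eh = exp(-TR R1 / 2).
    """
    delta = np.asarray(mtsat_pu, dtype=float) / 100.0
    if np.any(delta < 0) or np.any(delta >= 1):
        raise ValueError("saturation must lie in [0, 100) p.u.")
    alpha = np.deg2rad(alpha_deg)
    Eh = np.exp(-0.5 * np.asarray(tr_ms) * 1e-3 * np.asarray(R1))
    num = (1.0 - Eh) * (1.0 - delta) * Eh + (1.0 - Eh)
    den = 1.0 - (1.0 - delta) * Eh**2 * np.cos(alpha)
    out = np.asarray(A, dtype=float) * np.sin(alpha) * num / den
    return out if out.ndim else float(out)


def compute_mtsat(S_T1, S_PD, S_MT, protocol: MPMProtocol | None = None):
    """MTSat (p.u.), apparent R1 (1/s), and apparent amplitude from the
    three FLASH contrasts.

    Voxels whose T1w/PDw signal pair is inconsistent with the protocol
    (near-zero denominators, non-positive estimates) are returned as NaN.
    Accepts scalars or arrays.
    """
    if protocol is None:
        protocol = MPMProtocol()
    S_T1 = np.asarray(S_T1, dtype=float)
    S_PD = np.asarray(S_PD, dtype=float)
    S_MT = np.asarray(S_MT, dtype=float)
    if np.any(S_T1 <= 0) or np.any(S_PD <= 0) or np.any(S_MT <= 0):
        raise ValueError("FLASH signals must be positive")
    a_t1 = np.deg2rad(protocol.t1w.flip_angle)
    a_pd = np.deg2rad(protocol.pdw.flip_angle)
    a_mt = np.deg2rad(protocol.mtw.flip_angle)
    tr_t1 = protocol.t1w.tr * 1e-3
    tr_pd = protocol.pdw.tr * 1e-3
    tr_mt = protocol.mtw.tr * 1e-3

    den_r1 = S_PD / a_pd - S_T1 / a_t1
    den_a = S_T1 * tr_pd * a_t1 - S_PD * tr_t1 * a_pd
    scale = np.maximum(S_PD / a_pd, S_T1 / a_t1)
    bad = (np.abs(den_r1) < 1e-12 * scale) | (np.abs(den_a) < 1e-12 * scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1_app = 0.5 * (S_T1 * a_t1 / tr_t1 - S_PD * a_pd / tr_pd) / den_r1
        a_app = (S_PD * S_T1
                 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1) / den_a)
        mtsat = ((a_app * a_mt / S_MT - 1.0) * r1_app * tr_mt
                 - a_mt**2 / 2.0) * 100.0
    bad = bad | ~np.isfinite(mtsat) | (r1_app <= 0)
    mtsat = np.where(bad, np.nan, mtsat)
    r1_app = np.where(bad, np.nan, r1_app)
    a_app = np.where(bad, np.nan, a_app)
    if mtsat.ndim == 0:
        return float(mtsat), float(r1_app), float(a_app)
    return mtsat, r1_app, a_app


def simulate_mpm_voxel(A, R1, mtsat_pu, protocol: MPMProtocol | None = None):
    """Forward-simulate the (S_T1, S_PD, S_MT) triplet for one voxel."""
    if protocol is None:
        protocol = MPMProtocol()
    s_t1 = flash_signal(A, R1, protocol.t1w.flip_angle, protocol.t1w.tr)
    s_pd = flash_signal(A, R1, protocol.pdw.flip_angle, protocol.pdw.tr)
    s_mt = mt_flash_signal(A, R1, protocol.mtw.flip_angle, protocol.mtw.tr,
                           mtsat_pu)
    return s_t1, s_pd, s_mt
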