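"""Forward signal models for white-matter microstructure.

Compartments
------------
* restricted: water inside impermeable parallel cylinders.  The
  perpendicular spin-echo attenuation follows the Gaussian phase
  distribution (GPD) series for a rectangular-pulse PGSE sequence, summed
  over roots of J1'; parallel diffusion is free Gaussian with diffusivity
  ``D_a``.
* hindered: an axially symmetric Gaussian ("zeppelin") whose perpendicular
  diffusivity may decrease with diffusion time, modeling structural
  disorder of the extra-axonal space:
  D_perp(Delta, delta) = D_inf + A (ln(Delta/delta) + 3/2) / (Delta - delta/3).
* ball: isotropic Gaussian.
* Watson-dispersed stick: the intra-neurite compartment of NODDI, with
  orientation dispersion OD = (2/pi) arctan(1/kappa).

Composite models
----------------
CHARMED combines a restricted cylinder population (signal fraction ``FR``)
with a hindered zeppelin.  AxCaliber generalizes the restricted term to a
distribution of cylinder diameters (gamma, truncated gamma, or continuous
Poisson), weighted by cross-sectional area (d^2), and is fitted across
multiple diffusion times.  NODDI is the standard three-compartment model
with a tortuosity-coupled extracellular space, D_perp = D_par (1 - v_ic).

All attenuations are normalized to 1 at b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special
from scipy.integrate import quad

from callosim.units import GAMMA, b_to_ms_um2
from callosim.schemes import AcquisitionScheme


class QuadratureError(RuntimeError):
    """Numerical quadrature over the diameter distribution failed."""


# ---------------------------------------------------------------------------
# Restricted cylinder (GPD / van Gelderen series)
# ---------------------------------------------------------------------------

_DEFAULT_N_ROOTS = 20
_J1P_ROOTS = special.jnp_zeros(1, 64)


def _gpd_ln_attenuation(radius, G_perp, delta, Delta, D, n_roots):
    """ln attenuation for cylinders; broadcasts radius against the pulse
    arrays.  radius: (...,1) or scalar; G_perp/delta/Delta: (n,)."""
    mu = _J1P_ROOTS[:n_roots]                        # roots of J1'
    radius = np.asarray(radius, dtype=float)
    safe_r = np.where(radius > 0, radius, np.inf)
    alpha = mu / safe_r[..., None]                   # (..., m)
    a2D = D * alpha**2
    dl = np.asarray(delta, dtype=float)[..., None]
    Dl = np.asarray(Delta, dtype=float)[..., None]
    num = (
        2.0 * a2D * dl
        - 2.0
        + 2.0 * np.exp(-a2D * dl)
        + 2.0 * np.exp(-a2D * Dl)
        - np.exp(-a2D * (Dl - dl))
        - np.exp(-a2D * (Dl + dl))
    )
    # mu are roots of J1', so mu^2 - 1 > 0; express denom via mu to stay
    # finite at radius -> 0 (where the series vanishes).
    denom = D**2 * alpha**6 * (mu**2 - 1.0)
    series = np.sum(num / denom, axis=-1)
    series = np.where(np.broadcast_to(radius > 0, series.shape), series, 0.0)
    gG = GAMMA * np.asarray(G_perp, dtype=float)
    return -2.0 * gG**2 * series


def cylinder_perp_attenuation(d, G_perp, delta, Delta, D_a=1.7,
                              n_roots=_DEFAULT_N_ROOTS):
    """Perpendicular PGSE attenuation of water restricted in a cylinder.

    Parameters
    ----------
    d : diameter (um), scalar or array.  If both ``d`` and the pulse
        parameters are arrays, an outer (len(d), n_volumes) array results.
    G_perp : perpendicular gradient amplitude (mT/m).
    delta, Delta : pulse duration and separation (ms).
    D_a : intrinsic intra-cylinder diffusivity (um^2/ms).
    n_roots : number of J1' roots in the series (>= 10).

    Attenuation is in (0, 1], equals 1 at G_perp = 0, and tends to 1 as
    d -> 0 (full restriction on the experiment's length scale).
    """
    d = np.asarray(d, dtype=float)
    G_perp = np.asarray(G_perp, dtype=float)
    if np.any(d < 0) or np.any(G_perp < 0):
        raise ValueError("diameter and gradient amplitude must be >= 0")
    if np.any(np.asarray(delta) <= 0) or np.any(np.asarray(Delta) <= np.asarray(delta)):
        raise ValueError("require 0 < delta < Delta")
    if D_a < 0:
        raise ValueError("diffusivity must be >= 0")
    if n_roots < 10 or n_roots > _J1P_ROOTS.size:
        raise ValueError(f"n_roots must be in [10, {_J1P_ROOTS.size}]")
    scalar = d.ndim == 0 and G_perp.ndim == 0 and np.ndim(delta) == 0
    if d.ndim == 1 and G_perp.ndim >= 1:
        # outer product: rows over diameters, columns over volumes
        lnE = _gpd_ln_attenuation(d[:, None] / 2.0, G_perp, delta, Delta,
                                  D_a, n_roots)
    else:
        lnE = _gpd_ln_attenuation(d / 2.0, G_perp, delta, Delta, D_a, n_roots)
    out = np.exp(lnE)
    return float(out) if scalar and out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Diameter distributions
# ---------------------------------------------------------------------------

_POISSON_SUPPORT = (1e-3, 25.0)
_TRUNC_DEFAULT_BOUNDS = (0.1, 20.0)


@dataclass(frozen=True)
class DiameterDistribution:
    """Axon diameter distribution.

    families: ``delta`` (single diameter d), ``gamma`` (shape k, scale
    theta), ``gamma_truncated`` (k, theta, bounds), ``poisson`` (continuous
    Poisson, p(d) proportional to lam^d e^-lam / Gamma(d+1) on (0, 25]).
    """

    family: str
    d: float | None = None
    k: float | None = None
    theta: float | None = None
    lam: float | None = None
    bounds: tuple = _TRUNC_DEFAULT_BOUNDS

    def __post_init__(self):
        if self.family == "delta":
            if self.d is None or self.d <= 0:
                raise ValueError("delta family requires d > 0")
        elif self.family in ("gamma", "gamma_truncated"):
            if self.k is None or self.theta is None or self.k <= 0 or self.theta <= 0:
                raise ValueError("gamma family requires k > 0 and theta > 0")
            lo, hi = self.bounds
            if not (0 < lo < hi):
                raise ValueError("truncation bounds must satisfy 0 < d_min < d_max")
        elif self.family == "poisson":
            if self.lam is None or self.lam <= 0:
                raise ValueError("poisson family requires lam > 0")
        else:
            raise ValueError(f"unknown diameter distribution family: {self.family!r}")

    # -- density ------------------------------------------------------------
    def pdf(self, d):
        """Number-weighted density (normalized on the support)."""
        d = np.asarray(d, dtype=float)
        if self.family == "delta":
            raise ValueError("delta distribution has no density")
        if self.family == "gamma":
            return _gamma_pdf(d, self.k, self.theta)
        if self.family == "gamma_truncated":
            lo, hi = self.bounds
            mass = _gamma_cdf(hi, self.k, self.theta) - _gamma_cdf(lo, self.k, self.theta)
            if mass <= 0:
                raise QuadratureError("truncated gamma has no mass inside bounds")
            p = _gamma_pdf(d, self.k, self.theta) / mass
            return np.where((d >= lo) & (d <= hi), p, 0.0)
        # continuous Poisson, numerically normalized on its support
        lo, hi = _POISSON_SUPPORT
        logp = d * np.log(self.lam) - self.lam - special.gammaln(d + 1.0)
        z = self._poisson_norm()
        return np.where((d > lo) & (d <= hi), np.exp(logp) / z, 0.0)

    def _poisson_norm(self):
        lo, hi = _POISSON_SUPPORT
        val, err = quad(
            lambda x: np.exp(x * np.log(self.lam) - self.lam - special.gammaln(x + 1.0)),
            lo, hi, limit=200,
        )
        if not np.isfinite(val) or val <= 0:
            raise QuadratureError("continuous Poisson normalization failed")
        return val

    def mean(self):
        """Number-weighted mean diameter (um); the default scalar d_a."""
        if self.family == "delta":
            return self.d
        if self.family == "gamma":
            return self.k * self.theta
        d, w = _quadrature_nodes()
        p = self.pdf(d)
        return float(np.sum(w * p * d) / np.sum(w * p))

    def volume_weighted_mean(self):
        """Mean diameter under cross-section (d^2) weighting."""
        if self.family == "delta":
            return self.d
        d, w = _quadrature_nodes()
        p = self.pdf(d) * d**2
        return float(np.sum(w * p * d) / np.sum(w * p))


def _gamma_pdf(d, k, theta):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (k - 1) * np.log(d) - d / theta - special.gammaln(k) - k * np.log(theta)
    return np.where(d > 0, np.exp(logp), 0.0)


def _gamma_cdf(d, k, theta):
    return special.gammainc(k, np.asarray(d, dtype=float) / theta)


_QUAD_N = 128
_QUAD_SUPPORT = (0.05, 25.0)
_quad_cache: dict = {}


def _quadrature_nodes(n=_QUAD_N, support=_QUAD_SUPPORT):
    key = (n, support)
    if key not in _quad_cache:
        x, w = np.polynomial.legendre.leggauss(n)
        lo, hi = support
        d = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        _quad_cache[key] = (d, 0.5 * (hi - lo) * w)
    return _quad_cache[key]


def distribution_signal(dist: DiameterDistribution, G_perp, delta, Delta,
                        D_a=1.7, n_roots=_DEFAULT_N_ROOTS, n_nodes=_QUAD_N):
    """Perpendicular attenuation of a cylinder population.

    The population signal is the volume-weighted (d^2, i.e. spins per
    cylinder) average of single-cylinder attenuations:
    S = integral w(d) E(d) dd with w(d) proportional to d^2 p(d).
    The ``delta`` family reduces exactly to the single-cylinder case.
    """
    if dist.family == "delta":
        return cylinder_perp_attenuation(dist.d, G_perp, delta, Delta, D_a, n_roots)
    d, w = _quadrature_nodes(n_nodes)
    weights = w * dist.pdf(d) * d**2
    total = weights.sum()
    if not np.isfinite(total) or total <= 1e-12:
        raise QuadratureError(
            f"diameter quadrature degenerate for {dist}: total weight {total}"
        )
    weights = weights / total
    E = cylinder_perp_attenuation(d, np.asarray(G_perp, dtype=float),
                                  delta, Delta, D_a, n_roots)
    return weights @ E if E.ndim == 2 else float(weights @ E)


# ---------------------------------------------------------------------------
# Gaussian compartments
# ---------------------------------------------------------------------------

def zeppelin_perp_diffusivity(Delta, delta, D_inf, A):
    """Time-dependent perpendicular diffusivity of the extra-axonal space.

    D_perp(Delta, delta) = D_inf + A (ln(Delta/delta) + 3/2) / (Delta - delta/3),
    the short-range-disorder form; strictly decreasing in Delta for A > 0
    and equal to the asymptote D_inf when A = 0.  A has units um^2.
    """
    Delta = np.asarray(Delta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if np.any(Delta <= delta):
        raise ValueError("require Delta > delta")
    if D_inf < 0 or A < 0:
        raise ValueError("D_inf and A must be >= 0")
    out = D_inf + A * (np.log(Delta / delta) + 1.5) / (Delta - delta / 3.0)
    return out if out.ndim else float(out)


def ball_attenuation(bvals, D_iso):
    return np.exp(-b_to_ms_um2(np.asarray(bvals, dtype=float)) * D_iso)


def stick_attenuation(bvals, bvecs, orientation, D_par):
    b = b_to_ms_um2(np.asarray(bvals, dtype=float))
    cos2 = (np.asarray(bvecs) @ np.asarray(orientation)) ** 2
    return np.exp(-b * D_par * cos2)


def zeppelin_attenuation(bvals, bvecs, orientation, D_par, D_perp):
    b = b_to_ms_um2(np.asarray(bvals, dtype=float))
    cos2 = (np.asarray(bvecs) @ np.asarray(orientation)) ** 2
    return np.exp(-b * (cos2 * D_par + (1.0 - cos2) * np.asarray(D_perp)))


# ---------------------------------------------------------------------------
# Parameter container
# ---------------------------------------------------------------------------

def _default_orientation():
    return np.array([0.0, 0.0, 1.0])


@dataclass
class MicrostructureParams:
    """Ground-truth or estimated voxel tissue parameters.

    Diffusivities in um^2/ms, diameters in um, A in um^2; ``fr``, ``v_ic``
    and ``v_iso`` are signal fractions in [0, 1].
    """

    fr: float = 0.35
    dist: DiameterDistribution = field(
        default_factory=lambda: DiameterDistribution("delta", d=3.0)
    )
    D_a: float = 1.7            # intra-axonal parallel diffusivity
    D_par_ec: float = 1.7       # extracellular parallel diffusivity
    D_inf: float = 0.5          # extracellular perpendicular asymptote
    A: float = 0.0              # extracellular disorder amplitude (um^2)
    orientation: np.ndarray = field(default_factory=_default_orientation)
    v_ic: float = 0.68          # NODDI intracellular fraction
    v_iso: float = 0.02         # NODDI isotropic fraction
    kappa: float = 16.0         # Watson concentration
    D_iso: float = 3.0          # free-water diffusivity
    mtsat: float | None = None  # p.u.

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(self.orientation)
        if not np.isclose(nrm, 1.0, atol=1e-6):
            raise ValueError("orientation must be unit-norm")
        for name in ("fr", "v_ic", "v_iso"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("D_a", "D_par_ec", "D_inf", "A", "D_iso"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    def replace(self, **kw):
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Composite models
# ---------------------------------------------------------------------------

def _decompose_gradient(scheme: AcquisitionScheme, orientation):
    """Per-volume parallel b (s/mm^2 -> ms/um^2 handled by callers) and
    perpendicular gradient amplitude."""
    n = np.asarray(orientation, dtype=float)
    cos2 = np.clip((scheme.bvecs @ n) ** 2, 0.0, 1.0)
    G = scheme.gradient_amplitudes
    G_perp = G * np.sqrt(1.0 - cos2)
    return cos2, G_perp


def restricted_signal(scheme: AcquisitionScheme, params: MicrostructureParams,
                      n_roots=_DEFAULT_N_ROOTS):
    """Attenuation of the restricted (intra-axonal) compartment."""
    cos2, G_perp = _decompose_gradient(scheme, params.orientation)
    b_par = b_to_ms_um2(scheme.bvals) * cos2
    E_par = np.exp(-b_par * params.D_a)
    E_perp = distribution_signal(params.dist, G_perp, scheme.delta,
                                 scheme.Delta, params.D_a, n_roots)
    return E_par * E_perp


def hindered_signal(scheme: AcquisitionScheme, params: MicrostructureParams):
    """Attenuation of the hindered (extra-axonal, time-dependent zeppelin)
    compartment."""
    D_perp = zeppelin_perp_diffusivity(scheme.Delta, scheme.delta,
                                       params.D_inf, params.A)
    return zeppelin_attenuation(scheme.bvals, scheme.bvecs, params.orientation,
                                params.D_par_ec, D_perp)


def compartment_signals(scheme: AcquisitionScheme, params: MicrostructureParams):
    """Per-compartment attenuations: ball, stick, zeppelin, restricted."""
    return {
        "ball": ball_attenuation(scheme.bvals, params.D_iso),
        "stick": stick_attenuation(scheme.bvals, scheme.bvecs,
                                   params.orientation, params.D_par_ec),
        "zeppelin": hindered_signal(scheme, params),
        "restricted": restricted_signal(scheme, params),
    }


def charmed_signal(scheme: AcquisitionScheme, params: MicrostructureParams,
                   n_roots=_DEFAULT_N_ROOTS):
    """Composite hindered-and-restricted attenuation:
    S = FR * restricted + (1 - FR) * hindered."""
    return (params.fr * restricted_signal(scheme, params, n_roots)
            + (1.0 - params.fr) * hindered_signal(scheme, params))


def axcaliber_signal(scheme: AcquisitionScheme, params: MicrostructureParams,
                     n_roots=_DEFAULT_N_ROOTS):
    """CHARMED composition with a diameter *distribution* as the restricted
    term, evaluated across diffusion times.  Identical to
    :func:`charmed_signal` (the distinction is the distribution family
    carried by ``params.dist``)."""
    return charmed_signal(scheme, params, n_roots)


def ball_stick_signal(scheme: AcquisitionScheme, f, D, orientation):
    """Two-compartment ball-and-stick attenuation with shared diffusivity."""
    return (f * stick_attenuation(scheme.bvals, scheme.bvecs, orientation, D)
            + (1.0 - f) * ball_attenuation(scheme.bvals, D))


# ---------------------------------------------------------------------------
# NODDI
# ---------------------------------------------------------------------------

def od_from_kappa(kappa):
    """Orientation dispersion index OD = (2/pi) arctan(1/kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be > 0")
    out = (2.0 / np.pi) * np.arctan(1.0 / kappa)
    return out if out.ndim else float(out)


def kappa_from_od(od):
    od = np.asarray(od, dtype=float)
    if np.any((od <= 0) | (od >= 1)):
        raise ValueError("OD must lie in (0, 1)")
    out = 1.0 / np.tan(np.pi * od / 2.0)
    return out if out.ndim else float(out)


def watson_mean_cos2(kappa):
    """E[(mu . n)^2] under a Watson distribution with concentration kappa."""
    sk = np.sqrt(kappa)
    F = special.dawsn(sk)
    return float(-1.0 / (2.0 * kappa) + 1.0 / (2.0 * sk * F))


_N_THETA, _N_PHI = 96, 48
_watson_grid_cache: dict = {}


def _polar_grid(n_theta=_N_THETA, n_phi=_N_PHI):
    """Hemisphere quadrature grid in the frame of the mean orientation:
    Gauss-Legendre in u = cos(theta) on [0, 1] (antipodal symmetry supplies
    the other hemisphere), trapezoid in phi."""
    key = (n_theta, n_phi)
    if key not in _watson_grid_cache:
        x, w = np.polynomial.legendre.leggauss(n_theta)
        u = 0.5 * (x + 1.0)
        wu = 0.5 * w
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
        U = np.repeat(u, n_phi)
        PHI = np.tile(phi, n_theta)
        W = np.repeat(wu, n_phi) / n_phi       # integrates to 1 over u, phi
        s = np.sqrt(1.0 - U**2)
        local = np.stack([s * np.cos(PHI), s * np.sin(PHI), U], axis=1)
        _watson_grid_cache[key] = (local, U, W)
    return _watson_grid_cache[key]


def _orientation_frame(mu):
    """Right-handed orthonormal frame with third axis mu."""
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    return np.stack([e1, e2, mu], axis=1)


def watson_sphere_weights(kappa, n_theta=_N_THETA, n_phi=_N_PHI):
    """Quadrature nodes (in the mu frame) and self-normalized Watson
    weights; weights sum to 1 exactly in quadrature."""
    local, U, W = _polar_grid(n_theta, n_phi)
    w = W * np.exp(kappa * (U**2 - 1.0))    # shifted for overflow safety
    return local, w / w.sum()


def dispersed_stick_signal(scheme: AcquisitionScheme, orientation, kappa,
                           D_par=1.7, n_theta=_N_THETA, n_phi=_N_PHI):
    """Watson-dispersed stick attenuation via spherical quadrature in the
    frame of the mean orientation (exactly rotation-equivariant)."""
    local, w = watson_sphere_weights(kappa, n_theta, n_phi)
    R = _orientation_frame(orientation)
    nodes = local @ R.T
    b = b_to_ms_um2(scheme.bvals)
    cos2 = (scheme.bvecs @ nodes.T) ** 2
    return np.exp(-b[:, None] * D_par * cos2) @ w


def noddi_signal(scheme: AcquisitionScheme, params: MicrostructureParams,
                 n_theta=_N_THETA, n_phi=_N_PHI):
    """Three-compartment NODDI attenuation.

    Watson-dispersed stick (v_ic, kappa) + extracellular zeppelin with
    tortuosity D_perp = D_par (1 - v_ic) and Watson mean-tensor dispersion
    + isotropic ball (v_iso, D_iso).  D_par is taken from
    ``params.D_par_ec`` for both neurite and extracellular spaces
    (single-diffusivity convention).
    """
    D_par = params.D_par_ec
    A_ic = dispersed_stick_signal(scheme, params.orientation, params.kappa,
                                  D_par, n_theta, n_phi)
    # extracellular: axially symmetric mean tensor of the dispersed zeppelin
    tau = watson_mean_cos2(params.kappa)
    D_perp = D_par * (1.0 - params.v_ic)
    d_axial = tau * D_par + (1 - tau) * D_perp          # along mu
    d_radial = 0.5 * (1 - tau) * D_par + 0.5 * (1 + tau) * D_perp
    A_ec = zeppelin_attenuation(scheme.bvals, scheme.bvecs, params.orientation,
                                d_axial, d_radial)
    A_iso = ball_attenuation(scheme.bvals, params.D_iso)
    return ((1.0 - params.v_iso)
            * (params.v_ic * A_ic + (1.0 - params.v_ic) * A_ec)
            + params.v_iso * A_iso)


# ---------------------------------------------------------------------------
# Diffusion tensor / FA
# ---------------------------------------------------------------------------

def fit_dti(scheme: AcquisitionScheme, signals, b_max=1200.0):
    """Log-linear least-squares diffusion tensor fit.

    Uses volumes with b <= ``b_max`` (default keeps the Gaussian regime of
    protocol 1).  Non-positive signals are masked with a warning.  Returns
    (eigenvalues desc (um^2/ms), eigenvectors (columns), FA).
    """
    import warnings as _warnings

    signals = np.asarray(signals, dtype=float)
    mask = scheme.bvals <= b_max
    s = signals[mask]
    b = b_to_ms_um2(scheme.bvals[mask])
    g = scheme.bvecs[mask]
    pos = s > 0
    if not np.all(pos):
        _warnings.warn("non-positive signals masked in tensor fit", stacklevel=2)
        s, b, g = s[pos], b[pos], g[pos]
    if s.size < 7:
        raise ValueError("need at least 7 usable volumes for a tensor fit")
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    coef, *_ = np.linalg.lstsq(X, np.log(s), rcond=None)
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = coef[1:]
    T = np.array([[Dxx, Dxy, Dxz], [Dxy, Dyy, Dyz], [Dxz, Dyz, Dzz]])
    evals, evecs = np.linalg.eigh(T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return evals, evecs, fa_from_eigenvalues(evals)


def fa_from_eigenvalues(evals):
    """Fractional anisotropy from tensor eigenvalues."""
    evals = np.asarray(evals, dtype=float)
    md = evals.mean()
    num = np.sum((evals - md) ** 2)
    den = np.sum(evals**2)
    if den == 0:
        return 0.0
    return float(np.sqrt(1.5 * num / den))


def dti_fa(scheme: AcquisitionScheme, signals, b_max=1200.0):
    """FA from a log-linear tensor fit on the low-b shells."""
    return fit_dti(scheme, signals, b_max)[2]
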