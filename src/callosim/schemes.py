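"""Acquisition schemes, protocol builders, and scheme/volume/table I/O.

A diffusion acquisition is described per volume by its b-value, gradient
direction, pulse duration ``delta``, pulse separation ``Delta``, and echo
time.  Three built-in multi-shell protocols are provided:

1. fixed diffusion time (Delta = 23 ms), shells b = 0/500/1200/2400/4000/6000
   s/mm^2, used for tensor and NODDI fitting;
2. variable diffusion time (Delta = 18/30/42/55 ms), shells b = 0/2000/4000
   s/mm^2 per diffusion time, used for axon-diameter mapping;
3. as (2) with a reduced field of view (shorter TR).

Gradient amplitudes are derived from b via the rectangular-pulse PGSE
relation b = (gamma G delta)^2 (Delta - delta/3) and stay below the
300 mT/m system limit for every built-in volume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from callosim.units import GAMMA, b_to_ms_um2, b_from_ms_um2

logger = logging.getLogger(__name__)

MAX_GRADIENT_MT_M = 300.0

#: Corpus callosum parcellation: genu, anterior/mid/posterior body,
#: isthmus, splenium.
REGION_CODES = {1: "G", 2: "B1", 3: "B2", 4: "B3", 5: "ISTH", 6: "S"}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}
REGION_ORDER = ["G", "B1", "B2", "B3", "ISTH", "S"]


class SchemeFormatError(ValueError):
    """Malformed or mutually inconsistent scheme files."""


class ProtocolConfigurationError(ValueError):
    """Unknown or invalid built-in protocol request."""


def region_name(code: int) -> str:
    """Map an integer label code (1-6) to its region abbreviation."""
    try:
        return REGION_CODES[int(code)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown region code: {code!r}") from exc


def region_code(name: str) -> int:
    try:
        return REGION_NAMES[name]
    except KeyError as exc:
        raise ValueError(f"unknown region name: {name!r}") from exc


def gradient_amplitude(b, delta, Delta):
    """Gradient amplitude G (mT/m) for a rectangular-pulse PGSE experiment.

    Inverts b = (gamma G delta)^2 (Delta - delta/3) with b in s/mm^2 and
    timings in ms.
    """
    b = np.asarray(b, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-value must be non-negative")
    if np.any(delta <= 0) or np.any(Delta <= delta):
        raise ValueError("require 0 < delta < Delta")
    b_nat = b_to_ms_um2(b)
    g = np.sqrt(b_nat / (Delta - delta / 3.0)) / (GAMMA * delta)
    return g if g.ndim else float(g)


def b_value(G, delta, Delta):
    """b-value (s/mm^2) of a rectangular-pulse PGSE block; inverse of
    :func:`gradient_amplitude`."""
    G = np.asarray(G, dtype=float)
    delta = np.asarray(delta, dtype=float)
    Delta = np.asarray(Delta, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient amplitude must be non-negative")
    if np.any(delta <= 0) or np.any(Delta <= delta):
        raise ValueError("require 0 < delta < Delta")
    b = b_from_ms_um2((GAMMA * G * delta) ** 2 * (Delta - delta / 3.0))
    return b if b.ndim else float(b)


@dataclass
class AcquisitionScheme:
    """Per-volume acquisition table for a multi-shell PGSE protocol."""

    bvals: np.ndarray          # (n,), s/mm^2
    bvecs: np.ndarray          # (n, 3), unit vectors where b > 0
    delta: np.ndarray          # (n,), ms
    Delta: np.ndarray          # (n,), ms
    te: np.ndarray | None = None   # (n,), ms
    protocol_id: int | None = None

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        n = self.bvals.size
        if self.bvecs.shape != (n, 3):
            raise SchemeFormatError(
                f"bvecs shape {self.bvecs.shape} inconsistent with {n} b-values"
            )
        self.delta = np.broadcast_to(
            np.asarray(self.delta, dtype=float), (n,)
        ).copy()
        self.Delta = np.broadcast_to(
            np.asarray(self.Delta, dtype=float), (n,)
        ).copy()
        if self.te is not None:
            self.te = np.broadcast_to(np.asarray(self.te, dtype=float), (n,)).copy()
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(self.delta >= self.Delta):
            raise ValueError("require delta < Delta for every volume")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit-norm where b > 0")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def gradient_amplitudes(self) -> np.ndarray:
        """Per-volume G in mT/m (0 where b = 0)."""
        g = np.zeros_like(self.bvals)
        dw = self.bvals > 0
        g[dw] = gradient_amplitude(self.bvals[dw], self.delta[dw], self.Delta[dw])
        return g

    @property
    def shells(self) -> np.ndarray:
        return np.unique(np.round(self.bvals, 6))

    @property
    def diffusion_times(self) -> np.ndarray:
        return np.unique(self.Delta)

    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def subset(self, mask) -> "AcquisitionScheme":
        mask = np.asarray(mask)
        return AcquisitionScheme(
            self.bvals[mask],
            self.bvecs[mask],
            self.delta[mask],
            self.Delta[mask],
            None if self.te is None else self.te[mask],
            self.protocol_id,
        )


@dataclass(frozen=True)
class FlashContrast:
    """One spoiled gradient-echo contrast of the multi-parametric protocol."""

    tr: float            # ms
    flip_angle: float    # degrees
    mt_pulse: bool = False


@dataclass(frozen=True)
class MPMProtocol:
    """Three-contrast FLASH protocol (T1w, PDw, MTw)."""

    t1w: FlashContrast = field(default_factory=lambda: FlashContrast(23.0, 28.0))
    pdw: FlashContrast = field(default_factory=lambda: FlashContrast(23.0, 5.0))
    mtw: FlashContrast = field(
        default_factory=lambda: FlashContrast(42.0, 7.0, mt_pulse=True)
    )


def _load_directions(n: int) -> np.ndarray:
    with resources.files("callosim.data").joinpath(f"dirs{n}.txt").open() as fh:
        dirs = np.loadtxt(fh)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs


def build_protocol(protocol_id: int) -> AcquisitionScheme:
    """Construct one of the three built-in diffusion protocols.

    Protocol 1 (fixed diffusion time, Delta = 23 ms): 14 interleaved b=0
    volumes plus shells 500 (30 dir), 1200 (30), 2400 (60), 4000 (60),
    6000 (60) s/mm^2.  Protocols 2 and 3 (variable diffusion time): for each
    Delta in {18, 30, 42, 55} ms, 4 b=0 volumes followed by 30 directions at
    b=2000 and 60 directions at b=4000 s/mm^2 (376 volumes total).
    delta = 7 ms throughout.
    """
    if protocol_id not in (1, 2, 3):
        raise ProtocolConfigurationError(
            f"unknown protocol id {protocol_id!r}; expected 1, 2, or 3"
        )
    d30 = _load_directions(30)
    d60 = _load_directions(60)
    delta = 7.0
    if protocol_id == 1:
        shells = [(500.0, d30), (1200.0, d30), (2400.0, d60), (4000.0, d60), (6000.0, d60)]
        dw_b = np.concatenate([np.full(len(d), b) for b, d in shells])
        dw_v = np.vstack([d for _, d in shells])
        n_b0 = 14
        n_total = dw_b.size + n_b0
        b0_idx = np.round(np.linspace(0, n_total - 1, n_b0)).astype(int)
        bvals = np.empty(n_total)
        bvecs = np.zeros((n_total, 3))
        is_b0 = np.zeros(n_total, dtype=bool)
        is_b0[b0_idx] = True
        bvals[is_b0] = 0.0
        bvals[~is_b0] = dw_b
        bvecs[~is_b0] = dw_v
        return AcquisitionScheme(
            bvals, bvecs, delta, 23.0, te=59.0, protocol_id=1
        )
    # protocols 2 and 3 share the shell structure; only TR differs (3900 vs
    # 2200 ms), which the scheme does not carry, and the field of view.
    blocks_b, blocks_v, blocks_D = [], [], []
    for Delta in (18.0, 30.0, 42.0, 55.0):
        nb = 4 + len(d30) + len(d60)
        blocks_b.append(np.concatenate([np.zeros(4), np.full(len(d30), 2000.0),
                                        np.full(len(d60), 4000.0)]))
        blocks_v.append(np.vstack([np.zeros((4, 3)), d30, d60]))
        blocks_D.append(np.full(nb, Delta))
    return AcquisitionScheme(
        np.concatenate(blocks_b),
        np.vstack(blocks_v),
        delta,
        np.concatenate(blocks_D),
        te=80.0,
        protocol_id=protocol_id,
    )


def write_scheme(scheme: AcquisitionScheme, path_bval, path_bvec, path_timing=None):
    """Write a scheme as FSL-dialect bval/bvec plus a CSV timing sidecar."""
    fmt = "%.17g"
    np.savetxt(path_bval, scheme.bvals[None, :], fmt=fmt)
    np.savetxt(path_bvec, scheme.bvecs.T, fmt=fmt)
    if path_timing is not None:
        df = pd.DataFrame({"delta_ms": scheme.delta, "Delta_ms": scheme.Delta})
        if scheme.te is not None:
            df["te_ms"] = scheme.te
        df.to_csv(path_timing, index=False, float_format="%.17g")


def read_scheme(path_bval, path_bvec, path_timing=None,
                default_delta=7.0, default_Delta=23.0) -> AcquisitionScheme:
    """Read a scheme from FSL-dialect bval/bvec files and a timing sidecar.

    If the timing sidecar is absent the scheme falls back to a single
    diffusion time (``default_delta``/``default_Delta``) with a warning.
    """
    bvals = np.atleast_1d(np.loadtxt(path_bval))
    bvecs = np.atleast_2d(np.loadtxt(path_bvec))
    if bvecs.shape[0] != 3:
        raise SchemeFormatError(
            f"bvec file must have 3 rows (FSL dialect), got {bvecs.shape[0]}"
        )
    if bvecs.shape[1] != bvals.size:
        raise SchemeFormatError(
            f"column-count mismatch: {bvals.size} b-values vs "
            f"{bvecs.shape[1]} direction columns"
        )
    if path_timing is not None and Path(path_timing).exists():
        timing = pd.read_csv(path_timing)
        if len(timing) != bvals.size:
            raise SchemeFormatError(
                f"timing sidecar has {len(timing)} rows for {bvals.size} volumes"
            )
        delta = timing["delta_ms"].to_numpy()
        Delta = timing["Delta_ms"].to_numpy()
        te = timing["te_ms"].to_numpy() if "te_ms" in timing else None
    else:
        msg = (
            "no timing sidecar: assuming single diffusion time "
            f"delta={default_delta} ms, Delta={default_Delta} ms"
        )
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
        delta, Delta, te = default_delta, default_Delta, None
    return AcquisitionScheme(bvals, bvecs.T, delta, Delta, te=te)
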