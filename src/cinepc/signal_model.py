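"""bSSFP steady-state signal physics, a Bloch transient iterator, and inflow.

The balanced SSFP magnitude response is periodic in off-resonance with
period 1/TR and has a deep null (banding) where the per-TR precession angle
cancels the RF phase increment ψ.  Shifting ψ rigidly translates the band
pattern in frequency — the basis of phase-cycled banding removal.  Spins
that flow through the slice never reach steady state; their transient
signal near a band exceeds the steady-state value, which is the origin of
the hyperintense, time-varying flow artifact.

Conventions
-----------
Let E1 = exp(−TR/T1), E2 = exp(−TR/T2), α the flip angle,
φ = 2π·Δf·TR the free-precession angle per TR (positive Δf precesses
counterclockwise), and θ = φ − ψ.  With these signs ψ = 180° places the
on-resonant spin (Δf = 0) in the middle of the passband.  The echo at TE
carries the additional factor e^{iφ·TE/TR}·e^{−TE/T2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .protocol import ScanProtocol

__all__ = [
    "TissueParams",
    "FlowSpec",
    "ssfp_steady_state",
    "bloch_transient",
    "inflow_signal",
    "band_null_offset",
]


@dataclass
class TissueParams:
    """Relaxation, density and off-resonance of one tissue compartment.

    t1_ms/t2_ms in milliseconds with t1 ≥ t2 > 0; rho is proton density in
    arbitrary units (≥ 0); df_hz the local off-resonance frequency.
    """

    t1_ms: float
    t2_ms: float
    rho: float = 1.0
    df_hz: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1_ms >= self.t2_ms > 0):
            raise ValueError(
                f"require T1 >= T2 > 0 ms, got T1={self.t1_ms}, T2={self.t2_ms}"
            )
        if self.rho < 0:
            raise ValueError(f"proton density must be >= 0, got {self.rho}")


@dataclass
class FlowSpec:
    """Through-plane plug flow of fresh spins across the imaging slice.

    velocity_mm_s holds one through-plane speed per cardiac frame;
    slice_thickness_mm is the excited slab the spins traverse; ``tissue``
    describes the flowing spins (typically blood).
    """

    velocity_mm_s: Sequence[float]
    slice_thickness_mm: float
    tissue: TissueParams = field(
        default_factory=lambda: TissueParams(t1_ms=1900.0, t2_ms=250.0)
    )

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice_thickness_mm must be positive")
        self.velocity_mm_s = np.asarray(self.velocity_mm_s, dtype=float)


def _angles(tissue: TissueParams, protocol: ScanProtocol, psi_deg: float,
            df_hz=None):
    df = np.asarray(tissue.df_hz if df_hz is None else df_hz, dtype=float)
    phi = 2.0 * np.pi * df * protocol.tr_s
    psi = np.deg2rad(psi_deg)
    return df, phi, phi - psi


def ssfp_steady_state(tissue: TissueParams, protocol: ScanProtocol,
                      psi_deg: float, df_hz=None) -> np.ndarray | complex:
    """Closed-form bSSFP steady-state transverse magnetization at TE.

    Parameters
    ----------
    df_hz : array_like, optional
        Off-resonance value(s) overriding ``tissue.df_hz``; the closed form
        broadcasts over it, which the phantom renderer uses to evaluate a
        whole field map at once.

    Returns
    -------
    complex scalar or ndarray matching the shape of ``df_hz``.
    """
    _, phi, theta = _angles(tissue, protocol, psi_deg, df_hz)
    e1 = np.exp(-protocol.tr_ms / tissue.t1_ms)
    e2 = np.exp(-protocol.tr_ms / tissue.t2_ms)
    a = np.deg2rad(protocol.flip_deg)
    num = tissue.rho * (1.0 - e1) * np.sin(a) * (1.0 - e2 * np.exp(-1j * theta))
    den = (1.0 - e1 * np.cos(a)) * (1.0 - e2 * np.cos(theta)) \
        - e2 * (e1 - np.cos(a)) * (e2 - np.cos(theta))
    m = num / den
    m = m * np.exp(1j * phi * protocol.te_ms / protocol.tr_ms)
    m = m * np.exp(-protocol.te_ms / tissue.t2_ms)
    return m if np.ndim(m) else complex(m)


def bloch_transient(tissue: TissueParams, protocol: ScanProtocol,
                    psi_deg: float, n_tr: int, m_init=None,
                    df_hz=None) -> np.ndarray:
    """Brute-force per-TR Bloch iteration; the oracle for the closed form.

    Each TR applies the α pulse about an axis whose phase has advanced by ψ
    relative to the previous pulse (handled here in the demodulated frame,
    where the pulse axis is fixed and the effective precession per TR is
    θ = φ − ψ), samples the echo at TE, then relaxes/precesses over the
    remainder of the TR.  Starting from thermal equilibrium [0, 0, rho]
    the echo train oscillates and converges to ``ssfp_steady_state``.

    Returns an array of complex echoes with shape ``(n_tr,) + df.shape``.
    """
    if n_tr < 1:
        raise ValueError(f"n_tr must be >= 1, got {n_tr}")
    df, phi, theta = _angles(tissue, protocol, psi_deg, df_hz)
    e1 = np.exp(-protocol.tr_ms / tissue.t1_ms)
    e2 = np.exp(-protocol.tr_ms / tissue.t2_ms)
    a = np.deg2rad(protocol.flip_deg)
    ca, sa = np.cos(a), np.sin(a)
    shape = np.broadcast_shapes(np.shape(phi))
    mx = np.zeros(shape)
    my = np.zeros(shape)
    mz = np.full(shape, float(tissue.rho))
    if m_init is not None:
        mx = np.full(shape, float(m_init[0]))
        my = np.full(shape, float(m_init[1]))
        mz = np.full(shape, float(m_init[2]))
    te_phase = np.exp(1j * phi * protocol.te_ms / protocol.tr_ms)
    te_decay = np.exp(-protocol.te_ms / tissue.t2_ms)
    ct, st = np.cos(theta), np.sin(theta)
    echoes = np.empty((n_tr,) + shape, dtype=complex)
    for n in range(n_tr):
        # alpha pulse about the (demodulated-frame) x axis
        my, mz = ca * my + sa * mz, -sa * my + ca * mz
        # -i: receiver reference aligns the x-pulse echo with the closed form
        echoes[n] = -1j * (mx + 1j * my) * te_phase * te_decay
        # free precession by theta + relaxation over one TR
        mx, my = e2 * (ct * mx - st * my), e2 * (st * mx + ct * my)
        mz = e1 * mz + tissue.rho * (1.0 - e1)
    return echoes


def inflow_signal(flow: FlowSpec, protocol: ScanProtocol, psi_deg: float,
                  df_hz=None) -> np.ndarray:
    """Per-frame magnitude of a voxel refreshed by through-plane flow.

    Plug flow replaces the slice contents continuously; a voxel holds spin
    cohorts that entered 1..n_dwell TRs ago, where n_dwell(f) is the number
    of TRs a spin needs to cross the slice at the frame's speed.  The voxel
    magnitude is the mean transient-echo magnitude over those cohorts, each
    starting from thermal equilibrium.  Slow or zero flow recovers the
    stationary steady-state magnitude.

    Returns shape ``(n_frames,) + df.shape``.
    """
    df = np.asarray(flow.tissue.df_hz if df_hz is None else df_hz, dtype=float)
    v = np.abs(flow.velocity_mm_s)
    tr_s = protocol.tr_s
    # TRs needed to cross the slice; settled spins are at steady state
    n_settle = int(np.ceil(5.0 * flow.tissue.t1_ms / protocol.tr_ms))
    with np.errstate(divide="ignore"):
        dwell = np.where(
            v > 0,
            np.maximum(1, np.round(flow.slice_thickness_mm / np.maximum(v * tr_s, 1e-12))),
            np.inf,
        )
    dwell = np.where(dwell > n_settle, np.inf, dwell)
    ss_mag = np.abs(ssfp_steady_state(flow.tissue, protocol, psi_deg, df_hz=df))
    finite = dwell[np.isfinite(dwell)]
    out = np.empty((len(v),) + df.shape)
    if finite.size:
        n_max = int(finite.max())
        mags = np.abs(bloch_transient(flow.tissue, protocol, psi_deg,
                                      n_tr=n_max, df_hz=df))
        cummean = np.cumsum(mags, axis=0) / np.arange(1, n_max + 1).reshape(
            (-1,) + (1,) * df.ndim)
    for f, d in enumerate(dwell):
        out[f] = ss_mag if not np.isfinite(d) else cummean[int(d) - 1]
    return out


def band_null_offset(protocol: ScanProtocol, psi_deg: float) -> float:
    """Off-resonance frequency (Hz) of the banding null, in [0, 1/TR).

    The magnitude minimum sits at θ = 0, i.e. Δf = ψ/(360°·TR); nulls of ψ
    and ψ+180° are separated by exactly 1/(2TR).
    """
    period = 1.0 / protocol.tr_s
    return ((psi_deg % 360.0) / 360.0) * period % period
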