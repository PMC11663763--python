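"""Synthetic phase-cycled cardiac cine phantom.

Renders 2D+time magnitude movies of simple ellipse-based short-axis and
left-atrial-like scenes through the bSSFP steady-state signal model: each
static voxel carries its tissue's closed-form magnitude at the voxel's
off-resonance, flow regions carry the transient inflow magnitude, ellipses
contract sinusoidally over the cardiac cycle, and Rician noise is applied as
the magnitude of the signal plus complex Gaussian noise.  Each rendered set
includes a matched artifact-free reference (every voxel evaluated at the
mid-passband, flow rendered stationary, noise-free) and named ROI masks, so
the phantom doubles as ground truth for training and for quality metrics.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protocol import ScanProtocol
from .signal_model import FlowSpec, TissueParams, inflow_signal, ssfp_steady_state

__all__ = [
    "Ellipse",
    "TissueRegion",
    "FlowRegion",
    "B0Spec",
    "PhantomConfig",
    "CineMeta",
    "CineMovie",
    "PhaseCycledSet",
    "make_b0_map",
    "render_phase_cycled_cine",
    "make_default_scene",
    "sample_scene",
]

PRESETS = ("lv_short_axis", "la_view")


@dataclass
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates: center (row, col), semi-axes."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def mask(self, grid: tuple[int, int], scale: float = 1.0) -> np.ndarray:
        yy, xx = np.mgrid[0: grid[0], 0: grid[1]]
        ay, ax = self.axes[0] * scale, self.axes[1] * scale
        return ((yy - self.center[0]) / max(ay, 1e-9)) ** 2 + (
            (xx - self.center[1]) / max(ax, 1e-9)
        ) ** 2 <= 1.0


@dataclass
class TissueRegion:
    shape: Ellipse
    tissue: TissueParams
    contraction: float = 0.0  # peak fractional shrink of the semi-axes at systole


@dataclass
class FlowRegion:
    shape: Ellipse
    flow: FlowSpec
    contraction: float = 0.0


@dataclass
class B0Spec:
    """Off-resonance field: 2nd-order polynomial background + focal Gaussian.

    ``poly`` holds coefficients (c0, cy, cx, cyy, cxx, cyx) of
    c0 + cy·v + cx·u + cyy·v² + cxx·u² + cyx·u·v in Hz, with u, v the
    column/row coordinates normalized to [−1, 1].  The focal term adds
    ``focal_amp_hz · exp(−r²/(2·focal_width_px²))`` around focal_center.
    """

    poly: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    focal_amp_hz: float = 0.0
    focal_center: tuple[float, float] = (0.0, 0.0)
    focal_width_px: float = 1.0


@dataclass
class PhantomConfig:
    grid: tuple[int, int] = (128, 128)
    n_frames: int = 12
    regions: list = field(default_factory=list)
    b0: B0Spec = field(default_factory=B0Spec)
    flow_regions: list = field(default_factory=list)
    noise_sigma: float = 0.0  # complex-Gaussian std relative to peak tissue signal
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 16:
            raise ValueError("grid dimensions must be >= 16")
        if self.n_frames < 4:
            raise ValueError("need at least 4 cardiac frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class CineMeta:
    psi_deg: float
    tr_ms: float
    te_ms: float
    flip_deg: float
    frame_duration_ms: float
    kind: str = "bssfp"  # bssfp | reference | average | spc | network

    def to_dict(self) -> dict:
        return dict(psi_deg=self.psi_deg, tr_ms=self.tr_ms, te_ms=self.te_ms,
                    flip_deg=self.flip_deg,
                    frame_duration_ms=self.frame_duration_ms, kind=self.kind)

    @classmethod
    def from_dict(cls, d: dict) -> "CineMeta":
        keys = ("psi_deg", "tr_ms", "te_ms", "flip_deg", "frame_duration_ms", "kind")
        return cls(**{k: d[k] for k in keys if k in d})


@dataclass
class CineMovie:
    """A 2D+time magnitude image stack, in-memory axis order (t, y, x)."""

    data: np.ndarray
    meta: CineMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"cine data must be 3D (t, y, x), got {self.data.ndim}D")
        if np.any(self.data < 0):
            raise ValueError("magnitude movie must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class PhaseCycledSet:
    """Co-registered movies differing only in ψ, plus reference and ROI masks."""

    movies: list
    reference: Optional[CineMovie] = None
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.data.shape for m in self.movies}
        if self.reference is not None:
            shapes.add(self.reference.data.shape)
        if len(shapes) > 1:
            raise ValueError(f"movies do not share geometry: {shapes}")

    def movie(self, psi_deg: float) -> CineMovie:
        for m in self.movies:
            if abs((m.meta.psi_deg - psi_deg) % 360.0) < 1e-6:
                return m
        raise KeyError(f"no movie with psi={psi_deg} deg")


def make_b0_map(config: PhantomConfig) -> np.ndarray:
    """Deterministic off-resonance map in Hz, shape = config.grid."""
    rows, cols = config.grid
    v, u = np.mgrid[0:rows, 0:cols].astype(float)
    v = 2.0 * v / (rows - 1) - 1.0
    u = 2.0 * u / (cols - 1) - 1.0
    c0, cy, cx, cyy, cxx, cyx = config.b0.poly
    b0 = c0 + cy * v + cx * u + cyy * v * v + cxx * u * u + cyx * u * v
    if config.b0.focal_amp_hz != 0.0:
        fy, fx = config.b0.focal_center
        yy, xx = np.mgrid[0:rows, 0:cols].astype(float)
        r2 = (yy - fy) ** 2 + (xx - fx) ** 2
        b0 = b0 + config.b0.focal_amp_hz * np.exp(-r2 / (2.0 * config.b0.focal_width_px ** 2))
    return b0


def _contraction_schedule(n_frames: int) -> np.ndarray:
    # 0 at end-diastole (frame 0), 1 at mid-cycle systole, back to 0
    f = np.arange(n_frames)
    return np.sin(np.pi * f / n_frames) ** 2


def _render_one(config: PhantomConfig, protocol: ScanProtocol, psi_deg: float,
                b0: np.ndarray, reference: bool) -> np.ndarray:
    rows, cols = config.grid
    sched = _contraction_schedule(config.n_frames)
    frames = np.zeros((config.n_frames, rows, cols))

    # static-tissue magnitude maps are frame-independent; evaluate once per region
    tissue_maps = []
    for reg in config.regions:
        df = np.zeros_like(b0) if reference else b0
        tissue = reg.tissue
        if reference:
            tissue = TissueParams(tissue.t1_ms, tissue.t2_ms, tissue.rho, 0.0)
        psi = 180.0 if reference else psi_deg
        tissue_maps.append(np.abs(ssfp_steady_state(tissue, protocol, psi, df_hz=df)))

    flow_maps = []  # (n_frames, rows, cols) per flow region
    for reg in config.flow_regions:
        if reference:
            mag = np.abs(ssfp_steady_state(reg.flow.tissue, protocol, 180.0,
                                           df_hz=np.zeros_like(b0)))
            flow_maps.append(np.broadcast_to(mag, frames.shape))
        else:
            flow_maps.append(inflow_signal(reg.flow, protocol, psi_deg, df_hz=b0))

    for f in range(config.n_frames):
        img = frames[f]
        for reg, sig in zip(config.regions, tissue_maps):
            scale = 1.0 - reg.contraction * sched[f]
            m = reg.shape.mask(config.grid, scale)
            img[m] = sig[m]
        for reg, sig in zip(config.flow_regions, flow_maps):
            scale = 1.0 - reg.contraction * sched[f]
            m = reg.shape.mask(config.grid, scale)
            img[m] = sig[f][m]
    return frames


def render_phase_cycled_cine(config: PhantomConfig, protocol: ScanProtocol,
                             psis: Sequence[float]) -> PhaseCycledSet:
    """Render one phase-cycled set: one movie per ψ plus the clean reference.

    The reference is rendered with every voxel at the mid-passband (B0 map
    replaced by zero, ψ = 180°) and flow regions stationary, noise-free; it
    is therefore banding- and flow-artifact-free by construction and
    identical regardless of which ψ values are requested.
    """
    psis = list(psis)
    if not psis:
        raise ValueError("psis must be non-empty")
    if len({round(p % 360.0, 6) for p in psis}) != len(psis):
        raise ValueError(f"duplicate phase increments in {psis}")

    b0 = make_b0_map(config)
    frame_ms = protocol.views_per_segment * protocol.tr_ms
    ref_data = _render_one(config, protocol, 180.0, b0, reference=True)
    peak = float(ref_data.max()) or 1.0

    movies = []
    for idx, psi in enumerate(psis):
        clean = _render_one(config, protocol, psi, b0, reference=False)
        if config.noise_sigma > 0:
            rng = np.random.default_rng([config.seed, idx])
            sigma = config.noise_sigma * peak
            noisy = np.abs(clean + sigma * rng.standard_normal(clean.shape)
                           + 1j * sigma * rng.standard_normal(clean.shape))
        else:
            noisy = clean
        meta = CineMeta(psi_deg=float(psi), tr_ms=protocol.tr_ms,
                        te_ms=protocol.te_ms, flip_deg=protocol.flip_deg,
                        frame_duration_ms=frame_ms)
        movies.append(CineMovie(noisy, meta))

    ref = CineMovie(ref_data, CineMeta(psi_deg=180.0, tr_ms=protocol.tr_ms,
                                       te_ms=protocol.te_ms,
                                       flip_deg=protocol.flip_deg,
                                       frame_duration_ms=frame_ms,
                                       kind="reference"))
    masks = _preset_masks(config)
    return PhaseCycledSet(movies=movies, reference=ref, masks=masks)


def _preset_masks(config: PhantomConfig) -> dict:
    """ROI masks derived from the scene geometry (end-diastolic shapes)."""
    from .metrics import ROIMask  # local import to avoid a cycle

    masks: dict = {}
    named = getattr(config, "_mask_shapes", None)
    if not named:
        return masks
    for label, ell in named.items():
        masks[label] = ROIMask(ell.mask(config.grid), label=label)
    return masks


# ---------------------------------------------------------------------------
# presets


def _testing_protocol() -> ScanProtocol:
    return ScanProtocol(tr_ms=2.98, te_ms=1.37, flip_deg=60.0,
                        views_per_segment=24, n_cardiac_phases=25,
                        phase_increments_deg=[90.0, 270.0])


_MYO = dict(t1_ms=1200.0, t2_ms=45.0, rho=0.8)
_BLOOD = dict(t1_ms=1900.0, t2_ms=250.0, rho=1.0)
_MUSCLE = dict(t1_ms=1000.0, t2_ms=40.0, rho=0.6)
_FAT = dict(t1_ms=380.0, t2_ms=120.0, rho=0.9)


def make_default_scene(preset: str, grid: tuple[int, int] = (128, 128),
                       n_frames: int = 12, seed: int = 0,
                       noise_sigma: float = 0.02
                       ) -> tuple[PhantomConfig, ScanProtocol]:
    """Fully populated scene configuration for a named preset.

    ``lv_short_axis`` emulates a mid-ventricular short-axis view: chest wall,
    LV myocardium and blood pool, and a descending-aorta-like flow region,
    with a smooth background field plus a focal gradient that lays a band
    across the heart.  ``la_view`` emulates an atrial view where a strong
    focal off-resonance sits on the blood-pool ROI, so a single 180° movie
    shows a large-area signal void there.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    protocol = _testing_protocol()
    rows, cols = grid
    cy, cx = rows / 2.0, cols / 2.0
    s = min(rows, cols) / 128.0  # geometric scale relative to the default grid
    n = n_frames

    # pulsatile through-plane waveform, peak in systole (mm/s)
    vwave = 350.0 * _contraction_schedule(n) + 30.0

    if preset == "lv_short_axis":
        regions = [
            TissueRegion(Ellipse((cy, cx), (58 * s, 60 * s)), TissueParams(**_MUSCLE)),
            TissueRegion(Ellipse((cy - 40 * s, cx), (14 * s, 52 * s)), TissueParams(**_FAT)),
            TissueRegion(Ellipse((cy + 2 * s, cx - 6 * s), (30 * s, 30 * s)),
                         TissueParams(**_MYO), contraction=0.10),
            TissueRegion(Ellipse((cy + 2 * s, cx - 6 * s), (19 * s, 19 * s)),
                         TissueParams(**_BLOOD), contraction=0.35),
        ]
        flow_regions = [
            FlowRegion(Ellipse((cy + 34 * s, cx + 30 * s), (7 * s, 7 * s)),
                       FlowSpec(velocity_mm_s=vwave, slice_thickness_mm=8.0,
                                tissue=TissueParams(**_BLOOD, df_hz=0.0))),
        ]
        b0 = B0Spec(poly=(20.0, 35.0, 55.0, 0.0, 25.0, 0.0),
                    focal_amp_hz=150.0, focal_center=(cy + 8 * s, cx + 6 * s),
                    focal_width_px=26.0 * s)
        mask_shapes = {
            "heart": Ellipse((cy + 2 * s, cx - 6 * s), (32 * s, 32 * s)),
            "blood_pool": Ellipse((cy + 2 * s, cx - 6 * s), (14 * s, 14 * s)),
            "flow": Ellipse((cy + 34 * s, cx + 30 * s), (6 * s, 6 * s)),
        }
    else:  # la_view
        regions = [
            TissueRegion(Ellipse((cy, cx), (58 * s, 60 * s)), TissueParams(**_MUSCLE)),
            TissueRegion(Ellipse((cy + 6 * s, cx), (30 * s, 38 * s)),
                         TissueParams(**_MYO), contraction=0.06),
            TissueRegion(Ellipse((cy + 6 * s, cx), (24 * s, 32 * s)),
                         TissueParams(**_BLOOD), contraction=0.12),
        ]
        flow_regions = [
            FlowRegion(Ellipse((cy - 24 * s, cx + 28 * s), (6 * s, 6 * s)),
                       FlowSpec(velocity_mm_s=0.6 * vwave, slice_thickness_mm=8.0,
                                tissue=TissueParams(**_BLOOD, df_hz=0.0))),
        ]
        # strong focal off-resonance centered on the LA blood pool:
        # ~170 Hz reaches the psi=180 null (1/(2TR) = 167.8 Hz) at its peak
        b0 = B0Spec(poly=(10.0, 20.0, 30.0, 0.0, 0.0, 0.0),
                    focal_amp_hz=175.0, focal_center=(cy + 6 * s, cx + 4 * s),
                    focal_width_px=30.0 * s)
        mask_shapes = {
            "heart": Ellipse((cy + 6 * s, cx), (32 * s, 40 * s)),
            "blood_pool": Ellipse((cy + 6 * s, cx), (20 * s, 27 * s)),
            "pv_ostium": Ellipse((cy - 24 * s, cx + 28 * s), (5 * s, 5 * s)),
            "flow": Ellipse((cy - 24 * s, cx + 28 * s), (5 * s, 5 * s)),
        }

    config = PhantomConfig(grid=grid, n_frames=n, regions=regions, b0=b0,
                           flow_regions=flow_regions, noise_sigma=noise_sigma,
                           seed=seed)
    config._mask_shapes = mask_shapes  # carried for ROI generation
    return config, protocol


def sample_scene(preset: str, seed: int, grid: tuple[int, int] = (64, 64),
                 n_frames: int = 8, noise_sigma: float = 0.02
                 ) -> tuple[PhantomConfig, ScanProtocol]:
    """Randomized variant of a preset scene for building training corpora.

    Jitters region positions and sizes, the background field, and the focal
    off-resonance amplitude/position so each scene presents the bands and
    flow artifacts at different locations and severities.
    """
    rng = np.random.default_rng(seed)
    config, protocol = make_default_scene(preset, grid=grid, n_frames=n_frames,
                                          seed=seed, noise_sigma=noise_sigma)
    config = copy.deepcopy(config)
    s = min(grid) / 128.0
    jit = lambda lo, hi: float(rng.uniform(lo, hi))

    for reg in config.regions + config.flow_regions:
        dy, dx = rng.uniform(-4 * s, 4 * s, size=2)
        reg.shape.center = (reg.shape.center[0] + dy, reg.shape.center[1] + dx)
        f = jit(0.85, 1.15)
        reg.shape.axes = (reg.shape.axes[0] * f, reg.shape.axes[1] * f)
    # rebuild masks from the (jittered) anatomy
    heart = config.regions[2].shape if preset == "lv_short_axis" else config.regions[1].shape
    blood = config.regions[3].shape if preset == "lv_short_axis" else config.regions[2].shape
    config._mask_shapes = {
        "heart": Ellipse(heart.center, (heart.axes[0] * 1.06, heart.axes[1] * 1.06)),
        "blood_pool": Ellipse(blood.center, (blood.axes[0] * 0.75, blood.axes[1] * 0.75)),
        "flow": Ellipse(config.flow_regions[0].shape.center,
                        (config.flow_regions[0].shape.axes[0] * 0.9,
                         config.flow_regions[0].shape.axes[1] * 0.9)),
    }

    # field sampled so that the banding nulls (±1/(4TR) for the 90/270 pair)
    # are crossed within or near the heart in most draws, as deliberately
    # unshimmed 3 T chest fields do
    b0 = config.b0
    config.b0 = B0Spec(
        poly=(jit(-40, 40), jit(-75, 75), jit(-75, 75), jit(-25, 25),
              jit(-25, 25), jit(-20, 20)),
        focal_amp_hz=jit(230.0, 320.0) * (1 if rng.random() < 0.7 else -1),
        focal_center=(heart.center[0] + jit(-8 * s, 8 * s),
                      heart.center[1] + jit(-8 * s, 8 * s)),
        focal_width_px=b0.focal_width_px * jit(0.7, 1.4),
    )
    config.flow_regions[0].flow.velocity_mm_s = (
        np.asarray(config.flow_regions[0].flow.velocity_mm_s) * jit(0.5, 1.5))
    config.seed = int(rng.integers(0, 2**31 - 1))
    return config, protocol
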