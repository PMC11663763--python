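"""Classical magnitude combinations of phase-cycled cine movies.

Averaging movies acquired with different RF phase increments flattens the
bSSFP magnitude response and thins the bands (the 2P average baseline);
short-range phase cycling (SPC) averages the five movies with increments
120°–240° after rigid registration and serves as the training label.  All
combination is done on magnitude images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import CineMeta, CineMovie

__all__ = ["RigidTransform", "average_combine", "rigid_register", "spc_label",
           "SPC_INCREMENTS"]

SPC_INCREMENTS = (120.0, 150.0, 180.0, 210.0, 240.0)


@dataclass
class RigidTransform:
    """In-plane rigid motion: translation (pixels) and rotation (degrees)."""

    dy: float = 0.0
    dx: float = 0.0
    angle_deg: float = 0.0
    degenerate: bool = False  # set when estimation fell back to identity

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.dy, self.dx, self.angle_deg])):
            raise ValueError("transform parameters must be finite")
        if abs(self.angle_deg) > 45:
            raise ValueError("rotation beyond 45 deg is not a plausible "
                             "breath-hold misregistration")


def _geometry_check(movies) -> None:
    shapes = {m.data.shape for m in movies}
    if len(shapes) != 1:
        raise ValueError(f"movies do not share geometry: {sorted(shapes)}")


def average_combine(movies) -> CineMovie:
    """Voxel-wise arithmetic mean of magnitude movies (the N-point average).

    Metadata records the contributing ψ values; with the two half-cycle-
    apart movies of a twofold acquisition this is the 2P average baseline.
    """
    if len(movies) < 1:
        raise ValueError("need at least one movie")
    _geometry_check(movies)
    data = np.mean([m.data for m in movies], axis=0)
    m0 = movies[0].meta
    meta = CineMeta(psi_deg=float(np.mean([m.meta.psi_deg for m in movies])),
                    tr_ms=m0.tr_ms, te_ms=m0.te_ms, flip_deg=m0.flip_deg,
                    frame_duration_ms=m0.frame_duration_ms, kind="average")
    out = CineMovie(data, meta)
    out.psis = [m.meta.psi_deg for m in movies]
    return out


def _ncc_translation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Translation (dy, dx) maximizing the cross-correlation of zero-mean
    images, integer peak + parabolic sub-pixel refinement."""
    a = a - a.mean()
    b = b - b.mean()
    ny, nx = a.shape
    fa = np.fft.rfft2(a, s=(2 * ny, 2 * nx))
    fb = np.fft.rfft2(b, s=(2 * ny, 2 * nx))
    corr = np.fft.irfft2(fa * np.conj(fb), s=(2 * ny, 2 * nx))
    corr = np.fft.fftshift(corr)
    py, px = np.unravel_index(np.argmax(corr), corr.shape)

    def _parabolic(c, i, n):
        if 0 < i < n - 1:
            den = c[i - 1] - 2 * c[i] + c[i + 1]
            if den != 0:
                return float(np.clip(0.5 * (c[i - 1] - c[i + 1]) / den, -0.5, 0.5))
        return 0.0

    sy = _parabolic(corr[:, px], py, corr.shape[0])
    sx = _parabolic(corr[py, :], px, corr.shape[1])
    dy = (py + sy) - ny
    dx = (px + sx) - nx
    return dy, dx


def rigid_register(moving: CineMovie, fixed: CineMovie,
                   max_rotation_deg: float = 0.0
                   ) -> tuple[RigidTransform, CineMovie]:
    """Estimate one rigid transform on the temporal means and resample.

    Breath-hold misregistration is constant within a movie, so a single
    transform is estimated from the temporal-mean images by maximizing
    normalized cross-correlation over translation (integer grid, then
    parabolic sub-pixel refinement), with an optional small-rotation grid
    search, and applied to every frame with linear interpolation.
    Degenerate (constant) images yield the identity transform with the
    ``degenerate`` flag set.
    """
    _geometry_check([moving, fixed])
    a = moving.data.mean(axis=0).astype(float)
    b = fixed.data.mean(axis=0).astype(float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("degenerate (constant) image; returning identity transform")
        return RigidTransform(degenerate=True), CineMovie(moving.data.copy(), moving.meta)

    best_angle = 0.0
    if max_rotation_deg > 0:
        def score(angle):
            rot = ndimage.rotate(a, angle, reshape=False, order=1)
            dy, dx = _ncc_translation(b, rot)
            shifted = ndimage.shift(rot, (dy, dx), order=1)
            za, zb = shifted - shifted.mean(), b - b.mean()
            return float((za * zb).sum() / (np.linalg.norm(za) * np.linalg.norm(zb) + 1e-12))
        angles = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, 0.5)
        best_angle = float(angles[int(np.argmax([score(t) for t in angles]))])
    rot = a if best_angle == 0.0 else ndimage.rotate(a, best_angle, reshape=False, order=1)
    dy, dx = _ncc_translation(b, rot)
    # sanity-check the fit: images sharing no structure (e.g. pure noise)
    # give a vanishing correlation peak and fall back to identity
    shifted = ndimage.shift(rot, (dy, dx), order=1)
    za, zb = shifted - shifted.mean(), b - b.mean()
    ncc = float((za * zb).sum()
                / (np.linalg.norm(za) * np.linalg.norm(zb) + 1e-12))
    if ncc < 0.2:
        warnings.warn(f"correlation peak too weak (NCC={ncc:.3f}); "
                      "returning identity transform")
        return RigidTransform(degenerate=True), CineMovie(moving.data.copy(),
                                                          moving.meta)
    tform = RigidTransform(dy=dy, dx=dx, angle_deg=best_angle)

    frames = moving.data.astype(float)
    if best_angle != 0.0:
        frames = np.stack([ndimage.rotate(f, best_angle, reshape=False, order=1)
                           for f in frames])
    frames = np.stack([ndimage.shift(f, (dy, dx), order=1, mode="nearest")
                       for f in frames])
    out = CineMovie(np.clip(frames, 0.0, None), moving.meta)
    return tform, out


def spc_label(movies) -> CineMovie:
    """Short-range phase-cycling label: register to the 180° movie, average.

    Requires exactly the five movies with increments 120°, 150°, 180°,
    210° and 240° (any order).  Each non-180° movie is rigidly registered
    to the 180° movie before the voxel-wise mean is taken; the result is
    flagged as an SPC label in its metadata.
    """
    got = sorted(round(m.meta.psi_deg % 360.0, 6) for m in movies)
    want = sorted(SPC_INCREMENTS)
    if got != want:
        missing = sorted(set(want) - set(got))
        extra = sorted(set(got) - set(want))
        raise ValueError(
            f"SPC needs increments {want}; missing {missing}, extra {extra}")
    _geometry_check(movies)
    target = next(m for m in movies
                  if abs(m.meta.psi_deg % 360.0 - 180.0) < 1e-6)
    aligned = []
    for m in movies:
        if m is target:
            aligned.append(m)
        else:
            _, resampled = rigid_register(m, target)
            aligned.append(resampled)
    out = average_combine(aligned)
    out.meta.kind = "spc"
    return out
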