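"""Phase-cycled bSSFP scan protocol: timing, schedules and pair combinatorics.

A twofold phase-cycled (2P-SSFP) cine acquisition runs two retrospectively
gated cine movies back to back in one breath-hold, the second with an RF
phase increment a half cycle (180°) away from the first.  Each movie is
preceded by a dummy heartbeat that drives the magnetization toward steady
state.  This module models that schedule at heartbeat granularity and
enumerates the training-pair combinatorics used when a network is trained on
pairs of phase-cycled movies drawn from a full 12-point phase-cycle set.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

__all__ = [
    "ScanProtocol",
    "phase_schedule",
    "enumerate_training_pairs",
    "scan_duration_beats",
    "temporal_resolution_ms",
]

_DEG_TOL = 1e-6


@dataclass
class ScanProtocol:
    """Sequence timing and segmentation parameters of a cine bSSFP scan.

    Parameters
    ----------
    tr_ms, te_ms : float
        Repetition and echo time in milliseconds; ``tr_ms > te_ms > 0``.
    flip_deg : float
        Excitation flip angle in degrees, in (0, 90].
    views_per_segment : int
        k-space lines acquired per heartbeat per cardiac phase; the product
        ``views_per_segment * tr_ms`` is the temporal resolution.
    n_cardiac_phases : int
        Number of reconstructed cine frames.
    n_movies : int
        Movies acquired sequentially within the breath-hold (2 for 2P-SSFP).
    dummy_beats_per_movie, imaging_beats_per_movie : int
        Un-sampled steady-state preparation beats and sampled beats per movie.
    phase_increments_deg : list of float
        RF phase increments of the movies, degrees in (0, 360].
    """

    tr_ms: float
    te_ms: float
    flip_deg: float
    views_per_segment: int = 16
    n_cardiac_phases: int = 25
    n_movies: int = 2
    dummy_beats_per_movie: int = 1
    imaging_beats_per_movie: int = 5
    phase_increments_deg: list = field(default_factory=lambda: [90.0, 270.0])

    def __post_init__(self) -> None:
        if not (self.tr_ms > self.te_ms > 0):
            raise ValueError(
                f"require tr_ms > te_ms > 0, got TR={self.tr_ms}, TE={self.te_ms}"
            )
        if not (0 < self.flip_deg <= 90):
            raise ValueError(f"flip angle must be in (0, 90] deg, got {self.flip_deg}")
        for name in ("views_per_segment", "n_cardiac_phases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        psis = self.phase_increments_deg
        if any(not (0 < p <= 360 + _DEG_TOL) for p in psis):
            raise ValueError(f"phase increments must lie in (0, 360], got {psis}")
        if self.n_movies == 2 and len(psis) == 2:
            d = (psis[1] - psis[0]) % 360.0
            if abs(d - 180.0) > _DEG_TOL:
                raise ValueError(
                    "twofold protocol requires increments 180 deg apart "
                    f"(mod 360), got {psis}"
                )

    @property
    def tr_s(self) -> float:
        return self.tr_ms * 1e-3

    # -- JSON sidecar -----------------------------------------------------
    _SIDE_KEYS = (
        "tr_ms", "te_ms", "flip_deg", "views_per_segment", "n_cardiac_phases",
        "phase_increments_deg", "dummy_beats_per_movie", "imaging_beats_per_movie",
    )

    def to_sidecar(self) -> dict:
        d = asdict(self)
        return {k: d[k] for k in self._SIDE_KEYS} | {"n_movies": self.n_movies}

    @classmethod
    def from_sidecar(cls, d: dict) -> "ScanProtocol":
        known = {k: d[k] for k in cls._SIDE_KEYS if k in d}
        if "n_movies" in d:
            known["n_movies"] = d["n_movies"]
        return cls(**known)

    def save(self, path: str | os.PathLike) -> None:
        tmp = f"{path}.tmp"
        with open(tmp, "w") as fh:
            json.dump(self.to_sidecar(), fh, indent=1)
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ScanProtocol":
        with open(path) as fh:
            return cls.from_sidecar(json.load(fh))


def phase_schedule(n_increments: int) -> list[float]:
    """Uniform RF phase increment schedule ψ_n = 360°·n/N, n = 1..N.

    Values lie in (0, 360]; the last entry is 360° (equivalent to 0°).
    """
    if not isinstance(n_increments, int) or n_increments < 1:
        raise ValueError(f"n_increments must be a positive integer, got {n_increments}")
    return [360.0 * n / n_increments for n in range(1, n_increments + 1)]


def _spacing_of(increments: Sequence[float]) -> float:
    vals = sorted(p % 360.0 for p in increments)
    if len(vals) < 2:
        return 360.0
    gaps = {round(b - a, 6) for a, b in zip(vals, vals[1:])}
    gaps.add(round(vals[0] + 360.0 - vals[-1], 6))
    if len(gaps) != 1:
        raise ValueError(f"increments are not uniformly spaced: {sorted(vals)}")
    return gaps.pop()


def enumerate_training_pairs(
    increments: Sequence[float],
    offsets: Iterable[float],
    n_slice_sets: int,
) -> tuple[list[tuple[int, float, float]], dict[float, int]]:
    """Enumerate training pairs of phase-cycled movies across slice-sets.

    For each slice-set, every ordered pair (ψi, ψj), i ≠ j, whose offset
    (ψj − ψi) mod 360 is in ``offsets`` is emitted — except that pairs at
    offset exactly 180° are deduplicated to unordered pairs, because an
    order-invariant (symmetrized) network makes the two orderings redundant
    while a 90° and the reversed 270° pairing present genuinely different
    offsets.

    Returns ``(pairs, counts)`` where ``pairs`` is a list of
    ``(slice_set_index, psi_i, psi_j)`` and ``counts`` maps each offset to
    its total pair count.

    With the 12-point schedule, offsets {90, 180, 270} and 54 slice-sets
    (18 subjects × 3 slices) this reproduces 1620 pairs: 648 + 324 + 648.
    """
    if n_slice_sets < 0:
        raise ValueError("n_slice_sets must be non-negative")
    if len(increments) < 2:
        return [], {o % 360.0: 0 for o in offsets}
    spacing = _spacing_of(increments)
    offs = []
    for o in offsets:
        om = o % 360.0
        if om == 0.0 or abs(om / spacing - round(om / spacing)) > 1e-9:
            raise ValueError(
                f"offset {o} deg is not a nonzero multiple of the spacing {spacing}"
            )
        offs.append(om)
    offs = sorted(set(offs))

    per_set: list[tuple[float, float, float]] = []  # (offset, psi_i, psi_j)
    for i, pi in enumerate(increments):
        for j, pj in enumerate(increments):
            if i == j:
                continue
            d = round((pj - pi) % 360.0, 6)
            if d not in offs:
                continue
            if abs(d - 180.0) < _DEG_TOL and (pi % 360.0) > (pj % 360.0):
                continue  # unordered at the half cycle
            per_set.append((d, pi, pj))

    pairs = [
        (s, pi, pj)
        for s in range(n_slice_sets)
        for (_, pi, pj) in per_set
    ]
    counts = {o: n_slice_sets * sum(1 for d, *_ in per_set if d == o) for o in offs}
    return pairs, counts


def scan_duration_beats(protocol: ScanProtocol) -> int:
    """Total breath-hold length in heartbeats (dummy + imaging, all movies)."""
    return protocol.n_movies * (
        protocol.dummy_beats_per_movie + protocol.imaging_beats_per_movie
    )


def temporal_resolution_ms(protocol: ScanProtocol) -> float:
    """Cine temporal resolution: views per segment × TR, in milliseconds."""
    return protocol.views_per_segment * protocol.tr_ms
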