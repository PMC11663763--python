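"""NIfTI cine I/O with JSON sidecars, and dataset manifests.

Movies are stored as 3D NIfTI volumes with on-disk axis order (x, y, t) and
float32 intensities; acquisition metadata (RF phase increment, TR/TE, flip
angle, frame duration) travels in a JSON sidecar next to the image file.
In memory the axis order is (t, y, x).  All writes are atomic (temp file +
rename) so interrupted runs never leave truncated files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .metrics import ROIMask
from .phantom import CineMeta, CineMovie, PhaseCycledSet

__all__ = ["CineFormatError", "read_cine", "write_cine", "read_mask",
           "write_mask", "DatasetManifest", "write_set", "read_set"]

log = logging.getLogger("cinepc")


class CineFormatError(ValueError):
    """Raised when a file does not hold a 2D+time cine volume."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def _atomic_save(img: nib.Nifti1Image, path: Path) -> None:
    tmp = path.parent / (".tmp." + path.name)
    nib.save(img, str(tmp))
    os.replace(tmp, path)


def write_cine(path: str | os.PathLike, movie: CineMovie) -> None:
    """Write a movie as NIfTI (x, y, t) plus a JSON metadata sidecar."""
    path = Path(path)
    data = np.asarray(movie.data, dtype=np.float32).transpose(2, 1, 0)  # x,y,t
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_xyzt_units("mm", "msec")
    _atomic_save(img, path)
    side = _sidecar_path(path)
    tmp = side.parent / (".tmp." + side.name)
    with open(tmp, "w") as fh:
        json.dump(movie.meta.to_dict(), fh, indent=1)
    os.replace(tmp, side)


def read_cine(path: str | os.PathLike) -> CineMovie:
    """Read a cine NIfTI + sidecar; singleton 4th axes are squeezed."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        log.info("squeezing singleton 4th axis of %s", path)
        data = data[..., 0]
    if data.ndim != 3:
        raise CineFormatError(
            f"{path} has {data.ndim} axes; expected 3 (x, y, t)")
    side = _sidecar_path(path)
    if side.exists():
        with open(side) as fh:
            meta = CineMeta.from_dict(json.load(fh))
    else:
        log.warning("no sidecar for %s; using default metadata", path)
        meta = CineMeta(psi_deg=180.0, tr_ms=2.98, te_ms=1.37, flip_deg=60.0,
                        frame_duration_ms=71.52)
    return CineMovie(np.maximum(data.transpose(2, 1, 0), 0.0), meta)


def write_mask(path: str | os.PathLike, mask: ROIMask) -> None:
    path = Path(path)
    data = np.asarray(mask.data, dtype=np.uint8)
    if data.ndim == 2:
        data = data.T  # (x, y)
    else:
        data = data.transpose(2, 1, 0)
    _atomic_save(nib.Nifti1Image(data, affine=np.eye(4)), path)


def read_mask(path: str | os.PathLike, label: str = "roi") -> ROIMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        return ROIMask(data.T.astype(bool), label=label)
    if data.ndim == 3:
        return ROIMask(data.transpose(2, 1, 0).astype(bool), label=label)
    raise CineFormatError(f"{path} has {data.ndim} axes; expected 2 or 3")


@dataclass
class DatasetManifest:
    """Index of one or more rendered phase-cycled scenes on disk.

    Each entry maps a scene id to its movie files (keyed by ψ in degrees),
    the reference movie, mask files (keyed by label) and a protocol sidecar.
    """

    entries: list = field(default_factory=list)
    seed: int = 0
    preset: str = ""
    schema_version: int = 1

    def add_scene(self, scene_id: str, movies: dict, reference: str | None,
                  masks: dict, protocol: str) -> None:
        self.entries.append(dict(scene_id=scene_id, movies=movies,
                                 reference=reference, masks=masks,
                                 protocol=protocol))

    def save(self, path: str | os.PathLike) -> None:
        path = Path(path)
        tmp = path.parent / (".tmp." + path.name)
        with open(tmp, "w") as fh:
            json.dump(dict(schema_version=self.schema_version, seed=self.seed,
                           preset=self.preset, entries=self.entries), fh, indent=1)
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DatasetManifest":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh)
        m = cls(entries=d["entries"], seed=d.get("seed", 0),
                preset=d.get("preset", ""), schema_version=d.get("schema_version", 1))
        base = path.parent
        for e in m.entries:
            psis = [round(float(p) % 360.0, 6) for p in e["movies"]]
            if len(set(psis)) != len(psis):
                raise ValueError(f"scene {e['scene_id']}: duplicate psi values")
            for f in list(e["movies"].values()) + list(e["masks"].values()) \
                    + [e["reference"], e["protocol"]]:
                if f and not (base / f).exists():
                    raise FileNotFoundError(base / f)
        return m


def write_set(out_dir: str | os.PathLike, pc_set: PhaseCycledSet, protocol,
              scene_id: str = "scene_000", manifest: DatasetManifest | None = None
              ) -> DatasetManifest:
    """Write one phase-cycled set (movies, reference, masks, protocol) and
    register it in a manifest (created if not given; caller saves it)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest or DatasetManifest()
    movies = {}
    for m in pc_set.movies:
        fname = f"{scene_id}_psi{m.meta.psi_deg:g}.nii.gz"
        write_cine(out / fname, m)
        movies[f"{m.meta.psi_deg:g}"] = fname
    ref_name = None
    if pc_set.reference is not None:
        ref_name = f"{scene_id}_reference.nii.gz"
        write_cine(out / ref_name, pc_set.reference)
    masks = {}
    for label, mask in pc_set.masks.items():
        fname = f"{scene_id}_mask_{label}.nii.gz"
        write_mask(out / fname, mask)
        masks[label] = fname
    prot_name = f"{scene_id}_protocol.json"
    protocol.save(out / prot_name)
    manifest.add_scene(scene_id, movies, ref_name, masks, prot_name)
    return manifest


def read_set(manifest_path: str | os.PathLike, scene_id: str | None = None
             ) -> PhaseCycledSet:
    """Load one scene of a manifest back into a PhaseCycledSet."""
    manifest = DatasetManifest.load(manifest_path)
    base = Path(manifest_path).parent
    entry = manifest.entries[0] if scene_id is None else next(
        e for e in manifest.entries if e["scene_id"] == scene_id)
    movies = [read_cine(base / f) for f in entry["movies"].values()]
    ref = read_cine(base / entry["reference"]) if entry["reference"] else None
    masks = {lbl: read_mask(base / f, label=lbl)
             for lbl, f in entry["masks"].items()}
    return PhaseCycledSet(movies=movies, reference=ref, masks=masks)
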