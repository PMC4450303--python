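"""NIfTI volume / projection-set I/O with YAML metadata sidecars.

Volumes are stored as NIfTI-1 with the voxel size in the affine and
header zooms; axes are written in (x, y, z) order and reorientation to
the closest canonical frame is applied on load, so files written with a
permuted axis order read back consistently.  Projection sets get a
``<name>.meta.yaml`` sidecar holding the acquisition geometry, the angle
list and the noise flag, which makes the round trip lossless.
"""

from __future__ import annotations

import pathlib
import warnings

import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError, InvalidInputError
from .phantom import ActivityVolume
from .projector import AcquisitionSpec, ProjectionSet

__all__ = [
    "save_volume",
    "load_volume",
    "save_projections",
    "load_projections",
    "volume_io",
]


def _sidecar(path) -> pathlib.Path:
    p = pathlib.Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            name = name[: -len(suf)]
            break
    return p.with_name(name + ".meta.yaml")


def save_volume(volume: ActivityVolume, path) -> None:
    """Write an ActivityVolume as NIfTI ((z,y,x) array stored as (x,y,z))."""
    arr = np.asarray(volume.voxels, dtype=np.float64).T  # -> (x, y, z)
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path) -> ActivityVolume:
    """Read a NIfTI volume back into an ActivityVolume.

    The image is reoriented to the closest canonical axis order first,
    so the stored orientation is honoured.
    """
    try:
        img = nib.as_closest_canonical(nib.load(str(path)))
        arr = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path} is not a 3D volume")
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-6:
        warnings.warn("anisotropic voxels; using the first zoom as voxel size")
    return ActivityVolume(voxels=arr.T, voxel_size=float(zooms[0]))


def save_projections(proj: ProjectionSet, path) -> None:
    """Write a ProjectionSet as NIfTI (angle slowest) plus a YAML sidecar."""
    arr = np.asarray(proj.data, dtype=np.float64).T  # (bin, row, angle)
    g = proj.geometry
    affine = np.diag([g.bin_size, g.bin_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    meta = {
        "kind": "projection_set",
        "angles_deg": [float(a) for a in proj.angles],
        "noise_applied": bool(proj.noise_applied),
        "geometry": {
            "n_angles": g.n_angles,
            "arc_degrees": g.arc_degrees,
            "detector_bins": g.detector_bins,
            "bin_size": g.bin_size,
            "counts_per_projection": g.counts_per_projection,
        },
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_projections(path) -> ProjectionSet:
    """Read a projection set and its sidecar back into a ProjectionSet.

    A missing sidecar degrades gracefully: geometry defaults are derived
    from the array shape and a warning is issued.
    """
    try:
        arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if arr.ndim != 3:
        raise FormatError(f"{path} does not hold a projection stack")
    data = arr.T  # -> (angle, row, bin)
    side = _sidecar(path)
    if side.exists():
        meta = yaml.safe_load(side.read_text())
        g = meta["geometry"]
        geom = AcquisitionSpec(
            n_angles=int(g["n_angles"]),
            arc_degrees=float(g["arc_degrees"]),
            detector_bins=int(g["detector_bins"]),
            bin_size=float(g["bin_size"]),
            counts_per_projection=g.get("counts_per_projection"),
        )
        angles = np.asarray(meta["angles_deg"], dtype=float)
        noise = bool(meta["noise_applied"])
    else:
        warnings.warn(f"no metadata sidecar for {path}; assuming default geometry")
        geom = AcquisitionSpec(n_angles=data.shape[0], detector_bins=data.shape[2])
        angles = geom.angles
        noise = False
    return ProjectionSet(data=data, angles=angles, geometry=geom, noise_applied=noise)


def volume_io(path, mode: str, obj=None):
    """Unified read/write entry point for volumes and projection sets.

    ``mode='r'`` loads (a projection set when the metadata sidecar is
    present, a plain volume otherwise); ``mode='w'`` dispatches on the
    object type.
    """
    if mode == "r":
        if _sidecar(path).exists():
            return load_projections(path)
        return load_volume(path)
    if mode == "w":
        if isinstance(obj, ProjectionSet):
            save_projections(obj, path)
        elif isinstance(obj, ActivityVolume):
            save_volume(obj, path)
        else:
            raise InvalidInputError(f"cannot write object of type {type(obj)!r}")
        return obj
    raise InvalidInputError("mode must be 'r' or 'w'")
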