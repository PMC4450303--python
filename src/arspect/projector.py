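"""Ideal parallel-beam projector, count scaling and Poisson noise.

The projector models an ideal SPECT acquisition: no attenuation, no
scatter and perfect depth-independent resolution, so the only physics is
the line integral and (optionally) Poisson counting noise.

Projection is rotation-based: each transaxial slice is rotated by the
view angle with bilinear interpolation and summed along columns.  The
rotation is materialized as a sparse matrix, so its exact transpose is
available as the matched back projector — ordered-subset EM needs a
projector/back-projector pair that is adjoint to machine precision, or
the multiplicative updates drift.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .errors import ConfigurationError, InvalidInputError
from .phantom import ActivityVolume

__all__ = [
    "AcquisitionSpec",
    "ProjectionSet",
    "DEFAULT_ACQUISITION",
    "forward_project",
    "scale_counts",
    "simulate_counts",
    "projection_matrix",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Parallel-beam acquisition geometry.

    ``counts_per_projection`` is the expected total count in each
    projection image after scaling (None = leave projections in
    line-integral units).
    """

    n_angles: int = 120
    arc_degrees: float = 360.0
    detector_bins: int = 64
    bin_size: float = 4.0
    counts_per_projection: float | None = None

    def __post_init__(self):
        if self.n_angles < 1:
            raise ConfigurationError("n_angles must be >= 1")
        if not (0.0 < self.arc_degrees <= 360.0):
            raise ConfigurationError("arc_degrees must lie in (0, 360]")
        if self.detector_bins < 1:
            raise ConfigurationError("detector_bins must be >= 1")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")

    @property
    def angles(self) -> np.ndarray:
        """View angles in degrees, equally spaced over the arc."""
        return np.arange(self.n_angles) * (self.arc_degrees / self.n_angles)


DEFAULT_ACQUISITION = AcquisitionSpec()


@dataclass
class ProjectionSet:
    """Stack of projection images, indexed (angle, row, bin); rows are slices."""

    data: np.ndarray
    angles: np.ndarray
    geometry: AcquisitionSpec
    noise_applied: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError("projection data must be 3D (angle, row, bin)")
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("projection data contain non-finite values")
        if np.any(self.data < 0):
            raise InvalidInputError("projection data must be nonnegative")
        if self.data.shape[0] != len(self.angles):
            raise InvalidInputError("angle list does not match data")
        if len(self.angles) != self.geometry.n_angles:
            raise ConfigurationError("angle count does not match geometry")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    def totals(self) -> np.ndarray:
        """Total counts of each projection image."""
        return self.data.sum(axis=(1, 2))


@functools.lru_cache(maxsize=1024)
def projection_matrix(n: int, angle_deg: float) -> sp.csr_matrix:
    """Sparse (n x n^2) voxel-driven parallel projection at one angle.

    Each voxel's centre is mapped to its detector coordinate
    ``t = sin(th)*di + cos(th)*dj`` (pixel units about the grid centre)
    and its value is split linearly between the two adjacent bins.  The
    per-voxel weights sum to one, so any activity inside the detector
    range is counted exactly once at every angle; the matrix transpose
    is the exact adjoint — the classic interpolating back projector.
    """
    c = (n - 1) / 2.0
    th = np.deg2rad(angle_deg)
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    t = (np.sin(th) * (ii - c) + np.cos(th) * (jj - c) + c).ravel()
    j0 = np.floor(t).astype(int)
    f = t - j0
    src = np.arange(n * n)
    rows, cols, vals = [], [], []
    for bins, w in ((j0, 1.0 - f), (j0 + 1, f)):
        ok = (bins >= 0) & (bins < n) & (w > 0)
        rows.append(bins[ok])
        cols.append(src[ok])
        vals.append(w[ok])
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n * n),
    )
    return mat.tocsr()


def _project_slices(slices_flat: np.ndarray, n: int, angle_deg: float) -> np.ndarray:
    """Project flattened slices (n^2, nslices) at one angle -> (nslices, nbins)."""
    return (projection_matrix(n, float(angle_deg)) @ slices_flat).T


def _backproject_slices(profiles: np.ndarray, n: int, angle_deg: float) -> np.ndarray:
    """Adjoint of :func:`_project_slices`: (nslices, nbins) -> (n^2, nslices)."""
    return projection_matrix(n, float(angle_deg)).T @ profiles.T


def forward_project(volume: ActivityVolume, acq: AcquisitionSpec) -> ProjectionSet:
    """Noise-free parallel-beam projection of a volume.

    Each transaxial slice is projected independently; row ``r`` of every
    projection image corresponds to slice ``r`` of the volume.  Totals
    are conserved per angle because rotation keeps the activity inside
    the grid (the phantom body is inscribed in the field of view).
    """
    vox = volume.voxels
    n = vox.shape[1]
    if vox.shape[2] != n:
        raise ConfigurationError("transaxial slices must be square")
    if n != acq.detector_bins:
        raise ConfigurationError(
            f"in-plane matrix {n} does not match detector_bins {acq.detector_bins}"
        )
    if abs(volume.voxel_size - acq.bin_size) > 1e-9:
        raise ConfigurationError("voxel size and detector bin size must match")
    nz = vox.shape[0]
    flat = vox.reshape(nz, n * n).T
    data = np.empty((acq.n_angles, nz, n))
    for a, ang in enumerate(acq.angles):
        data[a] = _project_slices(flat, n, ang)
    data = np.clip(data, 0.0, None)  # interpolation can leave tiny negatives
    return ProjectionSet(data=data, angles=acq.angles, geometry=acq, noise_applied=False)


def scale_counts(proj: ProjectionSet, counts_per_projection: float) -> ProjectionSet:
    """Scale each projection image so its total equals ``counts_per_projection``.

    Per-projection normalization: every view carries the same expected
    count regardless of how much of the object its rows intersect.
    """
    if counts_per_projection <= 0:
        raise InvalidInputError("counts_per_projection must be positive")
    totals = proj.totals()
    if np.any(totals <= 0):
        raise InvalidInputError("cannot scale projections with zero total")
    scaled = proj.data * (counts_per_projection / totals)[:, None, None]
    geom = replace(proj.geometry, counts_per_projection=counts_per_projection)
    return ProjectionSet(
        data=scaled, angles=proj.angles, geometry=geom, noise_applied=proj.noise_applied
    )


def simulate_counts(
    proj: ProjectionSet, counts_per_projection: float, seed: int
) -> ProjectionSet:
    """Scale ideal projections to a count level and add Poisson noise.

    The input must be noise-free.  Reproducible: the same seed gives the
    same realization.
    """
    if proj.noise_applied:
        raise InvalidInputError("projections already carry noise")
    scaled = scale_counts(proj, counts_per_projection)
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(scaled.data).astype(float)
    return ProjectionSet(
        data=noisy,
        angles=proj.angles,
        geometry=scaled.geometry,
        noise_applied=True,
    )
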