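"""Digital cylinder phantom and synthetic planar test slices.

The main object is a mathematical cylinder phantom: a warm cylindrical
body (relative activity 1) containing three parallel stacks of five
coaxial cylinders each — one cold stack (activity 0) and two hot stacks
(activities 2 and 4).  The stacked cylinders have diameters 4, 10, 20,
40 and 60 mm and are 30 mm long, so each stack spans 150 mm axially
inside the 200 mm body.  The phantom is purely mathematical: activity is
piecewise constant and voxelization assigns each voxel the activity of
the innermost cylinder containing its centre.

World coordinates are right-handed with z along the scanner axis and the
origin at the body centre; a rasterized volume is centred on the origin
and voxel centres sit at ``(index + 0.5) * voxel_size`` from the volume
corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "CylinderSpec",
    "PhantomSpec",
    "ActivityVolume",
    "default_3dmac",
    "rasterize_phantom",
    "make_test_slice",
    "STACK_DIAMETERS_MM",
    "STACK_ACTIVITIES",
    "CYLINDER_LENGTH_MM",
]

#: diameters of the stacked cylinders, bottom to top (mm)
STACK_DIAMETERS_MM = (4.0, 10.0, 20.0, 40.0, 60.0)
#: relative activities of the three stacks (cold, hot x2, hot x4)
STACK_ACTIVITIES = (0.0, 2.0, 4.0)
CYLINDER_LENGTH_MM = 30.0
_BODY_DIAMETER_MM = 200.0
_BODY_LENGTH_MM = 200.0
_STACK_RADIUS_MM = 55.0  # radial offset of stack axes from the body axis
_STACK_ANGLES_DEG = (90.0, 210.0, 330.0)  # cold, hot x2, hot x4


@dataclass(frozen=True)
class CylinderSpec:
    """One cylinder: centre (mm, world frame), axis along z."""

    center: tuple[float, float, float]
    diameter: float
    length: float
    relative_activity: float

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ConfigurationError("cylinder diameter and length must be positive")
        if self.relative_activity < 0:
            raise ConfigurationError("relative activity must be nonnegative")

    def contains(self, x, y, z):
        """Vectorized membership test of world points (centre-inclusion)."""
        cx, cy, cz = self.center
        r = self.diameter / 2.0
        inside_r = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        inside_z = np.abs(z - cz) <= self.length / 2.0
        return inside_r & inside_z


@dataclass(frozen=True)
class PhantomSpec:
    """Background body cylinder plus embedded object cylinders."""

    body: CylinderSpec
    objects: tuple[CylinderSpec, ...]

    def __post_init__(self):
        objs = tuple(self.objects)
        bx, by, bz = self.body.center
        br = self.body.diameter / 2.0
        for o in objs:
            ox, oy, oz = o.center
            radial = math.hypot(ox - bx, oy - by) + o.diameter / 2.0
            axial = abs(oz - bz) + o.length / 2.0
            if radial > br + 1e-9 or axial > self.body.length / 2.0 + 1e-9:
                raise ConfigurationError(
                    f"object cylinder at {o.center} (d={o.diameter}) "
                    "extends outside the phantom body"
                )
        object.__setattr__(self, "objects", objs)

    def find_cylinder(self, relative_activity: float, diameter: float) -> CylinderSpec:
        """Look up an object cylinder by its activity and diameter."""
        for o in self.objects:
            if (
                math.isclose(o.relative_activity, relative_activity)
                and math.isclose(o.diameter, diameter)
            ):
                return o
        raise KeyError(
            f"no cylinder with activity {relative_activity} and diameter {diameter}"
        )


@dataclass
class ActivityVolume:
    """3D voxel grid with isotropic voxel size in mm, axes ordered (z, y, x).

    Used both for phantom activity maps (nonnegative) and for
    reconstructed volumes, which may carry negative values when produced
    by filtered back projection.
    """

    voxels: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise InvalidInputError("voxels must be a 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("voxels contain non-finite values")
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def total(self) -> float:
        return float(self.voxels.sum())

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one array axis.

        Axis 0 is z, axis 1 is y, axis 2 is x; the volume is centred on
        the world origin.
        """
        n = self.voxels.shape[axis]
        return (np.arange(n) + 0.5) * self.voxel_size - n * self.voxel_size / 2.0

    def plane_coords_mm(self):
        """(y, x) centre-coordinate grids for one transaxial plane."""
        y = self.axis_coords_mm(1)
        x = self.axis_coords_mm(2)
        return np.meshgrid(y, x, indexing="ij")

    def slice_index(self, z_mm: float) -> int:
        """Index of the transaxial slice whose slab contains world z (mm)."""
        nz = self.voxels.shape[0]
        idx = int(np.floor(z_mm / self.voxel_size + nz / 2.0))
        if not 0 <= idx < nz:
            raise InvalidInputError(f"z = {z_mm} mm lies outside the volume")
        return idx


def default_3dmac() -> PhantomSpec:
    """The default mathematical cylinder phantom.

    Body: 200 mm diameter x 200 mm length, relative activity 1.  Three
    stacks (activities 0, 2, 4) at 120 degree spacing on a 55 mm radius,
    each of five 30 mm long cylinders (diameters 4-60 mm) stacked
    end-to-end and centred axially.  The placement leaves more than a
    10 mm margin between the largest cylinder and the body wall.
    """
    body = CylinderSpec(
        center=(0.0, 0.0, 0.0),
        diameter=_BODY_DIAMETER_MM,
        length=_BODY_LENGTH_MM,
        relative_activity=1.0,
    )
    objects = []
    stack_span = CYLINDER_LENGTH_MM * len(STACK_DIAMETERS_MM)
    z0 = -stack_span / 2.0 + CYLINDER_LENGTH_MM / 2.0
    for activity, ang in zip(STACK_ACTIVITIES, _STACK_ANGLES_DEG):
        cx = _STACK_RADIUS_MM * math.cos(math.radians(ang))
        cy = _STACK_RADIUS_MM * math.sin(math.radians(ang))
        for j, d in enumerate(STACK_DIAMETERS_MM):
            objects.append(
                CylinderSpec(
                    center=(cx, cy, z0 + j * CYLINDER_LENGTH_MM),
                    diameter=d,
                    length=CYLINDER_LENGTH_MM,
                    relative_activity=activity,
                )
            )
    return PhantomSpec(body=body, objects=tuple(objects))


def rasterize_phantom(
    spec: PhantomSpec,
    matrix: int = 64,
    voxel_size: float = 4.0,
    n_slices: int = 50,
) -> ActivityVolume:
    """Voxelize a phantom on a centred grid by voxel-centre membership.

    Each voxel takes the activity of the innermost (smallest-diameter)
    cylinder containing its centre; voxels outside the body are zero.
    """
    if matrix * voxel_size < spec.body.diameter - 1e-9:
        raise ConfigurationError("phantom body exceeds the transaxial field of view")
    if n_slices * voxel_size < spec.body.length - 1e-9:
        raise ConfigurationError("phantom body exceeds the axial field of view")
    z = (np.arange(n_slices) + 0.5) * voxel_size - n_slices * voxel_size / 2.0
    y = (np.arange(matrix) + 0.5) * voxel_size - matrix * voxel_size / 2.0
    x = y.copy()
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    vol = np.zeros((n_slices, matrix, matrix))
    vol[spec.body.contains(xx, yy, zz)] = spec.body.relative_activity
    # larger cylinders first so smaller (inner) ones override
    for o in sorted(spec.objects, key=lambda c: -c.diameter):
        vol[o.contains(xx, yy, zz)] = o.relative_activity
    return ActivityVolume(voxels=vol, voxel_size=voxel_size)


def analytic_activity_integral(spec: PhantomSpec) -> float:
    """Closed-form activity integral (activity x mm^3) of a phantom."""
    r = spec.body.diameter / 2.0
    total = spec.body.relative_activity * math.pi * r * r * spec.body.length
    for o in spec.objects:
        ro = o.diameter / 2.0
        vol = math.pi * ro * ro * o.length
        total += (o.relative_activity - spec.body.relative_activity) * vol
    return total


def make_test_slice(
    size: int = 64,
    structures: int = 3,
    seed: int = 0,
    total_counts: float = 100_000.0,
):
    """Synthetic piecewise-constant planar slice with a Poisson realization.

    Builds a seeded anatomical-like 2D truth image made of ``structures``
    nested elliptical regions of distinct activity inside a zero
    background, scales it so the expected total equals ``total_counts``,
    and draws one Poisson sample.  Used as a self-contained stand-in for
    external planar phantom data in the AR model-selection protocol.

    Returns ``(truth, noisy)`` — both scaled to the requested count level.
    """
    if size < 32:
        raise ConfigurationError("size must be >= 32")
    if structures < 1:
        raise ConfigurationError("need at least one structure")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0

    truth = np.zeros((size, size))
    a = size * 0.42
    b = size * 0.34
    # distinct levels, strictly increasing so nesting keeps values distinct
    levels = np.cumsum(rng.uniform(0.5, 1.5, size=structures))
    oy, ox = cy, cx
    for i in range(structures):
        mask = ((yy - oy) / a) ** 2 + ((xx - ox) / b) ** 2 <= 1.0
        truth[mask] = levels[i]
        # shrink and jitter the next ellipse, keeping it inside the current one
        a_next, b_next = a * 0.62, b * 0.62
        oy = oy + rng.uniform(-1, 1) * (a - a_next) * 0.4
        ox = ox + rng.uniform(-1, 1) * (b - b_next) * 0.4
        a, b = a_next, b_next
    truth *= total_counts / truth.sum()
    noisy = rng.poisson(truth).astype(float)
    return truth, noisy
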