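"""Geometric measurement of 3D lesion masks.

A lesion is a binary occupancy array on a regular voxel grid. Axis 2 of the
array is the inferior-superior (z) axis, so an *axial* slice is a fixed-z
plane ``occupancy[:, :, k]`` — the plane on which clinical diameters are
measured. Volumes are voxel counts scaled by the voxel volume; the longest
axial diameter is the in-plane Feret maximum (largest voxel-centre to
voxel-centre distance within any single axial slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist


class ClippingError(RuntimeError):
    """A rotation pushed occupied voxels off the grid."""


@dataclass(frozen=True)
class Mask3D:
    """Binary lesion occupancy on a regular grid with physical spacing.

    Parameters
    ----------
    occupancy : (nx, ny, nz) bool array
        Voxel occupancy; axis 2 is inferior-superior (z).
    spacing : 3-tuple of float
        Voxel edge length per axis in mm; must be strictly positive.
    origin : 3-tuple of float
        Physical (mm) coordinates of the centre of voxel (0, 0, 0), RAS.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3:
            raise ValueError(f"occupancy must be 3D, got shape {occ.shape}")
        if occ.dtype != bool:
            uniq = np.unique(occ)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("occupancy values must be binary (0/1)")
            occ = occ.astype(bool)
        object.__setattr__(self, "occupancy", occ)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def is_empty(self) -> bool:
        return not self.occupancy.any()

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centroid_voxel(self) -> np.ndarray:
        """Occupancy centroid in (fractional) voxel index coordinates."""
        if self.is_empty:
            raise ValueError("empty mask has no centroid")
        return np.array(ndimage.center_of_mass(self.occupancy))

    def __eq__(self, other: object) -> bool:  # voxel-identical comparison
        if not isinstance(other, Mask3D):
            return NotImplemented
        return (
            self.occupancy.shape == other.occupancy.shape
            and bool(np.array_equal(self.occupancy, other.occupancy))
            and self.spacing == other.spacing
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class RotationSpec:
    """Rotation-perturbation protocol: which angles, about which axes.

    ``axes="x"`` rotates about the patient x-axis only (the realistic
    head-tilt perturbation); ``axes="xyz"`` composes rotations of the same
    angle about x, then y, then z (the extreme-perturbation variant).
    Composition order matters and is fixed as R = Rz @ Ry @ Rx.
    """

    angles: tuple[float, ...] = field(default_factory=lambda: rotation_set(-20, 20, 2))
    axes: str = "x"

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        if not any(a == 0 for a in angles):
            raise ValueError("rotation angle set must include 0 (the reference)")
        if self.axes not in ("x", "y", "z", "xyz"):
            raise ValueError(f"axes must be 'x', 'y', 'z' or 'xyz', got {self.axes!r}")
        object.__setattr__(self, "angles", angles)


def rotation_set(min_deg: float, max_deg: float, step: float) -> tuple[float, ...]:
    """Inclusive arithmetic angle sequence containing 0.

    ``rotation_set(-20, 20, 2)`` yields the 21 angles of the standard
    perturbation protocol (including the unrotated reference).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not (min_deg <= 0 <= max_deg):
        raise ValueError("angle range must contain 0")
    n = (max_deg - min_deg) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("step must divide the angle range")
    if abs((0 - min_deg) / step - round((0 - min_deg) / step)) > 1e-9:
        raise ValueError("0 must be representable in the angle sequence")
    angles = min_deg + step * np.arange(int(round(n)) + 1)
    angles[np.abs(angles) < 1e-12] = 0.0
    return tuple(float(a) for a in angles)


def volume_mm3(mask: Mask3D) -> float:
    """Lesion volume as occupied-voxel count times voxel volume (mm^3)."""
    return mask.n_voxels * mask.voxel_volume


def cube_root_size(volume: float) -> float:
    """Cube root of a volume (mm) — puts volumes on the diameter length scale."""
    if volume < 0:
        raise ValueError(f"volume must be non-negative, got {volume}")
    return float(volume) ** (1.0 / 3.0)


def _slice_feret(points_mm: np.ndarray) -> float:
    """Max pairwise distance between 2D points; hull-accelerated."""
    if len(points_mm) < 2:
        return 0.0
    pts = points_mm
    if len(pts) > 10:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # degenerate (collinear) slice: brute force below
    return float(pdist(pts).max())


def longest_axial_diameter(mask: Mask3D) -> float:
    """Longest axial diameter (mm): max in-plane Feret over axial slices.

    Diameters are measured on axial (fixed-z) planes, as in clinical
    practice; a lesion elongated along z therefore reports its largest
    *cross-section*, not its 3D extent. Distances are voxel-centre to
    voxel-centre, so an empty mask or a single-voxel slice contributes 0.
    """
    if mask.is_empty:
        return 0.0
    xs, ys, zs = np.nonzero(mask.occupancy)
    sx, sy, _ = mask.spacing
    best = 0.0
    for z in np.unique(zs):
        in_slice = zs == z
        pts = np.column_stack((xs[in_slice] * sx, ys[in_slice] * sy))
        best = max(best, _slice_feret(pts))
    return best


def resample_mask(mask: Mask3D, target_spacing: float | tuple[float, float, float]) -> Mask3D:
    """Resample occupancy to a new grid spacing by nearest-neighbour.

    Binary contours are resampled nearest-neighbour (never interpolated to
    fractional occupancy). A mask already at the target spacing is returned
    as a voxel-identical copy.
    """
    if np.isscalar(target_spacing):
        target = (float(target_spacing),) * 3
    else:
        target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    if np.allclose(mask.spacing, target):
        return Mask3D(mask.occupancy.copy(), target, mask.origin)
    zoom = np.array(mask.spacing) / np.array(target)
    occ = ndimage.zoom(
        mask.occupancy.astype(np.uint8), zoom, order=0, mode="grid-constant", grid_mode=True
    ).astype(bool)
    return Mask3D(occ, target, mask.origin)


def _axis_rotation_matrix(axis: int, angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    r = np.eye(3)
    r[i, i] = c
    r[j, j] = c
    # sign convention: right-handed rotation about the axis
    if axis == 1:
        r[i, j] = s
        r[j, i] = -s
    else:
        r[i, j] = -s
        r[j, i] = s
    return r


def rotation_matrix(angle_deg: float, axes: str) -> np.ndarray:
    """Rotation matrix for one perturbation angle.

    For ``axes="xyz"`` the same angle is applied about x, then y, then z
    (R = Rz @ Ry @ Rx); composition order is fixed because rotations do
    not commute.
    """
    if axes in ("x", "y", "z"):
        return _axis_rotation_matrix("xyz".index(axes), angle_deg)
    if axes == "xyz":
        rx = _axis_rotation_matrix(0, angle_deg)
        ry = _axis_rotation_matrix(1, angle_deg)
        rz = _axis_rotation_matrix(2, angle_deg)
        return rz @ ry @ rx
    raise ValueError(f"unknown axes spec {axes!r}")


def rotate_mask(
    mask: Mask3D,
    angle_deg: float,
    axes: str = "x",
    center_voxel: np.ndarray | None = None,
) -> Mask3D:
    """Rigidly rotate a mask about its centroid, nearest-neighbour resampled.

    The grid is padded so the rotation cannot clip occupied voxels (a
    :class:`ClippingError` is raised if one still lands on the boundary).
    The rotation centre is the occupancy centroid snapped to the nearest
    voxel centre, which makes axis-aligned quarter-turns exact lattice
    permutations (voxel count preserved exactly); at other angles the
    nearest-neighbour resampling perturbs the voxel count slightly — the
    interpolation error whose effect on size measurements the rotation
    analysis quantifies.

    Requires isotropic spacing (rotation mixes axes).
    """
    if angle_deg == 0:
        return Mask3D(mask.occupancy.copy(), mask.spacing, mask.origin)
    if mask.is_empty:
        raise ValueError("cannot rotate an empty mask")
    if not np.allclose(mask.spacing, mask.spacing[0]):
        raise ValueError(f"rotation requires isotropic spacing, got {mask.spacing}")

    occ = mask.occupancy
    if center_voxel is None:
        center_voxel = np.round(mask.centroid_voxel())
    center_voxel = np.asarray(center_voxel, dtype=float)

    # pad so the farthest occupied voxel cannot leave the grid
    idx = np.array(np.nonzero(occ)).T
    r_max = np.linalg.norm(idx - center_voxel, axis=1).max()
    pad = int(np.ceil(r_max)) + 2
    padded = np.pad(occ, pad)
    center = center_voxel + pad

    rot = rotation_matrix(angle_deg, axes)
    rot_inv = rot.T  # orthonormal
    offset = center - rot_inv @ center
    out = ndimage.affine_transform(
        padded.astype(np.uint8), rot_inv, offset=offset, order=0, prefilter=False
    ).astype(bool)

    boundary = np.zeros_like(out)
    boundary[[0, -1], :, :] = True
    boundary[:, [0, -1], :] = True
    boundary[:, :, [0, -1]] = True
    if (out & boundary).any():
        raise ClippingError(
            f"rotation by {angle_deg} deg about {axes} clipped occupied voxels"
        )

    s = mask.spacing
    new_origin = tuple(mask.origin[i] - pad * s[i] for i in range(3))
    return Mask3D(out, mask.spacing, new_origin)
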