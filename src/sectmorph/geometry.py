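"""Section planes and 2D section extraction from 3D volumes.

A :class:`SectionPlane` is an oriented, finite sampling rectangle: an origin
at the center of the sampled image, an orthonormal right-handed frame
``(u, v, normal)`` with ``normal = u x v``, a pixel pitch in µm, and an
``extent`` of (rows, cols). Pixel ``(r, c)`` samples the world point

    origin + (c - (cols-1)/2) * pitch * u + (r - (rows-1)/2) * pitch * v

so ``u`` is the in-plane horizontal (mesiodistal) axis and ``v`` the in-plane
vertical (apico-occlusal) axis.

Plane perturbations mirror a virtual re-sectioning protocol: parallel offsets
in whole pixels along the normal (positive = buccal) and rotations about the
in-plane vertical axis as seen from the occlusal view (positive = clockwise).
Offset and rotated variants are always derived independently from the same
original plane, never chained.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import PhaseVolume, VoxelVolume

_ORTHO_TOL = 1e-9
#: tolerance (in voxel-index units) when deciding whether a sample point
#: lies inside the volume's voxel-center bounding box
_INSIDE_TOL = 1e-7


@dataclass(frozen=True)
class SectionPlane:
    origin: np.ndarray          # world µm (x, y, z), center of the sampled rectangle
    normal: np.ndarray          # unit vector, = u_axis x v_axis
    u_axis: np.ndarray          # unit vector, in-plane horizontal
    v_axis: np.ndarray          # unit vector, in-plane vertical
    pixel_pitch: float          # µm
    extent: tuple[int, int]     # (rows, cols)

    def __post_init__(self) -> None:
        for name in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be positive, got {self.pixel_pitch}")
        rows, cols = self.extent
        if rows <= 0 or cols <= 0:
            raise ValueError(f"extent must be positive, got {self.extent}")
        object.__setattr__(self, "extent", (int(rows), int(cols)))
        n, u, v = self.normal, self.u_axis, self.v_axis
        for vec, name in ((n, "normal"), (u, "u_axis"), (v, "v_axis")):
            if abs(np.linalg.norm(vec) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be a unit vector")
        if max(abs(u @ v), abs(u @ n), abs(v @ n)) > _ORTHO_TOL:
            raise ValueError("plane frame must be orthogonal")
        if np.max(np.abs(np.cross(u, v) - n)) > 1e-8:
            raise ValueError("frame must be right-handed: normal = u_axis x v_axis")

    def grid_points(self) -> np.ndarray:
        """World sample points, shape (rows, cols, 3)."""
        rows, cols = self.extent
        r = np.arange(rows, dtype=float) - (rows - 1) / 2.0
        c = np.arange(cols, dtype=float) - (cols - 1) / 2.0
        return (
            self.origin[None, None, :]
            + c[None, :, None] * self.pixel_pitch * self.u_axis
            + r[:, None, None] * self.pixel_pitch * self.v_axis
        )

    def to_dict(self) -> dict:
        """Full-precision JSON-ready serialization."""
        return {
            "origin": self.origin.tolist(),
            "normal": self.normal.tolist(),
            "u_axis": self.u_axis.tolist(),
            "v_axis": self.v_axis.tolist(),
            "pixel_pitch": self.pixel_pitch,
            "extent": list(self.extent),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SectionPlane":
        return cls(
            origin=np.array(d["origin"], dtype=float),
            normal=np.array(d["normal"], dtype=float),
            u_axis=np.array(d["u_axis"], dtype=float),
            v_axis=np.array(d["v_axis"], dtype=float),
            pixel_pitch=float(d["pixel_pitch"]),
            extent=tuple(d["extent"]),
        )


@dataclass
class SliceImage:
    """Grayscale section sampled on a plane; NaN outside the volume."""

    values: np.ndarray
    valid_mask: np.ndarray
    plane: SectionPlane

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != tuple(self.plane.extent):
            raise ValueError("values shape must equal plane.extent")
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid")


@dataclass
class PhaseMap:
    """Three-phase label section over a plane; labels at invalid pixels are meaningless."""

    labels: np.ndarray
    valid_mask: np.ndarray
    plane: SectionPlane
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.labels.shape != tuple(self.plane.extent):
            raise ValueError("labels shape must equal plane.extent")
        if self.valid_mask.shape != self.labels.shape:
            raise ValueError("valid_mask shape must match labels")
        if self.labels.size and not np.isin(self.labels[self.valid_mask], (0, 1, 2)).all():
            raise ValueError("labels must be restricted to {0, 1, 2}")
        self.labels = self.labels.astype(np.uint8)


# ---------------------------------------------------------------------------
# plane construction and perturbation

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

# for each slicing axis: (u world axis, v world axis) chosen so that
# (u, v, n) is right-handed and rows/cols match the raw numpy array slice
_AXIS_FRAMES = {
    # slice values[k]      -> rows = y, cols = x, normal = +z
    "z": (np.array([1.0, 0, 0]), np.array([0, 1.0, 0])),
    # slice values[:, :, k] -> rows = z, cols = y, normal = +x
    "x": (np.array([0, 1.0, 0]), np.array([0, 0, 1.0])),
    # slice values[:, k, :] -> rows = z, cols = x, normal = -y
    "y": (np.array([1.0, 0, 0]), np.array([0, 0, 1.0])),
}


def axis_aligned_plane(
    volume: VoxelVolume | PhaseVolume,
    axis: str,
    slice_index: int,
    extent: tuple[int, int] | None = None,
    pixel_pitch: float | None = None,
) -> SectionPlane:
    """Plane through the ``slice_index``-th layer of voxel centers along ``axis``.

    With the default extent and pitch, nearest-neighbor extraction at the
    returned plane reproduces the corresponding raw array slice exactly.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    arr = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    nz, ny, nx = arr.shape
    n_world = {"x": nx, "y": ny, "z": nz}
    if not 0 <= slice_index < n_world[axis]:
        raise IndexError(
            f"slice_index {slice_index} out of range for axis {axis} of size {n_world[axis]}"
        )
    u, v = _AXIS_FRAMES[axis]
    normal = np.cross(u, v)
    if extent is None:
        default_extent = {"z": (ny, nx), "x": (nz, ny), "y": (nz, nx)}
        extent = default_extent[axis]
    if pixel_pitch is None:
        pixel_pitch = volume.spacing
    rows, cols = extent
    ax = _AXIS_INDEX[axis]
    origin = volume.origin.copy()
    origin[ax] += slice_index * volume.spacing
    # center the sampled rectangle on the volume cross-section
    origin += (cols - 1) / 2.0 * pixel_pitch * u + (rows - 1) / 2.0 * pixel_pitch * v
    return SectionPlane(origin, normal, u, v, float(pixel_pitch), (rows, cols))


def offset_plane(plane: SectionPlane, k_pixels: int) -> SectionPlane:
    """Parallel offset by ``k_pixels`` pixel pitches along +normal (positive = buccal)."""
    return offset_plane_um(plane, k_pixels * plane.pixel_pitch)


def offset_plane_um(plane: SectionPlane, distance_um: float) -> SectionPlane:
    if distance_um == 0:
        return plane
    return replace(plane, origin=plane.origin + distance_um * plane.normal)


def _rotate_frame(plane: SectionPlane, axis: np.ndarray, angle_deg: float) -> SectionPlane:
    """Rigid rotation of the plane frame about a unit ``axis`` through plane.origin."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)

    def rot(x: np.ndarray) -> np.ndarray:
        return x * c + np.cross(axis, x) * s + axis * (axis @ x) * (1 - c)

    u = rot(plane.u_axis)
    v = rot(plane.v_axis)
    # Gram-Schmidt refresh keeps the frame orthonormal over long compositions
    u = u / np.linalg.norm(u)
    v = v - (v @ u) * u
    v = v / np.linalg.norm(v)
    n = np.cross(u, v)
    return replace(plane, normal=n, u_axis=u, v_axis=v)


def rotate_plane(plane: SectionPlane, angle_deg: float) -> SectionPlane:
    """Rotate the plane about its in-plane vertical axis through the image center.

    The pivot is ``v_axis`` (the apico-occlusal axis), so the rotation is the
    one seen from the occlusal view; a positive angle is clockwise in that
    view (normal swings from ``n`` toward ``-u``). ``v_axis`` and the origin
    are unchanged.
    """
    if angle_deg == 0:
        return plane
    return _rotate_frame(plane, plane.v_axis, -angle_deg)


def perturb_plane(
    plane: SectionPlane,
    offset_um: float = 0.0,
    tilt_u_deg: float = 0.0,
    tilt_v_deg: float = 0.0,
    inplane_rot_deg: float = 0.0,
    shift_u_um: float = 0.0,
) -> SectionPlane:
    """Compose the small perturbations used by plane search and the histology proxy.

    Rotations are applied in order tilt about ``v_axis``, tilt about the (new)
    ``u_axis``, in-plane rotation about the (new) normal; the origin is then
    displaced by ``offset_um`` along the final normal and ``shift_u_um`` along
    the final ``u_axis``.
    """
    p = plane
    if tilt_v_deg:
        p = _rotate_frame(p, p.v_axis, -tilt_v_deg)
    if tilt_u_deg:
        p = _rotate_frame(p, p.u_axis, tilt_u_deg)
    if inplane_rot_deg:
        p = _rotate_frame(p, p.normal, inplane_rot_deg)
    shift = offset_um * p.normal + shift_u_um * p.u_axis
    if offset_um or shift_u_um:
        p = replace(p, origin=p.origin + shift)
    return p


# ---------------------------------------------------------------------------
# section extraction


def _sample_coords(volume: VoxelVolume | PhaseVolume, plane: SectionPlane):
    """Voxel-index coordinates of the plane's sample points plus inside-mask."""
    arr = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    pts = plane.grid_points()                              # (rows, cols, 3) world xyz
    idx_xyz = (pts - volume.origin) / volume.spacing       # fractional voxel indices
    nz, ny, nx = arr.shape
    n_xyz = np.array([nx, ny, nz], dtype=float)
    inside = np.all(
        (idx_xyz >= -_INSIDE_TOL) & (idx_xyz <= n_xyz - 1 + _INSIDE_TOL), axis=-1
    )
    # map_coordinates wants array-order (z, y, x)
    coords = np.stack([idx_xyz[..., 2], idx_xyz[..., 1], idx_xyz[..., 0]])
    return arr, coords, inside


def extract_slice(
    volume: VoxelVolume, plane: SectionPlane, interpolation: str = "trilinear"
) -> SliceImage:
    """Sample a grayscale section at ``plane``.

    ``interpolation`` is ``"trilinear"`` or ``"nearest"``. Sample points
    outside the voxel-center bounding box are masked invalid and carry NaN.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0
    arr, coords, inside = _sample_coords(volume, plane)
    vals = ndimage.map_coordinates(
        arr, coords.reshape(3, -1), order=order, mode="nearest"
    ).reshape(plane.extent)
    vals = np.where(inside, vals, np.nan)
    return SliceImage(values=vals, valid_mask=inside, plane=plane)


def extract_phase_slice(phase: PhaseVolume, plane: SectionPlane) -> PhaseMap:
    """Sample a label section at ``plane`` with nearest-neighbor lookup.

    Labels are categorical, so only nearest sampling is meaningful.
    """
    arr, coords, inside = _sample_coords(phase, plane)
    labels = ndimage.map_coordinates(
        arr, coords.reshape(3, -1), order=0, mode="nearest"
    ).reshape(plane.extent)
    labels = np.where(inside, labels, 0).astype(np.uint8)
    return PhaseMap(labels=labels, valid_mask=inside, plane=plane)
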