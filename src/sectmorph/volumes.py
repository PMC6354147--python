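"""3D voxel containers for micro-CT-like grayscale data and phase labels.

Conventions used throughout the package:

* arrays are indexed ``[z, y, x]`` (image-stack order: page, row, column);
* world coordinates are ``(x, y, z)`` in micrometres;
* voxel ``(iz, iy, ix)`` has its *center* at ``origin + (ix, iy, iz) * spacing``;
* spacing is isotropic (one scalar, µm per voxel).

The voxel-center convention makes axis-aligned reslicing exact: sampling a
plane through a layer of voxel centers reproduces the raw array slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: phase labels of the three-phase microstructure
NONCALCIFIED, BONE, GRAFT = 0, 1, 2
PHASE_NAMES = {NONCALCIFIED: "noncalcified", BONE: "bone", GRAFT: "graft"}


def _as_origin(origin) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    if o.shape != (3,):
        raise ValueError(f"origin must be a world (x, y, z) triple, got shape {o.shape}")
    return o


@dataclass
class VoxelVolume:
    """A 3D grid of finite grayscale intensities with world geometry."""

    values: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array indexed [z, y, x]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grayscale values must all be finite")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_extent(self) -> np.ndarray:
        """Half-open bounding box of voxel centers, rows (min, max) per world axis."""
        nz, ny, nx = self.values.shape
        n_xyz = np.array([nx, ny, nz], dtype=float)
        return np.stack([self.origin, self.origin + (n_xyz - 1) * self.spacing])


@dataclass
class PhaseVolume:
    """A 3D label grid over {noncalcified, bone, graft} with world geometry.

    ``meta`` carries generator provenance such as realized phase fractions.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array indexed [z, y, x]")
        if self.labels.dtype != np.uint8:
            if not np.isin(self.labels, (0, 1, 2)).all():
                raise ValueError("labels must be restricted to {0, 1, 2}")
            self.labels = self.labels.astype(np.uint8)
        elif self.labels.size and self.labels.max() > 2:
            raise ValueError("labels must be restricted to {0, 1, 2}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world_extent(self) -> np.ndarray:
        nz, ny, nx = self.labels.shape
        n_xyz = np.array([nx, ny, nz], dtype=float)
        return np.stack([self.origin, self.origin + (n_xyz - 1) * self.spacing])

    def phase_fractions(self) -> dict[str, float]:
        """Exhaustive voxel-count fractions of each phase."""
        counts = np.bincount(self.labels.ravel(), minlength=3)
        total = self.labels.size
        return {PHASE_NAMES[p]: counts[p] / total for p in (0, 1, 2)}
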