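"""Synthetic three-phase bone-graft microstructure phantoms.

Real specimens here would be healed extraction sockets: a trabecular network
of mineralized host bone, residual roughly-spherical hydroxyapatite graft
particles, and noncalcified soft tissue/marrow filling the rest. The phantom
reproduces the *statistical* features the section-plane analysis depends on:

* bone is a stationary correlated binary field — Gaussian white noise smoothed
  with a kernel of width ``correlation_length``, thresholded at the empirical
  quantile that yields the target volume fraction, so nearby parallel planes
  are similar and distant ones decorrelate at a controllable rate;
* graft particles are hard spheres rejection-sampled into non-bone space;
* a grayscale rendering assigns each phase its mean attenuation value and adds
  Gaussian noise and blur, emulating a reconstructed scan;
* a "histology proxy" is the phase section at a slightly perturbed plane with
  a small rate of independently flipped labels, standing in for a stained
  physical section matched to the virtual one.

Everything is deterministic given ``PhantomSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import PhaseMap, SectionPlane, extract_phase_slice, perturb_plane
from .volumes import BONE, GRAFT, NONCALCIFIED, PhaseVolume, VoxelVolume

#: distinct random streams derived from the phantom seed
_STREAM_STRUCTURE, _STREAM_RENDER, _STREAM_HISTOLOGY = 0, 1, 2

#: reconstructed cross-section pixel size of the emulated scanner, µm
DEFAULT_SPACING_UM = 19.75


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic specimen.

    Defaults give a ~3.2 mm cube at scanner pitch with 30% bone, 15% graft,
    a bone correlation length of ~3 voxels, and a histology proxy taken at
    the matched plane with 2% label-flip noise.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: float = DEFAULT_SPACING_UM            # µm / voxel, isotropic
    bone_fraction_target: float = 0.30
    graft_fraction_target: float = 0.15
    correlation_length: float = 60.0               # µm, bone-field smoothing scale
    graft_radius_mean: float = 80.0                # µm
    graft_radius_sd: float = 20.0                  # µm
    phase_means: tuple[float, float, float] = (50.0, 120.0, 220.0)  # noncalcified, bone, graft
    noise_sd: float = 10.0                         # grayscale units
    blur_sigma: float = 10.0                       # µm
    histology_perturbation: tuple[float, float, float] = (0.0, 0.0, 0.02)
    # (offset µm, tilt degrees about the in-plane vertical axis, label-flip rate)
    seed: int = 0
    max_placement_attempts: int = 500_000

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"shape components must be >= 8, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        if not (0 <= self.bone_fraction_target <= 1 and 0 <= self.graft_fraction_target <= 1):
            raise ValueError("phase fraction targets must lie in [0, 1]")
        if self.bone_fraction_target + self.graft_fraction_target >= 1:
            raise ValueError("bone and graft fraction targets must sum to < 1")
        for name in ("spacing", "correlation_length", "graft_radius_mean"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.graft_radius_sd < 0 or self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("sd/blur parameters must be non-negative")
        if len(set(self.phase_means)) != 3:
            raise ValueError("phase_means must be pairwise distinct")
        if not 0 <= self.histology_perturbation[2] <= 1:
            raise ValueError("label-flip rate must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one of the phantom's random streams."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stream)))


class GraftPlacementError(RuntimeError):
    """Raised when the graft volume-fraction target cannot be reached."""

    def __init__(self, target: float, realized: float, attempts: int):
        self.target, self.realized, self.attempts = target, realized, attempts
        super().__init__(
            f"graft fraction target {target:.4f} unreachable: realized "
            f"{realized:.4f} after {attempts} placement attempts"
        )


_OFFSET_CACHE: dict[float, np.ndarray] = {}


def _sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer voxel offsets of a ball of the given radius (voxel units)."""
    radius_vox = round(radius_vox, 2)
    cached = _OFFSET_CACHE.get(radius_vox)
    if cached is not None:
        return cached
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dz**2 + dy**2 + dx**2 <= radius_vox**2
    out = np.stack([dz[keep], dy[keep], dx[keep]], axis=1)
    if len(_OFFSET_CACHE) < 4096:
        _OFFSET_CACHE[radius_vox] = out
    return out


def generate_phase_volume(spec: PhantomSpec) -> PhaseVolume:
    """Generate the three-phase label volume for ``spec``.

    Bone: smoothed-Gaussian-field threshold at the quantile matching
    ``bone_fraction_target``. Graft: non-overlapping spheres rejection-sampled
    into non-bone space until ``graft_fraction_target`` is reached (raises
    :class:`GraftPlacementError` naming the realized fraction if the attempt
    budget runs out first). Realized fractions are recorded in ``meta``.
    """
    rng = spec.rng(_STREAM_STRUCTURE)
    labels = np.zeros(spec.shape, dtype=np.uint8)

    if spec.bone_fraction_target > 0:
        fld = rng.standard_normal(spec.shape)
        sigma_vox = spec.correlation_length / spec.spacing
        fld = ndimage.gaussian_filter(fld, sigma_vox)
        thr = np.quantile(fld, 1.0 - spec.bone_fraction_target)
        labels[fld > thr] = BONE

    n_total = labels.size
    target_graft_vox = int(round(spec.graft_fraction_target * n_total))
    # granular packing *approaches* the target; stop within 2% (relative) of
    # it rather than chasing the jammed tail with ever-smaller fragments
    stop_graft_vox = target_graft_vox - int(0.02 * target_graft_vox)
    graft_vox = 0
    attempts = 0
    nz, ny, nx = spec.shape
    min_radius = spec.spacing  # radii truncated at one voxel
    # hard-sphere packing jams as the target nears; graft granules are
    # polydisperse, so after sustained rejection the candidate radius scale
    # shrinks (floor: one voxel) and small fragments fill the remaining gaps
    radius_scale = 1.0
    consecutive_rejects = 0
    while graft_vox < stop_graft_vox:
        if attempts >= spec.max_placement_attempts:
            raise GraftPlacementError(
                spec.graft_fraction_target, graft_vox / n_total, attempts
            )
        attempts += 1
        if consecutive_rejects >= 200:
            radius_scale = max(radius_scale * 0.7, min_radius / spec.graft_radius_mean)
            consecutive_rejects = 0
        radius_um = max(
            min_radius,
            radius_scale * rng.normal(spec.graft_radius_mean, spec.graft_radius_sd),
        )
        center = np.array(
            [rng.integers(0, nz), rng.integers(0, ny), rng.integers(0, nx)]
        )
        vox = center[None, :] + _sphere_offsets(radius_um / spec.spacing)
        ok = (
            (vox >= 0).all(axis=1)
            & (vox[:, 0] < nz)
            & (vox[:, 1] < ny)
            & (vox[:, 2] < nx)
        )
        if not ok.all():
            consecutive_rejects += 1
            continue  # keep particles wholly inside the volume
        zz, yy, xx = vox[:, 0], vox[:, 1], vox[:, 2]
        if np.any(labels[zz, yy, xx] != NONCALCIFIED):
            consecutive_rejects += 1
            continue  # overlaps bone or an earlier particle
        labels[zz, yy, xx] = GRAFT
        graft_vox += len(vox)
        consecutive_rejects = 0

    vol = PhaseVolume(labels=labels, spacing=spec.spacing)
    counts = np.bincount(labels.ravel(), minlength=3)
    vol.meta.update(
        realized_fractions={
            "noncalcified": counts[NONCALCIFIED] / n_total,
            "bone": counts[BONE] / n_total,
            "graft": counts[GRAFT] / n_total,
        },
        placement_attempts=attempts,
        seed=spec.seed,
        generator="sectmorph.phantom v1",
    )
    return vol


def render_grayscale(phase: PhaseVolume, spec: PhantomSpec) -> VoxelVolume:
    """Render a grayscale volume: per-phase mean + Gaussian noise, then blur."""
    if len(set(spec.phase_means)) != 3:
        raise ValueError("phase_means must be pairwise distinct")
    means = np.asarray(spec.phase_means, dtype=float)
    vals = means[phase.labels]
    if spec.noise_sd > 0:
        rng = spec.rng(_STREAM_RENDER)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
    if spec.blur_sigma > 0:
        vals = ndimage.gaussian_filter(vals, spec.blur_sigma / phase.spacing)
    return VoxelVolume(values=vals, spacing=phase.spacing, origin=phase.origin)


def make_histology_proxy(
    phase: PhaseVolume, plane: SectionPlane, spec: PhantomSpec
) -> PhaseMap:
    """Phase section standing in for the matched stained physical section.

    The section is taken at ``plane`` perturbed by
    ``spec.histology_perturbation`` (offset along the normal, tilt about the
    in-plane vertical axis), then a stated fraction of valid pixel labels is
    flipped to one of the other two phases — disagreement between modalities
    is modeled directly at the label level, since the physical measurement is
    itself a (manual) segmentation.
    """
    offset_um, tilt_deg, flip_rate = spec.histology_perturbation
    p = perturb_plane(plane, offset_um=offset_um, tilt_v_deg=tilt_deg)
    pmap = extract_phase_slice(phase, p)
    if not pmap.valid_mask.any():
        raise ValueError("perturbed histology plane does not intersect the volume")
    if flip_rate > 0:
        rng = spec.rng(_STREAM_HISTOLOGY)
        flip = rng.random(pmap.labels.shape) < flip_rate
        flip &= pmap.valid_mask
        # flipped labels move to one of the two other phases, uniformly
        step = rng.integers(1, 3, size=pmap.labels.shape).astype(np.uint8)
        labels = pmap.labels.copy()
        labels[flip] = (labels[flip] + step[flip]) % 3
        pmap = PhaseMap(labels=labels, valid_mask=pmap.valid_mask, plane=p)
    pmap.meta.update(histology_perturbation=tuple(spec.histology_perturbation))
    return pmap
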