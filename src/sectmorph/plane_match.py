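"""Section-plane search: find the virtual section most similar to a reference.

Matching a 2D reference (a stained physical section, here its synthetic
proxy) to a plane through the 3D volume was done by eye in the original
workflow. This module formalizes it as an optimization over five plane
parameters relative to an initial guess: offset along the normal, tilts
about the in-plane axes, in-plane rotation, and in-plane translation along
the horizontal axis. A coarse grid scan over the search bounds is followed by
derivative-free (Nelder-Mead) refinement from the best grid point.

The default similarity is the unweighted mean of per-phase Dice coefficients
over phases present in the reference, computed on segmented maps — the
reference object is itself a segmentation. Mutual information is available
for grayscale references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .geometry import (
    PhaseMap,
    SectionPlane,
    SliceImage,
    extract_phase_slice,
    extract_slice,
    perturb_plane,
)
from .volumes import PhaseVolume, VoxelVolume

_PARAM_NAMES = ("offset_um", "tilt_u_deg", "tilt_v_deg", "inplane_rot_deg", "shift_u_um")


@dataclass(frozen=True)
class PlaneSearchSpec:
    """Bounds, grid resolution and refinement settings for the plane search.

    Each range is an inclusive (lo, hi) interval around the initial plane;
    a zero-width range pins that parameter. ``grid_steps`` gives the number
    of coarse-grid points per non-degenerate parameter.
    """

    offset_range_um: tuple[float, float] = (-118.5, 118.5)   # +/- 6 pixels at scanner pitch
    tilt_u_range_deg: tuple[float, float] = (0.0, 0.0)
    tilt_v_range_deg: tuple[float, float] = (-15.0, 15.0)
    inplane_rot_range_deg: tuple[float, float] = (0.0, 0.0)
    shift_u_range_um: tuple[float, float] = (0.0, 0.0)
    grid_steps: dict = field(default_factory=lambda: {
        "offset_um": 13, "tilt_u_deg": 11, "tilt_v_deg": 11,
        "inplane_rot_deg": 5, "shift_u_um": 5,
    })
    metric: str = "mean_phase_dice"          # or "mutual_information"
    refine_maxiter: int = 200
    n_starts: int = 5                        # refine from the top-k grid points
    xatol: float = 0.1                       # µm (and used as degrees/10 for angles)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            lo, hi = self._range(name)
            if not np.isfinite([lo, hi]).all() or lo > hi:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if any(v <= 0 for v in self.grid_steps.values()):
            raise ValueError("grid steps must be positive")
        if self.metric not in ("mean_phase_dice", "mutual_information"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def _range(self, name: str) -> tuple[float, float]:
        return {
            "offset_um": self.offset_range_um,
            "tilt_u_deg": self.tilt_u_range_deg,
            "tilt_v_deg": self.tilt_v_range_deg,
            "inplane_rot_deg": self.inplane_rot_range_deg,
            "shift_u_um": self.shift_u_range_um,
        }[name]


@dataclass
class PlaneSearchResult:
    best_plane: SectionPlane
    best_params: dict
    score: float
    n_evaluations: int
    trace: list  # (params dict, score) per evaluation


def similarity(ref: PhaseMap, cand: PhaseMap) -> float:
    """Mean per-phase Dice over phases present in the reference.

    Computed on jointly valid pixels; 1.0 iff the maps agree everywhere there
    on every reference phase, 0.0 if no reference-phase pixel is matched.
    """
    if ref.labels.shape != cand.labels.shape:
        raise ValueError(
            f"shape mismatch: {ref.labels.shape} vs {cand.labels.shape}"
        )
    joint = ref.valid_mask & cand.valid_mask
    if not joint.any():
        return 0.0
    a = ref.labels[joint]
    b = cand.labels[joint]
    phases = np.unique(ref.labels[ref.valid_mask])
    dices = []
    for p in phases:
        in_a, in_b = a == p, b == p
        denom = in_a.sum() + in_b.sum()
        if denom == 0:
            continue  # phase vanished from the joint region
        dices.append(2 * (in_a & in_b).sum() / denom)
    return float(np.mean(dices)) if dices else 0.0


def similarity_mi(ref: SliceImage, cand: SliceImage, bins: int = 64) -> float:
    """Mutual information (nats) between two grayscale sections."""
    if ref.values.shape != cand.values.shape:
        raise ValueError("shape mismatch")
    joint = ref.valid_mask & cand.valid_mask
    if not joint.any():
        return 0.0
    h, _, _ = np.histogram2d(ref.values[joint], cand.values[joint], bins=bins)
    pxy = h / h.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


class _Evaluator:
    """Scores one parameter vector; remembers whether any plane hit the volume."""

    def __init__(self, volume, ref, init, spec, trace):
        self.volume, self.ref, self.init, self.spec, self.trace = volume, ref, init, spec, trace
        self.is_phase = isinstance(volume, PhaseVolume)
        if spec.metric == "mean_phase_dice" and not self.is_phase:
            raise TypeError(
                "mean_phase_dice requires a PhaseVolume and a PhaseMap reference"
            )
        self.any_intersect = False

    def __call__(self, theta: np.ndarray) -> float:
        params = dict(zip(_PARAM_NAMES, (float(t) for t in theta)))
        plane = perturb_plane(self.init, **params)
        if self.is_phase:
            cand = extract_phase_slice(self.volume, plane)
            hit = bool(cand.valid_mask.any())
            score = similarity(self.ref, cand) if hit else 0.0
        else:
            cand = extract_slice(self.volume, plane, interpolation="trilinear")
            hit = bool(cand.valid_mask.any())
            score = similarity_mi(self.ref, cand) if hit else 0.0
        self.any_intersect |= hit
        self.trace.append((params, score))
        return score


def search_best_plane(
    volume: PhaseVolume | VoxelVolume,
    ref: PhaseMap | SliceImage,
    init: SectionPlane,
    spec: PlaneSearchSpec | None = None,
) -> PlaneSearchResult:
    """Coarse-grid scan plus Nelder-Mead refinement of the plane parameters.

    Deterministic given ``spec``; every evaluation is logged in the trace.
    The returned score always equals re-evaluating the metric at the returned
    plane, and is never below the best coarse-grid score.
    """
    spec = spec or PlaneSearchSpec()
    trace: list = []
    evaluate = _Evaluator(volume, ref, init, spec, trace)

    axes = []
    active = []
    for i, name in enumerate(_PARAM_NAMES):
        lo, hi = spec._range(name)
        if hi > lo:
            axes.append(np.linspace(lo, hi, int(spec.grid_steps[name])))
            active.append(i)
        else:
            axes.append(np.array([lo]))
    grid = np.stack(
        [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=-1
    )

    scores = np.array([evaluate(theta) for theta in grid])
    if not evaluate.any_intersect:
        raise ValueError("no candidate plane intersects the volume")
    best_i = int(np.argmax(scores))
    best_theta, best_score = grid[best_i].copy(), float(scores[best_i])

    if active and spec.refine_maxiter > 0:
        bounds = [spec._range(_PARAM_NAMES[i]) for i in active]
        # the Dice objective over discrete labels is piecewise constant, so a
        # single simplex can stall in a sub-voxel plateau; restart from the
        # best few grid points and keep the overall winner
        start_order = np.argsort(scores)[::-1][: max(1, spec.n_starts)]
        for start_i in start_order:
            theta0 = grid[int(start_i)].copy()

            def neg(x: np.ndarray, theta0=theta0) -> float:
                theta = theta0.copy()
                theta[active] = x
                return -evaluate(theta)

            res = optimize.minimize(
                neg,
                theta0[active],
                method="Nelder-Mead",
                bounds=bounds,
                options={
                    "maxiter": spec.refine_maxiter,
                    "xatol": spec.xatol,
                    "fatol": 1e-6,
                },
            )
            if -res.fun > best_score:
                best_score = float(-res.fun)
                best_theta = grid[int(start_i)].copy()
                best_theta[active] = res.x
            if best_score >= 1.0:
                break

    best_params = dict(zip(_PARAM_NAMES, (float(t) for t in best_theta)))
    best_plane = perturb_plane(init, **best_params)
    return PlaneSearchResult(
        best_plane=best_plane,
        best_params=best_params,
        score=best_score,
        n_evaluations=len(trace),
        trace=trace,
    )
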