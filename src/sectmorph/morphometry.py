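"""Percent-area morphometry over a centered region of interest.

The morphometric value of a section is the percent area of each phase within
a fixed-size ROI (default 4 x 4 mm) centered on the image — phase pixel count
divided by the number of evaluated (valid, in-ROI) pixels, times 100. The
overlap-based *concordance area rate* compares two superimposed segmentations
phase by phase (intersection over union), distinguishing spatial overlap from
mere equality of cumulative areas: two maps can have identical percent areas
while overlapping poorly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PhaseMap
from .volumes import PHASE_NAMES


@dataclass(frozen=True)
class ROI:
    """Centered rectangular region of interest, sized in millimetres.

    ``center`` is (row, col) in pixel coordinates; ``None`` means the image
    center. Pixel bounds are derived from the section's pixel pitch and
    clipped to the image.
    """

    size_mm: tuple[float, float] = (4.0, 4.0)   # (height, width)
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.size_mm[0] <= 0 or self.size_mm[1] <= 0:
            raise ValueError(f"size_mm must be positive, got {self.size_mm}")

    def pixel_bounds(
        self, shape: tuple[int, int], pixel_pitch_um: float
    ) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open pixel bounds, clipped to the image."""
        rows, cols = shape
        cr, cc = self.center if self.center is not None else ((rows - 1) / 2, (cols - 1) / 2)
        half_r = self.size_mm[0] * 1000.0 / pixel_pitch_um / 2.0
        half_c = self.size_mm[1] * 1000.0 / pixel_pitch_um / 2.0
        r0 = max(0, int(np.ceil(cr - half_r)))
        r1 = min(rows, int(np.floor(cr + half_r)) + 1)
        c0 = max(0, int(np.ceil(cc - half_c)))
        c1 = min(cols, int(np.floor(cc + half_c)) + 1)
        if r0 >= r1 or c0 >= c1:
            raise ValueError("ROI does not intersect the image")
        return r0, r1, c0, c1


@dataclass
class MorphometryResult:
    """Percent area of each phase over the evaluated ROI pixels."""

    pct_bone: float
    pct_graft: float
    pct_noncalcified: float
    n_pixels_evaluated: int
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "pct_bone": self.pct_bone,
            "pct_graft": self.pct_graft,
            "pct_noncalcified": self.pct_noncalcified,
            "n_pixels_evaluated": self.n_pixels_evaluated,
        }


def percent_areas(pmap: PhaseMap, roi: ROI | None = None) -> MorphometryResult:
    """Percent area of each phase within the ROI.

    Only valid pixels enter the denominator; percents are exact counts
    followed by a single division, so they sum to 100 up to rounding.
    """
    roi = roi or ROI()
    r0, r1, c0, c1 = roi.pixel_bounds(pmap.labels.shape, pmap.plane.pixel_pitch)
    labels = pmap.labels[r0:r1, c0:c1]
    valid = pmap.valid_mask[r0:r1, c0:c1]
    n = int(valid.sum())
    if n == 0:
        raise ValueError("ROI contains no valid pixels")
    counts = np.bincount(labels[valid].ravel(), minlength=3)
    pct = 100.0 * counts / n
    return MorphometryResult(
        pct_bone=float(pct[1]),
        pct_graft=float(pct[2]),
        pct_noncalcified=float(pct[0]),
        n_pixels_evaluated=n,
        provenance={
            "roi_bounds_px": (r0, r1, c0, c1),
            "roi_size_mm": tuple(roi.size_mm),
            "plane": pmap.plane.to_dict(),
            **{k: v for k, v in pmap.meta.items() if k in ("t_low", "t_high")},
        },
    )


@dataclass
class OverlapResult:
    """Per-phase concordance area rates of two superimposed phase maps.

    ``jaccard[phase]`` = |both p| / |either p|; ``dice`` is the matching
    Dice coefficient. Phases absent from both maps are NaN (undefined) and
    must be excluded from any averaging.
    """

    jaccard: dict[str, float]
    dice: dict[str, float]
    n_pixels_evaluated: int


def concordance_area_rate(
    map_a: PhaseMap, map_b: PhaseMap, roi: ROI | None = None
) -> OverlapResult:
    """Phase-wise overlap (Jaccard and Dice) over jointly valid ROI pixels."""
    if map_a.labels.shape != map_b.labels.shape:
        raise ValueError(
            f"shape mismatch: {map_a.labels.shape} vs {map_b.labels.shape}"
        )
    roi = roi or ROI()
    r0, r1, c0, c1 = roi.pixel_bounds(map_a.labels.shape, map_a.plane.pixel_pitch)
    joint = map_a.valid_mask[r0:r1, c0:c1] & map_b.valid_mask[r0:r1, c0:c1]
    if not joint.any():
        raise ValueError("no jointly valid pixels in the ROI")
    a = map_a.labels[r0:r1, c0:c1][joint]
    b = map_b.labels[r0:r1, c0:c1][joint]
    jaccard, dice = {}, {}
    for p, name in PHASE_NAMES.items():
        in_a, in_b = a == p, b == p
        inter = int((in_a & in_b).sum())
        union = int((in_a | in_b).sum())
        if union == 0:
            jaccard[name] = float("nan")
            dice[name] = float("nan")
        else:
            jaccard[name] = inter / union
            dice[name] = 2 * inter / (in_a.sum() + in_b.sum())
    return OverlapResult(jaccard=jaccard, dice=dice, n_pixels_evaluated=int(joint.sum()))
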