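"""Luminance-threshold segmentation of grayscale sections into three phases.

The physical workflow demarcates bone, graft and noncalcified regions by hand
on each image. The algorithmic default here is the two-threshold (three-class)
Otsu solution computed per image over its valid pixels; a manual override map
can replace labels in regions where the automatic boundary is judged wrong,
mirroring the manual touch-up step.

Band-to-phase mapping defaults to darkest = noncalcified, middle = bone,
brightest = graft (hydroxyapatite attenuates more than mineralized bone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu

from .geometry import PhaseMap, SliceImage

#: default mapping of intensity bands (dark, middle, bright) to phase labels
DEFAULT_PHASE_ORDER = (0, 1, 2)


@dataclass(frozen=True)
class ThresholdPair:
    """Two luminance thresholds plus the band-to-phase mapping.

    Band 0 is ``value < t_low``, band 1 is ``t_low <= value < t_high``,
    band 2 is ``value >= t_high``; ``phase_order[band]`` is the phase label.
    """

    t_low: float
    t_high: float
    phase_order: tuple[int, int, int] = DEFAULT_PHASE_ORDER

    def __post_init__(self) -> None:
        if not self.t_low < self.t_high:
            raise ValueError(f"t_low must be < t_high, got {self.t_low} >= {self.t_high}")
        if sorted(self.phase_order) != [0, 1, 2]:
            raise ValueError("phase_order must be a bijection onto {0, 1, 2}")


def auto_thresholds(
    slice_image: SliceImage, phase_order: tuple[int, int, int] = DEFAULT_PHASE_ORDER
) -> ThresholdPair:
    """Two-threshold multi-class Otsu over the valid pixels of a section.

    Maximizes between-class variance of the three bands. Raises on a
    degenerate histogram (fewer than three distinct intensity values).
    """
    vals = slice_image.values[slice_image.valid_mask]
    if vals.size == 0:
        raise ValueError("section has no valid pixels")
    n_distinct = np.unique(vals).size
    if n_distinct < 3:
        raise ValueError(
            f"degenerate histogram: only {n_distinct} distinct intensity value(s), "
            "need at least 3 for two-threshold segmentation"
        )
    t_low, t_high = threshold_multiotsu(vals, classes=3)
    return ThresholdPair(float(t_low), float(t_high), phase_order)


def threshold_segment(slice_image: SliceImage, thresholds: ThresholdPair) -> PhaseMap:
    """Assign each valid pixel to a phase by its intensity band."""
    if not slice_image.valid_mask.any():
        raise ValueError("section has no valid pixels")
    vals = np.where(slice_image.valid_mask, slice_image.values, thresholds.t_low)
    bands = np.digitize(vals, [thresholds.t_low, thresholds.t_high])
    order = np.asarray(thresholds.phase_order, dtype=np.uint8)
    labels = order[bands]
    labels[~slice_image.valid_mask] = 0
    pmap = PhaseMap(
        labels=labels, valid_mask=slice_image.valid_mask.copy(), plane=slice_image.plane
    )
    pmap.meta.update(t_low=thresholds.t_low, t_high=thresholds.t_high,
                     phase_order=tuple(thresholds.phase_order))
    return pmap


def apply_manual_override(pmap: PhaseMap, override: PhaseMap) -> PhaseMap:
    """Replace labels where the override map provides them.

    ``override.valid_mask`` marks the pixels the override supplies; all other
    pixels keep their automatic label. Overridden pixels become valid.
    """
    if override.labels.shape != pmap.labels.shape:
        raise ValueError(
            f"override shape {override.labels.shape} does not match "
            f"map shape {pmap.labels.shape}"
        )
    labels = np.where(override.valid_mask, override.labels, pmap.labels).astype(np.uint8)
    valid = pmap.valid_mask | override.valid_mask
    out = PhaseMap(labels=labels, valid_mask=valid, plane=pmap.plane)
    out.meta.update(pmap.meta, n_overridden=int(override.valid_mask.sum()))
    return out
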