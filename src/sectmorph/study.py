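"""Orchestration of the full in-silico section-plane sensitivity study.

One study emulates the original design end to end: a cohort of synthetic
specimens; for each, a reference ("histology proxy") section at a nominal
mesiodistal plane; selection of the matched virtual section (by plane search,
or directly from the known generating plane in fast mode); four perturbed
virtual sections (+/- 4-pixel parallel offsets, +/- 10 degree rotations about
the in-plane vertical axis, each derived independently from the matched
plane); threshold segmentation and percent-area morphometry of all six
images; and the two agreement blocks (reference vs the five virtual
sections, matched section vs the four perturbed ones) for bone and graft.

Everything is deterministic given the master seed: specimen i uses the
spawned stream ``SeedSequence(master_seed).spawn()[i]``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import TABLE_ROWS, agreement_table, bland_altman, PairedMeasurements
from .geometry import axis_aligned_plane, extract_slice, offset_plane, rotate_plane
from .morphometry import ROI, percent_areas
from .phantom import PhantomSpec, generate_phase_volume, make_histology_proxy, render_grayscale
from .plane_match import PlaneSearchSpec, search_best_plane
from .segmentation import auto_thresholds, threshold_segment

__version__ = "0.1.0"

#: the study's fixed plane-variant set
OFFSETS_PX = (4, -4)
ROTATIONS_DEG = (10, -10)


@dataclass(frozen=True)
class StudyConfig:
    """Design of one replica study.

    ``bone_fraction_sd`` / ``graft_fraction_sd`` give the between-specimen
    spread of the phase-fraction targets (truncated normal around the phantom
    defaults); without between-specimen variance the agreement coefficients
    would be degenerate — real cohorts vary biologically.
    """

    n_specimens: int = 16
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    bone_fraction_sd: float = 0.05
    graft_fraction_sd: float = 0.03
    offsets_px: tuple[int, ...] = OFFSETS_PX
    rotations_deg: tuple[float, ...] = ROTATIONS_DEG
    roi_size_mm: tuple[float, float] = (4.0, 4.0)
    fast_mode: bool = True          # True: use the known generating plane as the match
    search: PlaneSearchSpec = field(default_factory=PlaneSearchSpec)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("need at least 2 specimens")
        if self.bone_fraction_sd < 0 or self.graft_fraction_sd < 0:
            raise ValueError("fraction sds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom" in raw:
            raw["phantom"] = PhantomSpec(**raw["phantom"])
        if "search" in raw:
            raw["search"] = PlaneSearchSpec(**raw["search"])
        for key in ("offsets_px", "rotations_deg", "roi_size_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class StudyReport:
    measurements: pd.DataFrame
    table_bone: pd.DataFrame
    table_graft: pd.DataFrame
    bland_altman_points: dict  # (block, variant, phase) -> DataFrame(mean, diff)
    provenance: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(out / "measurements.csv", index=False)
        self.table_bone.to_csv(out / "table_bone.csv", index=False)
        self.table_graft.to_csv(out / "table_graft.csv", index=False)
        ba_dir = out / "bland_altman"
        ba_dir.mkdir(exist_ok=True)
        for (block, variant, phase), pts in self.bland_altman_points.items():
            name = f"{block}_{variant}_{phase}".replace("+", "p").replace("-", "m")
            pts.to_csv(ba_dir / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {
                    "provenance": self.provenance,
                    "table_bone": self.table_bone.to_dict(orient="records"),
                    "table_graft": self.table_graft.to_dict(orient="records"),
                },
                fh,
                indent=2,
                default=float,
            )


def _specimen_seed(master_seed: int, index: int) -> int:
    """Independent per-specimen seed below 2**31 via SeedSequence spawning."""
    child = np.random.SeedSequence(master_seed).spawn(index + 1)[index]
    return int(child.generate_state(1)[0]) & 0x7FFFFFFF


def _specimen_spec(config: StudyConfig, index: int) -> PhantomSpec:
    """Phantom spec for one specimen: spawned seed plus biological variation."""
    seed = _specimen_seed(config.master_seed, index)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    base = config.phantom
    bone = float(np.clip(
        rng.normal(base.bone_fraction_target, config.bone_fraction_sd), 0.05, 0.6
    ))
    graft = float(np.clip(
        rng.normal(base.graft_fraction_target, config.graft_fraction_sd), 0.02, 0.35
    ))
    return replace(base, seed=seed, bone_fraction_target=bone, graft_fraction_target=graft)


def measure_specimen(config: StudyConfig, index: int) -> list[dict]:
    """All six morphometric records for one specimen.

    Returns one dict per variant with percent areas and provenance.
    """
    spec = _specimen_spec(config, index)
    roi = ROI(size_mm=config.roi_size_mm)
    try:
        phase_vol = generate_phase_volume(spec)
        gray = render_grayscale(phase_vol, spec)
        nz = phase_vol.shape[0]
        true_plane = axis_aligned_plane(phase_vol, axis="z", slice_index=nz // 2)

        hm_map = make_histology_proxy(phase_vol, true_plane, spec)
        records = [{
            "specimen": index, "variant": "hm",
            **percent_areas(hm_map, roi).as_dict(), "seed": spec.seed,
        }]

        if config.fast_mode:
            original = true_plane
        else:
            original = search_best_plane(
                phase_vol, hm_map, true_plane, config.search
            ).best_plane

        variants = {"original": original}
        for k in config.offsets_px:
            variants[f"offset{k:+d}"] = offset_plane(original, k)
        for a in config.rotations_deg:
            variants[f"rotation{a:+g}"] = rotate_plane(original, a)

        for name, plane in variants.items():
            sl = extract_slice(gray, plane, interpolation="trilinear")
            pmap = threshold_segment(sl, auto_thresholds(sl))
            records.append({
                "specimen": index, "variant": name,
                **percent_areas(pmap, roi).as_dict(), "seed": spec.seed,
            })
    except Exception as err:  # annotate the failing specimen and stage
        raise RuntimeError(f"specimen {index} failed: {err}") from err
    return records


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full study and assemble the agreement tables."""
    config = config or StudyConfig()
    records: list[dict] = []
    for i in range(config.n_specimens):
        records.extend(measure_specimen(config, i))
    measurements = pd.DataFrame.from_records(records)

    table_bone = agreement_table(measurements, "bone")
    table_graft = agreement_table(measurements, "graft")

    ba_points = {}
    for phase in ("bone", "graft"):
        wide = measurements.pivot(index="specimen", columns="variant",
                                  values=f"pct_{phase}")
        for block, variant in TABLE_ROWS:
            ref = "hm" if block == "vs_hm" else "original"
            paired = PairedMeasurements(
                wide[ref].to_numpy(), wide[variant].to_numpy(), labels=(ref, variant)
            )
            ba_points[(block, variant, phase)] = bland_altman(paired).points

    provenance = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "n_records": len(measurements),
        "software_version": __version__,
        "seed_scheme": "SeedSequence(master_seed).spawn()[specimen_index]",
    }
    return StudyReport(
        measurements=measurements,
        table_bone=table_bone,
        table_graft=table_graft,
        bland_altman_points=ba_points,
        provenance=provenance,
    )


def sweep_perturbation(
    config: StudyConfig,
    offsets: list[int] | None = None,
    angles: list[float] | None = None,
) -> pd.DataFrame:
    """Sensitivity curve: agreement with the matched section per perturbation level.

    For each offset (pixels) and each rotation angle (degrees), every specimen
    is measured at the matched plane and at the perturbed plane; rows report
    Lin's CCC and the mean absolute difference of percent areas per level and
    phase across the cohort.
    """
    offsets = list(offsets or [])
    angles = list(angles or [])
    if not offsets and not angles:
        raise ValueError("provide at least one offset or angle")
    roi = ROI(size_mm=config.roi_size_mm)
    levels = [("offset", k) for k in offsets] + [("rotation", a) for a in angles]

    values: dict[tuple, dict[str, list]] = {
        lv: {"bone": [], "graft": []} for lv in [("original", 0)] + levels
    }
    for i in range(config.n_specimens):
        spec = _specimen_spec(config, i)
        phase_vol = generate_phase_volume(spec)
        gray = render_grayscale(phase_vol, spec)
        nz = phase_vol.shape[0]
        original = axis_aligned_plane(phase_vol, axis="z", slice_index=nz // 2)
        for kind, level in [("original", 0)] + levels:
            if kind == "offset":
                plane = offset_plane(original, int(level))
            elif kind == "rotation":
                plane = rotate_plane(original, float(level))
            else:
                plane = original
            sl = extract_slice(gray, plane, interpolation="trilinear")
            pmap = threshold_segment(sl, auto_thresholds(sl))
            res = percent_areas(pmap, roi)
            values[(kind, level)]["bone"].append(res.pct_bone)
            values[(kind, level)]["graft"].append(res.pct_graft)

    rows = []
    for (kind, level) in levels:
        for phase in ("bone", "graft"):
            x = np.array(values[("original", 0)][phase])
            y = np.array(values[(kind, level)][phase])
            if np.allclose(x, y):
                est = 1.0
            else:
                from .agreement import ccc as _ccc
                est = _ccc(PairedMeasurements(x, y))[0]
            rows.append({
                "kind": kind, "level": level, "phase": phase,
                "ccc": est, "mean_abs_diff": float(np.abs(x - y).mean()),
                "n": len(x),
            })
    return pd.DataFrame(rows)
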