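"""Reading and writing volumes, sections and phase maps.

Volumes go to NRRD (detached text header + raw little-endian data in one
file) or multi-page TIFF; sections to TIFF/PNG with a sidecar JSON that
serializes the sampling plane to full precision; phase maps to indexed PNG
with a fixed three-color palette. The NRRD support is a minimal raw-encoding
subset of the format (header fields: type, dimension, sizes, encoding,
endian, spacings, space origin).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .geometry import PhaseMap, SectionPlane, SliceImage
from .volumes import PhaseVolume, VoxelVolume

_NRRD_TYPES = {"float": np.float32, "double": np.float64, "uchar": np.uint8}
_NRRD_NAMES = {np.dtype(np.float32): "float", np.dtype(np.float64): "double",
               np.dtype(np.uint8): "uchar"}

#: indexed-PNG palette: noncalcified, bone, graft, (255 = invalid)
PHASE_PALETTE = {0: (40, 40, 40), 1: (70, 140, 255), 2: (90, 220, 90),
                 255: (0, 0, 0)}


def write_nrrd(path: str | Path, volume: VoxelVolume | PhaseVolume) -> None:
    """Write a volume as NRRD (raw little-endian encoding)."""
    arr = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    data = arr.astype(np.float64 if arr.dtype.kind == "f" else np.uint8)
    if data.dtype not in _NRRD_NAMES:
        data = data.astype(np.float64)
    nz, ny, nx = data.shape
    header = [
        "NRRD0004",
        "# sectmorph volume",
        f"type: {_NRRD_NAMES[data.dtype]}",
        "dimension: 3",
        f"sizes: {nx} {ny} {nz}",          # fastest axis first
        "encoding: raw",
        "endian: little",
        f"spacings: {volume.spacing!r} {volume.spacing!r} {volume.spacing!r}",
        "space origin: ({}, {}, {})".format(*volume.origin),
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode())
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())


def read_nrrd(path: str | Path, as_phase: bool = False) -> VoxelVolume | PhaseVolume:
    """Read a raw-encoded NRRD written by :func:`write_nrrd` (or compatible)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, body = raw.partition(b"\n\n")
    fields = {}
    for line in head.decode().splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip()] = val.strip()
    if fields.get("encoding", "raw") != "raw":
        raise ValueError(f"unsupported NRRD encoding {fields.get('encoding')!r}")
    dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder("<")
    nx, ny, nz = (int(s) for s in fields["sizes"].split())
    arr = np.frombuffer(body, dtype=dtype, count=nx * ny * nz).reshape(nz, ny, nx)
    spacing = float(fields.get("spacings", "1 1 1").split()[0])
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = np.array(
            [float(t) for t in fields["space origin"].strip("()").split(",")]
        )
    if as_phase or fields["type"] == "uchar":
        return PhaseVolume(labels=np.array(arr, dtype=np.uint8),
                           spacing=spacing, origin=origin)
    return VoxelVolume(values=np.array(arr, dtype=float), spacing=spacing, origin=origin)


def write_tiff_stack(path: str | Path, volume: VoxelVolume | PhaseVolume) -> None:
    arr = volume.values if isinstance(volume, VoxelVolume) else volume.labels
    tifffile.imwrite(path, arr.astype(np.float32 if arr.dtype.kind == "f" else np.uint8))


def read_tiff_stack(path: str | Path, spacing: float, as_phase: bool = False):
    arr = tifffile.imread(path)
    if as_phase:
        return PhaseVolume(labels=arr.astype(np.uint8), spacing=spacing)
    return VoxelVolume(values=arr.astype(float), spacing=spacing)


def write_phantom_sidecar(path: str | Path, spec) -> None:
    """JSON record of the generation parameters, including the seed."""
    with open(path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2, default=list)


def write_plane_json(path: str | Path, plane: SectionPlane) -> None:
    with open(path, "w") as fh:
        json.dump(plane.to_dict(), fh, indent=2)


def read_plane_json(path: str | Path) -> SectionPlane:
    with open(path) as fh:
        return SectionPlane.from_dict(json.load(fh))


def write_slice(path: str | Path, sl: SliceImage) -> None:
    """Grayscale section as 16-bit TIFF/PNG plus a plane sidecar JSON.

    Values are rescaled to the uint16 range; the scale is recorded in the
    sidecar so the image remains quantitative. Invalid pixels map to 0.
    """
    path = Path(path)
    vals = np.where(sl.valid_mask, sl.values, np.nan)
    finite = vals[np.isfinite(vals)]
    lo = float(finite.min()) if finite.size else 0.0
    hi = float(finite.max()) if finite.size else 1.0
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    img = np.zeros(vals.shape, dtype=np.uint16)
    ok = np.isfinite(vals)
    img[ok] = np.round((vals[ok] - lo) * scale).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        Image.fromarray(img, mode="I;16").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"plane": sl.plane.to_dict(), "intensity_offset": lo,
                   "intensity_scale": scale}, fh, indent=2)


def write_phase_png(path: str | Path, pmap: PhaseMap) -> None:
    """Indexed PNG with the fixed three-phase palette; invalid pixels = 255."""
    idx = np.where(pmap.valid_mask, pmap.labels, 255).astype(np.uint8)
    img = Image.fromarray(idx, mode="P")
    palette = [0] * 768
    for value, rgb in PHASE_PALETTE.items():
        palette[3 * value: 3 * value + 3] = rgb
    img.putpalette(palette)
    img.save(path)
    with open(Path(str(path) + ".json"), "w") as fh:
        json.dump({"plane": pmap.plane.to_dict(), "invalid_index": 255,
                   **{k: v for k, v in pmap.meta.items()
                      if isinstance(v, (int, float, str, tuple, list))}},
                  fh, indent=2, default=list)


def read_phase_png(path: str | Path, plane: SectionPlane | None = None) -> PhaseMap:
    idx = np.asarray(Image.open(path))
    valid = idx != 255
    if plane is None:
        sidecar = Path(str(path) + ".json")
        with open(sidecar) as fh:
            plane = SectionPlane.from_dict(json.load(fh)["plane"])
    return PhaseMap(labels=np.where(valid, idx, 0).astype(np.uint8),
                    valid_mask=valid, plane=plane)
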