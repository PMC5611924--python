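"""Persistence of TCSPC cubes (HDF5, schema v1) and frame rendering (TIFF/PNG).

Container layout (schema version "1"): dataset ``counts`` of shape
``(nx, ny, nt)`` uint32, root attributes ``bin_ps``, ``window_ps``,
``exposure_s``, ``pixel_pitch_cm``, ``pulse_count``, ``seed``, ``scenario``
and ``schema_version``; remaining provenance as a JSON string attribute.
Round trips are bit-exact.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .camera import TCSPCCube

SCHEMA_VERSION = "1"

_REQUIRED_ATTRS = ("bin_ps", "window_ps", "exposure_s", "pixel_pitch_cm",
                   "pulse_count")


class SchemaError(ValueError):
    """Missing, malformed or unsupported cube-file schema."""


def write_cube(cube: TCSPCCube, path) -> None:
    """Write a cube to an HDF5 container (schema v1, lossless)."""
    counts = cube.counts
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("only integer-count cubes are persisted; "
                             "baseline-subtracted cubes are in-memory objects")
        counts = np.round(counts).astype(np.uint32)
    meta = dict(cube.meta)
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("counts", data=counts.astype(np.uint32),
                         track_times=False)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["bin_ps"] = float(cube.bin_ps)
        f.attrs["window_ps"] = float(cube.window_ps)
        f.attrs["exposure_s"] = float(cube.exposure_s)
        f.attrs["pixel_pitch_cm"] = float(cube.pitch_cm)
        f.attrs["pulse_count"] = int(cube.pulse_count)
        f.attrs["seed"] = int(meta.pop("seed", -1))
        f.attrs["scenario"] = str(meta.pop("scenario", ""))
        f.attrs["meta_json"] = json.dumps(meta, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_cube(path) -> TCSPCCube:
    """Read a schema-v1 cube; raises :class:`SchemaError` on any mismatch."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise SchemaError("not a cube file: missing 'schema_version' attribute")
        if str(version) != SCHEMA_VERSION:
            raise SchemaError(f"unsupported cube schema version {version!r} "
                              f"(expected {SCHEMA_VERSION!r})")
        if "counts" not in f:
            raise SchemaError("truncated cube file: missing 'counts' dataset")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise SchemaError(f"truncated cube file: missing attribute {attr!r}")
        counts = f["counts"][...]
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        if "seed" in f.attrs and int(f.attrs["seed"]) >= 0:
            meta["seed"] = int(f.attrs["seed"])
        scenario = str(f.attrs.get("scenario", ""))
        if scenario:
            meta["scenario"] = scenario
        return TCSPCCube(
            counts=counts,
            bin_ps=float(f.attrs["bin_ps"]),
            window_ps=float(f.attrs["window_ps"]),
            exposure_s=float(f.attrs["exposure_s"]),
            pulse_count=int(f.attrs["pulse_count"]),
            pitch_cm=float(f.attrs["pixel_pitch_cm"]),
            meta=meta,
        )


def frame_stack(cube: TCSPCCube, stride: int = 1,
                normalization: str = "frame"):
    """Reduce a cube to ``ceil(nt / stride)`` image frames.

    Each frame sums ``stride`` consecutive TDC bins (e.g. stride 4 at 50 ps
    bins gives 200 ps intervals).  ``normalization`` scales each frame to
    the 16-bit range by its own maximum (``"frame"``), by the global maximum
    (``"global"``), or not at all (``"none"``, raw counts).

    Returns ``(frames_uint, cmax_per_frame)``; frames are oriented as images
    (rows = y decreasing so that y points upward, columns = x).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if normalization not in ("frame", "global", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    nt = cube.nt
    n_frames = math.ceil(nt / stride)
    arr = cube.counts
    frames = np.stack([
        arr[:, :, j * stride:(j + 1) * stride].sum(axis=2) for j in range(n_frames)
    ])
    cmax = frames.reshape(n_frames, -1).max(axis=1)
    # image orientation: row 0 = top = largest y
    imgs = frames.transpose(0, 2, 1)[:, ::-1, :]
    if normalization == "none":
        return imgs.astype(np.uint32), cmax
    denom = np.where(cmax > 0, cmax, 1).astype(float)
    if normalization == "global":
        denom = np.full(n_frames, max(float(cmax.max()), 1.0))
    scaled = (imgs / denom[:, None, None] * 65535.0).round().astype(np.uint16)
    return scaled, cmax


def export_frames(cube: TCSPCCube, path, stride: int = 1,
                  normalization: str = "frame") -> int:
    """Write the frame stack as a multi-page TIFF (or numbered PNGs).

    A ``.tif``/``.tiff`` path receives one page per frame; any other path is
    treated as a directory receiving ``frame_0000.png`` etc.  Returns the
    number of frames written.
    """
    imgs, _ = frame_stack(cube, stride=stride, normalization=normalization)
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, imgs, photometric="minisblack")
    else:
        import imageio.v3 as iio
        p.mkdir(parents=True, exist_ok=True)
        for j, img in enumerate(imgs):
            iio.imwrite(p / f"frame_{j:04d}.png", img.astype(np.uint16))
    return imgs.shape[0]
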