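"""File formats: track CSV, cell/foci JSON, movie TIFF, config YAML.

All persisted positions are in μm and times in seconds; PSF widths are in
pixels (as fit), with the pixel size recorded alongside wherever they
appear.  Frames are stored 0-based; a CSV declaring ``frames_base: 1`` in
its sidecar dialect flag (or via the ``frames_base`` argument) is converted
on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import CellOutline
from .synthetic import FociSet, ImageStack
from .tracks import TRACK_COLUMNS, Track, frame_to_tracks, tracks_to_frame

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_cells",
    "write_cells",
    "read_foci",
    "write_foci",
    "read_stack",
    "write_stack",
    "read_config",
    "write_config",
]


class SchemaError(ValueError):
    pass


def write_tracks(tracks: list[Track] | pd.DataFrame, path) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else tracks_to_frame(tracks)
    df.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path, frames_base: int = 0) -> list[Track]:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track table missing column(s): {', '.join(missing)}")
    if frames_base not in (0, 1):
        raise ValueError("frames_base must be 0 or 1")
    if frames_base == 1 and len(df):
        df = df.assign(frame=df["frame"] - 1)
    return frame_to_tracks(df)


def write_cells(cells: list[CellOutline], path) -> None:
    payload = [
        {
            "cell_id": c.cell_id,
            "vertices": c.vertices.tolist(),
            "pole_a": c.pole_a.tolist(),
            "pole_b": c.pole_b.tolist(),
            "length": c.length,
            "width": c.width,
        }
        for c in cells
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_cells(path) -> list[CellOutline]:
    payload = json.loads(Path(path).read_text())
    return [
        CellOutline(
            cell_id=int(d["cell_id"]),
            vertices=np.array(d["vertices"]),
            pole_a=np.array(d["pole_a"]),
            pole_b=np.array(d["pole_b"]),
            length=float(d["length"]),
            width=float(d["width"]),
        )
        for d in payload
    ]


def write_foci(foci: list[FociSet], path) -> None:
    payload = [
        {
            "cell_id": f.cell_id,
            "centroids": f.centroids.tolist(),
            "widths": None if f.widths is None else np.asarray(f.widths).tolist(),
            "amplitudes": None
            if f.amplitudes is None
            else np.asarray(f.amplitudes).tolist(),
            "backgrounds": None
            if f.backgrounds is None
            else np.asarray(f.backgrounds).tolist(),
        }
        for f in foci
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_foci(path) -> list[FociSet]:
    payload = json.loads(Path(path).read_text())
    return [
        FociSet(
            cell_id=int(d["cell_id"]),
            centroids=np.array(d["centroids"]).reshape(-1, 2),
            widths=None if d.get("widths") is None else np.array(d["widths"]),
            amplitudes=None
            if d.get("amplitudes") is None
            else np.array(d["amplitudes"]),
            backgrounds=None
            if d.get("backgrounds") is None
            else np.array(d["backgrounds"]),
        )
        for d in payload
    ]


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(
        path,
        stack.data,
        metadata={
            "pixel_size_um": stack.pixel_size,
            "origin_um": list(stack.origin),
        },
    )


def read_stack(path, pixel_size: float = 0.106, origin=(0.0, 0.0)) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata
        if meta:
            m = meta[0]
            pixel_size = float(m.get("pixel_size_um", pixel_size))
            origin = tuple(m.get("origin_um", origin))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data=data, pixel_size=pixel_size, origin=origin)


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
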