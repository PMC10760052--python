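"""TIFF / CSV / JSON input-output.

Movies are written as multi-page 16-bit unsigned TIFF (frames as pages),
one file per channel with a ``_chA``/``_chB`` filename suffix; tables go
to CSV and run metadata to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile


def write_stack(stack, path) -> Path:
    """Write a movie as multi-page uint16 TIFF (values clipped to range)."""
    path = Path(path)
    data = np.asarray(getattr(stack, "data", stack))
    if data.ndim == 2:
        data = data[None]
    u16 = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = {
        "pixel_size_um": getattr(stack, "pixel_size_um", None),
        "frame_interval_s": getattr(stack, "frame_interval_s", None),
        "channel": getattr(stack, "channel", ""),
        "field_id": getattr(stack, "field_id", ""),
    }
    tifffile.imwrite(path, u16, photometric="minisblack", metadata=meta)
    return path


def read_stack(path):
    """Read a multi-page TIFF back as a TirfStack (float data)."""
    from .simulate import TirfStack
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return TirfStack(
        data,
        pixel_size_um=float(meta.get("pixel_size_um") or 0.16),
        frame_interval_s=float(meta.get("frame_interval_s") or 0.1),
        channel=str(meta.get("channel") or _channel_from_name(path)),
        field_id=str(meta.get("field_id") or ""))


def _channel_from_name(path: Path) -> str:
    stem = Path(path).stem
    for suffix in ("chA", "chB"):
        if stem.endswith("_" + suffix):
            return suffix
    return ""


def stack_path(outdir, field_id: str, channel: str) -> Path:
    return Path(outdir) / f"field{field_id}_{channel}.tif"


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable))
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
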