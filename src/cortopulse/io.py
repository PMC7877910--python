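"""File I/O: TIFF stacks, 0/255 mask TIFFs, CSV tables with provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import ImageStack, RegionMask

__all__ = [
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "write_json",
    "file_sha256",
]


def write_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata={
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
        },
    )


def read_stack(path, pixel_size_um: float | None = None, frame_interval_s: float | None = None) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    dt = frame_interval_s if frame_interval_s is not None else float(meta.get("frame_interval_s", 0.0))
    return ImageStack(data, px, dt)


def write_mask(path, mask: RegionMask) -> None:
    tifffile.imwrite(
        path,
        (mask.mask.astype(np.uint8)) * 255,
        metadata={"pixel_size_um": mask.pixel_size_um},
    )


def read_mask(path, pixel_size_um: float | None = None) -> RegionMask:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    px = pixel_size_um if pixel_size_um is not None else float(meta.get("pixel_size_um", 1.0))
    return RegionMask(data > 0, px)


def write_table(path, df: pd.DataFrame, header_comment: str | None = None) -> None:
    """CSV with an optional ``#``-prefixed provenance comment block."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
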