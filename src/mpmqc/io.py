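"""TIFF / OME-TIFF and sidecar I/O.

Movies and stacks travel as (OME-)TIFF via :mod:`tifffile`; generator
parameters, seeds and physical metadata go in a JSON sidecar next to the
image file so a synthetic dataset is fully reproducible from disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import FrameSequence


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def save_frame_sequence(path: str | Path, seq: FrameSequence, *,
                        dtype=np.uint16) -> None:
    """Write a movie as OME-TIFF plus a JSON sidecar with its metadata."""
    path = Path(path)
    data = np.asarray(seq.data)
    info = np.iinfo(dtype)
    if data.min() < info.min or data.max() > info.max:
        raise ValueError(f"data outside {np.dtype(dtype).name} range; "
                         "choose a wider dtype")
    tifffile.imwrite(path, data.astype(dtype), ome=True,
                     photometric="minisblack", metadata={"axes": "TYX"})
    sidecar = {"dx": seq.dx, "dy": seq.dy, "dt": seq.dt, "meta": seq.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, default=str, indent=1))


def load_frame_sequence(path: str | Path) -> FrameSequence:
    """Read a movie written by :func:`save_frame_sequence` (sidecar optional)."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    kwargs = {}
    sc = _sidecar_path(path)
    if sc.exists():
        side = json.loads(sc.read_text())
        kwargs = {k: side.get(k) for k in ("dx", "dy", "dt")}
        kwargs["meta"] = side.get("meta", {})
    return FrameSequence(data, **kwargs)


def save_image(path: str | Path, image: np.ndarray, *, dtype=np.float32) -> None:
    """Write a single diagnostic image (e.g. a CoV map) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=dtype))


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))
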