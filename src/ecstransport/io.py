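"""TIFF + JSON-sidecar I/O for stacks and section images.

Physical calibration and ground-truth metadata do not fit naturally in
TIFF tags across tools, so every TIFF is written with a JSON sidecar
(same stem, ``.json``) holding pixel size, frame interval, channel
names/exposures and any generator truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import InvalidParameterError
from .frap import ImageStack
from .maps import SectionImage

__all__ = ["save_stack", "load_stack", "save_section", "load_section"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
        metadata={"axes": "TYX"},
    )
    sidecar = {
        "kind": "frap-stack",
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "prebleach_count": stack.prebleach_count,
        "metadata": _jsonable(stack.metadata),
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidParameterError(f"missing calibration sidecar {side}")
    meta = json.loads(side.read_text())
    return ImageStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_s"]),
        prebleach_count=int(meta["prebleach_count"]),
        metadata=meta.get("metadata", {}),
    )


def save_section(image: SectionImage, path: str | Path) -> Path:
    path = Path(path)
    names = sorted(image.channels)
    data = np.stack([image.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", metadata={"axes": "CYX"})
    sidecar = {
        "kind": "section-image",
        "pixel_size_um": image.pixel_size,
        "channels": names,
        "exposure_us": _jsonable(image.exposure),
        "metadata": _jsonable(image.metadata),
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_section(path: str | Path) -> SectionImage:
    path = Path(path)
    data = tifffile.imread(path)
    side = _sidecar(path)
    if not side.exists():
        raise InvalidParameterError(f"missing calibration sidecar {side}")
    meta = json.loads(side.read_text())
    names = meta["channels"]
    if data.ndim == 2:
        data = data[None]
    channels = {n: np.asarray(data[i], dtype=float) for i, n in enumerate(names)}
    return SectionImage(
        channels=channels,
        pixel_size=float(meta["pixel_size_um"]),
        exposure={k: float(v) for k, v in meta.get("exposure_us", {}).items()},
        metadata=meta.get("metadata", {}),
    )
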