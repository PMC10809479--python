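"""Stack and artifact I/O.

Stacks travel as multi-page float TIFF (lossless round-trip of the [0, 1]
float data) with a JSON metadata sidecar, or as a directory of numbered
8-bit PNG frames (documented lossy: intensities quantized to 1/255).
Sidecar fields ``layer`` and ``laterality`` are mandatory; a missing
field is an error naming it.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import tifffile
from imageio.v3 import imread, imwrite

from .datatypes import ImageStack

__all__ = ["write_stack", "read_stack", "write_float_tiff", "write_png"]

REQUIRED_SIDECAR = ("layer", "laterality")


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_stack(stack: ImageStack, path: Union[str, Path]) -> Path:
    """Write a stack as multi-page float32 TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "eye_id": stack.eye_id,
        "layer": stack.layer,
        "laterality": stack.laterality,
        "group": stack.group,
        "signal_strength": stack.signal_strength.tolist(),
        "scale_um_per_px": stack.scale_um_per_px,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path) if path.suffix else path / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for field in REQUIRED_SIDECAR:
        if field not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required "
                             f"field {field!r}")
    return meta


def read_stack(path: Union[str, Path]) -> ImageStack:
    """Read a stack from a multi-page TIFF or a PNG-directory layout."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_sidecar(path)
    if path.is_dir():
        frames_files = sorted(path.glob("*.png"))
        if not frames_files:
            raise ValueError(f"no PNG frames found in {path}")
        frames = [np.asarray(imread(f), dtype=np.float64) / 255.0
                  for f in frames_files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            bad = [str(f) for f, a in zip(frames_files, frames)
                   if a.shape != frames[0].shape]
            raise ValueError(f"frames with mismatched sizes: {bad}")
        arr = np.stack(frames)
    else:
        arr = np.asarray(tifffile.imread(path), dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"{path} does not hold a T x H x W stack")
    return ImageStack(
        frames=arr,
        eye_id=meta.get("eye_id", path.stem),
        layer=meta["layer"],
        laterality=meta["laterality"],
        group=meta.get("group", "unknown"),
        signal_strength=np.asarray(meta["signal_strength"])
        if "signal_strength" in meta else None,
        scale_um_per_px=meta.get("scale_um_per_px", 12.0),
    )


def write_float_tiff(array: np.ndarray, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def write_png(array: np.ndarray, path: Union[str, Path]) -> Path:
    """8-bit export; float inputs in [0, 1] scale by 255 with rounding."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    imwrite(path, arr)
    return path
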