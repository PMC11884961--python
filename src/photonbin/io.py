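"""Stack I/O and run configuration.

Frame stacks travel as multi-page grayscale TIFF files with a JSON sidecar
(``<name>.tif.json``) holding the acquisition metadata a bare TIFF cannot:
frame interval, nominal bit depth and the processing provenance chain.
``write_stack`` followed by ``read_stack`` is the identity on data and
metadata. Frames are indexed (t, row, col), 0-based, with half-open ROI
intervals throughout.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .binning import FrameStack

__all__ = ["read_stack", "write_stack", "sidecar_path", "RunConfig"]


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.name + ".json")


def _storage_dtype(stack: FrameStack) -> np.dtype:
    if np.issubdtype(stack.data.dtype, np.integer):
        for bits, dt in ((8, np.uint8), (16, np.uint16), (32, np.uint32)):
            if stack.bit_depth <= bits:
                return np.dtype(dt)
        raise ValueError(f"bit depth {stack.bit_depth} too large for TIFF storage")
    return np.dtype(np.float32) if stack.data.dtype == np.float32 else np.dtype(np.float64)


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as multi-page grayscale TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(_storage_dtype(stack)), photometric="minisblack")
    meta = {
        "frame_interval": stack.frame_interval,
        "bit_depth": stack.bit_depth,
        "provenance": stack.provenance,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page grayscale TIFF written by :func:`write_stack`.

    A missing sidecar degrades gracefully: defaults (frame_interval = 1 s,
    bit depth from the sample format) are applied with a warning.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a grayscale T x H x W stack (shape {data.shape})")

    sc = sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    else:
        warnings.warn(f"no sidecar {sc.name}; using default metadata", stacklevel=2)
        meta = {}
    bit_depth = meta.get("bit_depth", data.dtype.itemsize * 8)
    if np.issubdtype(data.dtype, np.integer) and bit_depth > data.dtype.itemsize * 8:
        raise ValueError(
            f"sidecar bit depth {bit_depth} exceeds the {data.dtype} sample format"
        )
    return FrameStack(
        data=data,
        frame_interval=float(meta.get("frame_interval", 1.0)),
        bit_depth=int(bit_depth),
        provenance=meta.get("provenance", "raw"),
    )


@dataclasses.dataclass
class RunConfig:
    """Resolved parameters of a pipeline run, written next to its outputs.

    Round-trips losslessly through YAML so any run can be reproduced from the
    config file it left behind.
    """

    camera: dict = dataclasses.field(default_factory=dict)
    scene: dict = dataclasses.field(default_factory=dict)
    pipeline: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)
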