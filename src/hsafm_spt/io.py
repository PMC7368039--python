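"""Calibrated image stacks and on-disk fixture bundles.

A movie is stored as a multi-frame 32-bit float TIFF whose pixel values are
heights in nm above the bilayer plane, together with a JSON calibration
sidecar carrying the physical pixel size and frame interval.  Keeping the
calibration outside the TIFF avoids any reliance on writer-specific tag
conventions and makes the bundle trivially diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "CalibrationError"]

SIDECAR_SUFFIX = ".calib.json"


class CalibrationError(FileNotFoundError):
    """Raised when a movie is missing its physical-calibration sidecar."""


@dataclass
class ImageStack:
    """Multi-frame height map with physical calibration.

    Parameters
    ----------
    data:
        Array of shape ``(n_frames, n_rows, n_cols)`` holding heights in nm
        above the bilayer plane (bilayer = 0).
    nm_per_pixel:
        Lateral calibration; pixel centers sit at integer pixel coordinates,
        physical position = pixel index * nm_per_pixel.
    frame_interval_s:
        Time between consecutive frames (frames are treated as instantaneous
        snapshots; raster-line skew is not modelled).
    """

    data: np.ndarray
    nm_per_pixel: float
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack must be (frame, row, col); got shape {self.data.shape}"
            )
        if self.nm_per_pixel <= 0 or self.frame_interval_s <= 0:
            raise ValueError("nm_per_pixel and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def field_size_nm(self) -> float:
        return self.data.shape[-1] * self.nm_per_pixel

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def __getitem__(self, i):
        return self.data[i]


def _sidecar_path(tiff_path: Path) -> Path:
    stem = tiff_path.name.rsplit(".", 1)[0]
    return tiff_path.parent / (stem + SIDECAR_SUFFIX)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a movie as float32 TIFF plus a JSON calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    sidecar = _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "nm_per_pixel": stack.nm_per_pixel,
                "frame_interval_s": stack.frame_interval_s,
                "units": "nm",
                **stack.meta,
            },
            indent=2,
        )
    )
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a movie written by :func:`write_stack`.

    Raises
    ------
    CalibrationError
        If the ``*.calib.json`` sidecar is absent — an uncalibrated stack
        cannot be analysed in physical units.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise CalibrationError(
            f"missing calibration sidecar {sidecar.name!r} next to {path.name!r}"
        )
    meta = json.loads(sidecar.read_text())
    try:
        nm_per_pixel = float(meta.pop("nm_per_pixel"))
        frame_interval_s = float(meta.pop("frame_interval_s"))
    except KeyError as exc:  # pragma: no cover - malformed sidecar
        raise CalibrationError(f"calibration sidecar lacks key {exc}") from exc
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(data, nm_per_pixel, frame_interval_s, meta=meta)
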