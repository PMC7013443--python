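"""Domain types for frames, camera geometry and the spectral channel-mixing model.

The imaging rig is a nadir-mounted RGB machine-vision camera with its NIR-cut
filter removed and a 515 nm long-pass filter added, flashing 650 nm (red),
850 nm (NIR) and 525 nm (green) LED arrays simultaneously.  Every camera
channel therefore responds to every band; the 3x3 quantum-efficiency matrix
and the per-band LED duty cycles together define the effective channel
response that both the detection pipeline and the synthetic renderer share.

Conventions
-----------
* Pixel coordinates: origin top-left, (row, col), 0-based.  The direction of
  travel maps to the row axis, so the leading/trailing edges of the imaged
  strip are the top and bottom of each frame.
* Physical ground coordinates: millimetres, x along travel, y across, origin
  at the frame centre (the camera nadir point).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Frame",
    "CameraGeometry",
    "ChannelMixMatrix",
    "IlluminationConfig",
    "FrameFormatError",
    "load_frame",
    "save_frame",
    "effective_response",
]

# Estimated quantum efficiency of the modified camera's channels at the three
# illumination bands.  Rows: camera channels (red, green, blue); columns:
# bands in (650 nm, 850 nm, 525 nm) order.
DEFAULT_CHANNEL_MIX = np.array(
    [
        [0.45, 0.15, 0.05],
        [0.03, 0.15, 0.45],
        [0.05, 0.15, 0.15],
    ]
)

_TIMESTAMP_RE = re.compile(r"_(\d{10,16})$")


class FrameFormatError(ValueError):
    """Raised when an image file violates the 8-bit 3-channel frame contract."""


@dataclass
class Frame:
    """One captured 3-channel 8-bit image.

    ``red``/``green``/``blue`` are 2-D uint8 arrays of identical shape;
    ``timestamp`` is seconds (monotonic epoch when parsed from a filename);
    ``index`` is the frame counter within a run.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    timestamp: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        if not (self.red.shape == self.green.shape == self.blue.shape):
            raise ValueError("frame channels must have identical dimensions")
        for name in ("red", "green", "blue"):
            ch = getattr(self, name)
            if ch.ndim != 2:
                raise ValueError(f"{name} channel must be 2-D")
            if ch.dtype != np.uint8:
                a = np.asarray(ch)
                if a.min() < 0 or a.max() > 255:
                    raise ValueError(f"{name} channel intensities outside [0, 255]")
                setattr(self, name, a.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def as_array(self) -> np.ndarray:
        """Stack channels into an (H, W, 3) uint8 RGB array."""
        return np.stack([self.red, self.green, self.blue], axis=-1)


@dataclass
class CameraGeometry:
    """Nadir-camera geometry on the ground plane.

    At the working height of 0.6 m the field of view is 0.54 x 0.54 m at a
    ground resolution of ~0.9481 px/mm.  ``focal_px`` is a calibration input;
    when omitted it is derived from pinhole consistency as
    ``px_per_mm * height_mm``.
    """

    height_mm: float = 600.0
    frame_width_px: int = 512
    frame_height_px: int = 512
    fov_mm: float = 540.0
    px_per_mm: float | None = None
    focal_px: float | None = None

    def __post_init__(self) -> None:
        if self.height_mm <= 0:
            raise ValueError("height_mm must be > 0")
        if self.px_per_mm is None:
            self.px_per_mm = self.frame_width_px / self.fov_mm
        if self.focal_px is None:
            self.focal_px = self.px_per_mm * self.height_mm
        if self.focal_px <= 0:
            raise ValueError("focal_px must be > 0")
        implied = self.frame_width_px / self.fov_mm
        if abs(implied - self.px_per_mm) > 0.01 * self.px_per_mm:
            raise ValueError(
                f"px_per_mm={self.px_per_mm:.4f} inconsistent with "
                f"frame_width_px/fov_mm={implied:.4f} (>1% off)"
            )

    @property
    def centre_px(self) -> tuple[float, float]:
        """Nadir point in pixel coordinates (row, col)."""
        return ((self.frame_height_px - 1) / 2.0, (self.frame_width_px - 1) / 2.0)

    def px_to_ground_mm(self, row: float, col: float) -> tuple[float, float]:
        """Apparent ground-plane position (x along travel, y across) in mm."""
        cr, cc = self.centre_px
        return ((row - cr) / self.px_per_mm, (col - cc) / self.px_per_mm)

    def ground_mm_to_px(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        cr, cc = self.centre_px
        return (cr + x_mm * self.px_per_mm, cc + y_mm * self.px_per_mm)


@dataclass
class ChannelMixMatrix:
    """3x3 quantum-efficiency matrix: rows = camera channels (R, G, B),
    columns = illumination bands (650, 850, 525 nm), entries in [0, 1]."""

    matrix: np.ndarray = field(default_factory=lambda: DEFAULT_CHANNEL_MIX.copy())

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("channel mix matrix must be 3x3")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("quantum efficiencies must lie in [0, 1]")


@dataclass
class IlluminationConfig:
    """Per-band LED duty cycles (fraction of exposure each array is driven).

    Defaults are the balanced-response setting: 50% NIR, 50% green, 20% red.
    """

    red: float = 0.20
    nir: float = 0.50
    green: float = 0.50

    def __post_init__(self) -> None:
        for name in ("red", "nir", "green"):
            d = getattr(self, name)
            if not (0.0 < d <= 1.0):
                raise ValueError(f"duty cycle {name}={d} must lie in (0, 1]")

    @property
    def by_band(self) -> np.ndarray:
        """Duty cycles ordered as the mix-matrix columns (650, 850, 525 nm)."""
        return np.array([self.red, self.nir, self.green])


def effective_response(mix: ChannelMixMatrix, illum: IlluminationConfig) -> np.ndarray:
    """Effective channel response: each QE column scaled by its band's duty cycle.

    This is the matrix the synthetic renderer applies to band reflectances:
    ``channel_signal = effective_response @ reflectance_(650,850,525)``.
    """
    return mix.matrix * illum.by_band[np.newaxis, :]


def _parse_timestamp(path: str) -> float | None:
    stem = os.path.splitext(os.path.basename(path))[0]
    m = _TIMESTAMP_RE.search(stem)
    if m:
        return int(m.group(1)) / 1000.0
    return None


def load_frame(path: str, index: int = 0) -> Frame:
    """Read an 8-bit 3-channel PNG/TIFF as a Frame.

    The capture timestamp is parsed from a ``<prefix>_<epoch-millis>`` filename
    when present, otherwise the file's modification time is used.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # non-image or unreadable
        raise FrameFormatError(f"{path!r} is not a readable image: {exc}") from exc
    if arr.dtype != np.uint8:
        raise FrameFormatError(
            f"{path!r}: bit depth {arr.dtype} not supported, frames must be 8-bit"
        )
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FrameFormatError(
            f"{path!r}: expected 3 channels, got shape {arr.shape}"
        )
    if arr.shape[2] > 4:
        raise FrameFormatError(f"{path!r}: expected 3 channels, got {arr.shape[2]}")
    ts = _parse_timestamp(path)
    if ts is None:
        ts = os.path.getmtime(path)
    return Frame(
        red=arr[..., 0].copy(),
        green=arr[..., 1].copy(),
        blue=arr[..., 2].copy(),
        timestamp=ts,
        index=index,
    )


def save_frame(frame: Frame, path: str) -> None:
    """Write a Frame as an 8-bit RGB PNG/TIFF (bit-exact round trip)."""
    iio.imwrite(path, frame.as_array())
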