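"""Thermal-video container I/O and acquisition-protocol frame arithmetic.

A :class:`ThermalVideo` is a temporally ordered stack of per-pixel temperature
frames (degrees Celsius, 32-bit float) plus a free-form metadata block. Videos
are stored in the ``PTIV`` container: a small self-describing binary header
followed by the raw frame payload, so that round trips are bit-exact.

The :class:`AcquisitionProtocol` records the timing of the pulsed-thermography
acquisition — a front buffer at rest, a heating pulse, a cooling interval and
a rear buffer — and fixes all frame-index arithmetic. Frame indices are 0-based
and phase intervals are half-open ``[start, end)``: the boundary frame belongs
to the later phase.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

import numpy as np

MAGIC = b"PTIV"
FORMAT_VERSION = 1

_HEADER = struct.Struct("<4sHIIIdI")  # magic, version, H, W, F, fps, meta_len


class FormatError(ValueError):
    """Raised when a file is not a PTIV container."""


class CorruptionError(ValueError):
    """Raised when a PTIV container's payload size is inconsistent."""


class VersionError(ValueError):
    """Raised for an unsupported container version."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of one pulsed-thermography acquisition.

    Parameters
    ----------
    front_buffer_s : float
        Seconds recorded at rest before lamp activation.
    heat_s : float
        Seconds of thermal stimulation (lamps on).
    cool_s : float
        Seconds of cooling recorded after lamp deactivation.
    rear_buffer_s : float
        Seconds recorded after the data cutoff.
    fps : float
        Acquisition frame rate, frames per second.
    """

    front_buffer_s: float = 1.0
    heat_s: float = 5.0
    cool_s: float = 10.0
    rear_buffer_s: float = 1.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.heat_s <= 0 or self.cool_s <= 0:
            raise ValueError("heating and cooling durations must be positive")
        if self.front_buffer_s < 0 or self.rear_buffer_s < 0:
            raise ValueError("buffer durations must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for name in ("front_buffer_s", "heat_s", "cool_s", "rear_buffer_s"):
            _as_frames(getattr(self, name), self.fps, name)

    @property
    def total_frames(self) -> int:
        return protocol_frame_indices(self)[3]

    def to_dict(self) -> dict:
        return {
            "front_buffer_s": self.front_buffer_s,
            "heat_s": self.heat_s,
            "cool_s": self.cool_s,
            "rear_buffer_s": self.rear_buffer_s,
            "fps": self.fps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**{k: float(v) for k, v in d.items()})


def _as_frames(seconds: float, fps: float, name: str) -> int:
    frames = seconds * fps
    rounded = round(frames)
    if abs(frames - rounded) > 1e-9 * max(1.0, abs(frames)):
        raise ValueError(
            f"{name} ({seconds} s) times fps ({fps}) is not a whole frame count"
        )
    return int(rounded)


def protocol_frame_indices(protocol: AcquisitionProtocol) -> tuple[int, int, int, int]:
    """Return ``(lamp_on, lamp_off, cutoff, total)`` frame indices.

    ``lamp_on`` is the first heated frame, ``lamp_off`` the first cooling
    frame, ``cutoff`` the first rear-buffer frame, and ``total`` the frame
    count of the full video. With the default 1/5/10/1 s protocol at 30 fps
    these are (30, 180, 480, 510).
    """
    fps = protocol.fps
    lamp_on = _as_frames(protocol.front_buffer_s, fps, "front_buffer_s")
    lamp_off = lamp_on + _as_frames(protocol.heat_s, fps, "heat_s")
    cutoff = lamp_off + _as_frames(protocol.cool_s, fps, "cool_s")
    total = cutoff + _as_frames(protocol.rear_buffer_s, fps, "rear_buffer_s")
    return lamp_on, lamp_off, cutoff, total


@dataclass
class ThermalVideo:
    """A stack of per-pixel temperature frames.

    Attributes
    ----------
    frames : ndarray, shape (F, H, W), float32
        Per-pixel temperatures in degrees Celsius.
    fps : float
        Frame rate of the acquisition.
    metadata : dict
        Textual key-value block (class label, protocol, seed, ...).
    """

    frames: np.ndarray
    fps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a non-empty F x H x W array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


def write_video(video: ThermalVideo, path) -> None:
    """Write *video* to *path* in the PTIV container format.

    Layout: magic ``PTIV``; version (uint16); H, W, F (uint32); fps
    (float64); metadata byte length (uint32); UTF-8 JSON metadata; then the
    frames as little-endian float32, frame-major, row-major within a frame.
    """
    frames = np.ascontiguousarray(video.frames, dtype="<f4")
    n_frames, height, width = frames.shape
    meta = json.dumps(video.metadata, ensure_ascii=False).encode("utf-8")
    header = _HEADER.pack(
        MAGIC, FORMAT_VERSION, height, width, n_frames, float(video.fps), len(meta)
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(meta)
        fh.write(frames.tobytes())


def read_video(path) -> ThermalVideo:
    """Read a PTIV container; exact inverse of :func:`write_video`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size or raw[:4] != MAGIC:
        raise FormatError(f"{path}: not a PTIV container (bad magic)")
    magic, version, height, width, n_frames, fps, meta_len = _HEADER.unpack(
        raw[: _HEADER.size]
    )
    if version != FORMAT_VERSION:
        raise VersionError(f"{path}: unsupported container version {version}")
    offset = _HEADER.size
    expected = offset + meta_len + 4 * n_frames * height * width
    if len(raw) != expected:
        raise CorruptionError(
            f"{path}: payload size {len(raw)} != expected {expected} bytes"
        )
    metadata = json.loads(raw[offset : offset + meta_len].decode("utf-8"))
    offset += meta_len
    frames = np.frombuffer(raw[offset:], dtype="<f4").reshape(n_frames, height, width)
    return ThermalVideo(frames=frames.copy(), fps=fps, metadata=metadata)
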