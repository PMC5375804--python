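"""Specimen segmentation for pulsed-thermography videos.

Three strategies mirror the study protocol: Otsu thresholding of the peak-
temperature frame (used for most contaminant types, with an optional manual
threshold override), a fixed square window at the frame centre (cotton lint,
which fills the field of view), and a centred rectangle (paper squares).
Specimens are hotter than the reflective steel stage, so the foreground is
the above-threshold side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .videoio import ThermalVideo

STRATEGIES = ("otsu", "center_window", "center_rect", "manual_threshold")


@dataclass
class SampleMask:
    """Boolean image selecting the specimen's pixels on one video."""

    mask: np.ndarray
    strategy: str
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask selects no pixels")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def peak_frame_index(video: ThermalVideo) -> int:
    """Index of the frame of peak temperature.

    The peak frame is the one with the maximal spatial mean temperature
    (robust to single hot noisy pixels); ties break to the earliest index.
    """
    means = video.frames.reshape(video.n_frames, -1).mean(axis=1)
    return int(np.argmax(means))


def otsu_mask(
    frame: np.ndarray,
    manual_threshold: float | None = None,
    foreground: str = "above",
) -> SampleMask:
    """Threshold *frame* into specimen (hot) and stage (cool) pixels.

    Without a manual override the threshold maximises the between-class
    variance of a 256-bin histogram spanning the frame's min–max range; the
    mask is ``frame > threshold``. Specimens are hotter than the reflective
    stage, so ``foreground='above'`` is the default; ``'below'`` inverts the
    mask for the unusual case of a target cooler than its background.

    Raises
    ------
    ValueError
        For a constant frame with no manual threshold (no contrast to split).
    """
    frame = np.asarray(frame, dtype=float)
    if foreground not in ("above", "below"):
        raise ValueError("foreground must be 'above' or 'below'")
    if manual_threshold is not None:
        threshold, strategy = float(manual_threshold), "manual_threshold"
    else:
        if np.ptp(frame) == 0:
            raise ValueError(
                "constant frame: Otsu thresholding is degenerate; "
                "supply a manual threshold"
            )
        threshold, strategy = float(threshold_otsu(frame, nbins=256)), "otsu"
    mask = frame > threshold if foreground == "above" else frame <= threshold
    return SampleMask(mask=mask, strategy=strategy, threshold_used=threshold)


def _centered_rect(
    height: int, width: int, rect_h: int, rect_w: int
) -> np.ndarray:
    if rect_h < 1 or rect_w < 1:
        raise ValueError("rectangle dimensions must be >= 1")
    if rect_h > height or rect_w > width:
        raise ValueError(
            f"{rect_h}x{rect_w} region does not fit a {height}x{width} frame"
        )
    r0 = (height - rect_h) // 2
    c0 = (width - rect_w) // 2
    mask = np.zeros((height, width), dtype=bool)
    mask[r0 : r0 + rect_h, c0 : c0 + rect_w] = True
    return mask


def center_window_mask(video: ThermalVideo, side: int) -> SampleMask:
    """Square ``side x side`` window centred in the frame.

    For odd leftovers the extra margin goes to the bottom/right
    (start = floor((dim - side)/2)).
    """
    _, height, width = video.shape
    return SampleMask(
        mask=_centered_rect(height, width, side, side), strategy="center_window"
    )


def center_rect_mask(video: ThermalVideo, rect_height: int, rect_width: int) -> SampleMask:
    """Centred ``rect_height x rect_width`` rectangle, same floor rule."""
    _, height, width = video.shape
    return SampleMask(
        mask=_centered_rect(height, width, rect_height, rect_width),
        strategy="center_rect",
    )
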