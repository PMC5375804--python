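"""Waveform and pulse-phase (frequency-domain) feature extraction.

The analysed signal is the specimen's mean temperature per frame. Waveform
features are two scalar gains read at the protocol landmarks: peak minus rest
(temperature gain after heating) and final minus rest (gain remaining after
cooling). Pulse-phase features come from the discrete Fourier transform of
the buffer-trimmed trace — either of the whole rising+falling signal or of
the rising and falling portions separately. For an even ``N``-frame input the
retained components are indices ``0 .. N/2 - 1`` (frequencies ``k*fps/N``);
the aliased upper half and the exact-Nyquist bin are discarded, and the 0-Hz
phase (identically zero for a real signal) is dropped. Amplitudes are moduli
of the raw, unnormalised transform; phases are phasor angles in (-pi, pi].

Per-pixel transforms of a trimmed video at one retained component yield the
ampligram (amplitude image) and phasegram (phase image).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SampleMask
from .videoio import AcquisitionProtocol, ThermalVideo, protocol_frame_indices

MODES = ("whole", "rising", "falling")


@dataclass
class TemperatureTrace:
    """Per-frame mean temperature of a specimen's pixels."""

    values: np.ndarray
    fps: float
    protocol: AcquisitionProtocol
    trimmed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        lamp_on, _, cutoff, total = protocol_frame_indices(self.protocol)
        expected = cutoff - lamp_on if self.trimmed else total
        if len(self.values) != expected:
            raise ValueError(
                f"trace length {len(self.values)} does not match protocol "
                f"({'trimmed' if self.trimmed else 'untrimmed'} length {expected})"
            )


@dataclass(frozen=True)
class WaveformFeatures:
    """Temperature gain after heating and after heating+cooling, degrees C."""

    peak_minus_rest: float
    final_minus_rest: float


@dataclass
class SpectralFeatures:
    """Retained Fourier components of one trace.

    ``amplitudes`` has ``N/2`` entries for an ``N``-frame trace;
    ``phases`` excludes the 0-Hz component and has ``N/2 - 1``.
    """

    mode: str
    frequencies: np.ndarray  # Hz, one per retained component
    amplitudes: np.ndarray
    phases: np.ndarray  # radians in (-pi, pi], component indices 1..N/2-1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.phases) != len(self.amplitudes) - 1:
            raise ValueError("phases must exclude exactly the 0-Hz component")


def mean_trace(video: ThermalVideo, mask: SampleMask) -> TemperatureTrace:
    """Mean temperature of the masked pixels in every frame."""
    if mask.mask.shape != video.frames.shape[1:]:
        raise ValueError("mask dimensions do not match the video")
    values = video.frames[:, mask.mask].mean(axis=1)
    protocol = AcquisitionProtocol.from_dict(video.metadata["protocol"]) \
        if "protocol" in video.metadata else None
    if protocol is None:
        raise ValueError("video metadata carries no acquisition protocol")
    return TemperatureTrace(values=values, fps=video.fps, protocol=protocol)


def trim_buffers(trace: TemperatureTrace) -> TemperatureTrace:
    """Drop the front and rear buffers, keeping frames [lamp_on, cutoff).

    The default 1/5/10/1 s protocol at 30 fps yields exactly 450 frames.
    """
    if trace.trimmed:
        raise ValueError("trace is already trimmed")
    lamp_on, _, cutoff, _ = protocol_frame_indices(trace.protocol)
    return TemperatureTrace(
        values=trace.values[lamp_on:cutoff],
        fps=trace.fps,
        protocol=trace.protocol,
        trimmed=True,
    )


def waveform_features(
    trace: TemperatureTrace, smooth_window: int = 0
) -> WaveformFeatures:
    """Peak-minus-rest and final-minus-rest temperature gains.

    Rest, peak and final are single-frame reads at the lamp-on, lamp-off and
    cutoff frames of the untrimmed trace; ``smooth_window=w`` averages over
    ±w frames around each landmark (clipped at the trace ends) to damp
    camera noise. For a zero-rear-buffer protocol the cutoff frame does not
    exist and the last frame is used instead.
    """
    if trace.trimmed:
        raise ValueError("waveform features require the untrimmed trace")
    if smooth_window < 0:
        raise ValueError("smooth_window must be non-negative")
    lamp_on, lamp_off, cutoff, total = protocol_frame_indices(trace.protocol)

    def read(frame: int) -> float:
        lo = max(0, frame - smooth_window)
        hi = min(total, frame + smooth_window + 1)
        return float(trace.values[lo:hi].mean())

    rest = read(lamp_on)
    peak = read(lamp_off)
    final = read(min(cutoff, total - 1))
    return WaveformFeatures(
        peak_minus_rest=peak - rest, final_minus_rest=final - rest
    )


def split_trace(trace: TemperatureTrace) -> tuple[np.ndarray, np.ndarray]:
    """Split a trimmed trace into its rising (heating) and falling (cooling) parts."""
    if not trace.trimmed:
        raise ValueError("split requires a buffer-trimmed trace")
    lamp_on, lamp_off, _, _ = protocol_frame_indices(trace.protocol)
    n_rising = lamp_off - lamp_on
    return trace.values[:n_rising], trace.values[n_rising:]


def _retained_dft(values: np.ndarray, fps: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(values)
    if n % 2 != 0:
        raise ValueError(f"spectral analysis requires an even trace length, got {n}")
    spectrum = np.fft.fft(values)[: n // 2]  # drop aliased half + Nyquist bin
    frequencies = np.arange(n // 2) * fps / n
    amplitudes = np.abs(spectrum)
    phases = np.angle(spectrum[1:])
    return frequencies, amplitudes, phases


def spectral_features(trace: TemperatureTrace, mode: str = "whole") -> SpectralFeatures:
    """Retained DFT amplitudes and phases of a trimmed trace.

    ``mode='whole'`` transforms the full trimmed signal; ``'rising'`` and
    ``'falling'`` transform the corresponding split portion. A 450-frame
    whole trace yields 225 amplitudes and 224 phases; the default 150/300
    split yields 75/74 and 150/149.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not trace.trimmed:
        raise ValueError("spectral features require a buffer-trimmed trace")
    if mode == "whole":
        values = trace.values
    else:
        rising, falling = split_trace(trace)
        values = rising if mode == "rising" else falling
    frequencies, amplitudes, phases = _retained_dft(values, trace.fps)
    return SpectralFeatures(
        mode=mode, frequencies=frequencies, amplitudes=amplitudes, phases=phases
    )


def pixelwise_spectra(
    video: ThermalVideo, mask: SampleMask, component_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Phasegram and ampligram of a trimmed video at one retained component.

    The video must already be trimmed to the analysis window (even frame
    count). Pixels outside the mask are NaN. Returns ``(phasegram,
    ampligram)`` images of shape (H, W).
    """
    n = video.n_frames
    if n % 2 != 0:
        raise ValueError("pixelwise spectra require an even frame count")
    retained = n // 2
    if not 0 <= component_index < retained:
        raise ValueError(
            f"component index {component_index} outside retained range [0, {retained})"
        )
    if mask.mask.shape != video.frames.shape[1:]:
        raise ValueError("mask dimensions do not match the video")
    spectrum = np.fft.fft(video.frames.astype(float), axis=0)[component_index]
    phasegram = np.where(mask.mask, np.angle(spectrum), np.nan)
    ampligram = np.where(mask.mask, np.abs(spectrum), np.nan)
    return phasegram, ampligram


def amplitude_subset(features: SpectralFeatures, k: int) -> np.ndarray:
    """The ``k`` lowest-frequency amplitudes, in increasing frequency order."""
    if not 1 <= k <= len(features.amplitudes):
        raise ValueError(
            f"k={k} outside valid range [1, {len(features.amplitudes)}]"
        )
    return features.amplitudes[:k].copy()
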