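"""Raw-signal filtering, gravity/movement decomposition and windowing.

The raw 60 Hz triaxial signal is low-pass filtered at 20 Hz to remove
noise, then split at 0.5 Hz into a *static* (gravity / orientation)
stream and a *dynamic* (movement) stream, ``dynamic = noise_filtered -
static``.  Both streams are cut into non-overlapping 10-s windows, but
only the minutes flagged as gas-sampling minutes in the activity
annotations are analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from . import DEVICE_RANGE_G, SAMPLE_RATE_HZ, WINDOW_SAMPLES

__all__ = [
    "ActivityInterval",
    "RawRecording",
    "DecomposedSignal",
    "WindowFrame",
    "lowpass_filter",
    "decompose",
    "segment_windows",
]


@dataclass(frozen=True)
class ActivityInterval:
    """One annotated activity interval, in seconds from recording start.

    ``gas_minute`` is 0 for ordinary intervals; gas-sampling minutes carry
    the 1-based minute id (1 or 2 in the standard protocol).  ``posture``
    is the observed (video-criterion) posture for the interval, either
    ``"upright"`` or ``"not_upright"``.
    """

    activity_code: int
    start_s: float
    end_s: float
    gas_minute: int = 0
    posture: str = "not_upright"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"activity {self.activity_code}: empty interval "
                f"[{self.start_s}, {self.end_s})"
            )
        if self.posture not in ("upright", "not_upright"):
            raise ValueError(f"unknown posture {self.posture!r}")


@dataclass
class RawRecording:
    """One participant's raw 60 Hz triaxial recording with annotations.

    ``samples`` is an (n, 3) array in g, axis order X (mediolateral),
    Y (vertical when standing), Z (anteroposterior).
    """

    participant_id: str
    samples: np.ndarray
    annotations: list[ActivityInterval] = field(default_factory=list)
    sample_rate: int = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate != SAMPLE_RATE_HZ:
            raise ValueError(f"sample rate must be {SAMPLE_RATE_HZ} Hz")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if np.any(np.abs(self.samples) > DEVICE_RANGE_G):
            raise ValueError(
                f"samples exceed the ±{DEVICE_RANGE_G:g} g device range"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class DecomposedSignal:
    """Noise-filtered signal split into static (≤0.5 Hz) and dynamic streams."""

    noise_filtered: np.ndarray
    static: np.ndarray
    dynamic: np.ndarray


@dataclass
class WindowFrame:
    """One 10-s window (600 samples) of static and dynamic triaxial data."""

    window_index: int
    participant_id: str
    activity_code: int
    minute_id: int
    static_samples: np.ndarray
    dynamic_samples: np.ndarray
    posture: str = "not_upright"

    def __post_init__(self) -> None:
        for name in ("static_samples", "dynamic_samples"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (WINDOW_SAMPLES, 3):
                raise ValueError(
                    f"{name} must have shape ({WINDOW_SAMPLES}, 3), got {arr.shape}"
                )
            setattr(self, name, arr)


def lowpass_filter(
    series: np.ndarray,
    cutoff_hz: float,
    sample_rate: float = SAMPLE_RATE_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    A Butterworth filter of the given ``order`` is designed and applied
    forward and backward (``filtfilt``), which cancels phase distortion
    and squares the magnitude response.  Works on 1-D series or on each
    column of a 2-D array.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff_hz < sample_rate / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={sample_rate / 2} Hz)"
        )
    b, a = butter(order, cutoff_hz, btype="low", fs=sample_rate)
    padlen = 3 * max(len(a), len(b))
    n = series.shape[0]
    if n <= padlen:
        raise ValueError(
            f"series of length {n} too short for edge padding ({padlen} samples)"
        )
    return filtfilt(b, a, series, axis=0, padlen=padlen)


def decompose(
    recording: RawRecording,
    noise_cutoff_hz: float = 20.0,
    static_cutoff_hz: float = 0.5,
    order: int = 4,
) -> DecomposedSignal:
    """Split a raw recording into static and dynamic acceleration streams.

    ``static + dynamic == noise_filtered`` holds exactly by construction.
    """
    noise_filtered = lowpass_filter(
        recording.samples, noise_cutoff_hz, recording.sample_rate, order
    )
    static = lowpass_filter(
        noise_filtered, static_cutoff_hz, recording.sample_rate, order
    )
    dynamic = noise_filtered - static
    return DecomposedSignal(noise_filtered=noise_filtered, static=static, dynamic=dynamic)


def segment_windows(
    decomposed: DecomposedSignal, recording: RawRecording
) -> list[WindowFrame]:
    """Cut the gas-sampling minutes into non-overlapping 10-s windows.

    Only intervals with ``gas_minute > 0`` are windowed; each such minute
    must contain at least 60 s of signal and yields ``floor(n/600)``
    windows (6 for an exact minute).  Windows are aligned to the first
    sample of the minute.
    """
    fs = recording.sample_rate
    windows: list[WindowFrame] = []
    index = 0
    for iv in recording.annotations:
        if iv.gas_minute <= 0:
            continue
        start = int(round(iv.start_s * fs))
        stop = int(round(iv.end_s * fs))
        stop = min(stop, recording.n_samples)
        n = stop - start
        if n < fs * 60:
            raise ValueError(
                f"activity {iv.activity_code} minute {iv.gas_minute}: "
                f"marked minute has {n} samples, need {fs * 60}"
            )
        n_windows = n // WINDOW_SAMPLES
        for w in range(n_windows):
            lo = start + w * WINDOW_SAMPLES
            hi = lo + WINDOW_SAMPLES
            windows.append(
                WindowFrame(
                    window_index=index,
                    participant_id=recording.participant_id,
                    activity_code=iv.activity_code,
                    minute_id=iv.gas_minute,
                    static_samples=decomposed.static[lo:hi],
                    dynamic_samples=decomposed.dynamic[lo:hi],
                    posture=iv.posture,
                )
            )
            index += 1
    return windows
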