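"""Low-pass filtering and speed-synchronized 256-sample windowing.

Raw IMU channels are noise-reduced with a fourth-order Butterworth low-pass
filter at 30 Hz, applied forward-backward (zero phase) so that window centers
stay aligned with speed timestamps.  The filtered streams are then cut into
overlapping 256-sample windows, one per 5 Hz speed sample: the window middle
is the IMU sample nearest the speed timestamp, so consecutive windows are 40
IMU samples (200/5) apart and share 216 samples.  Windows without full
support inside the recording, or straddling a gait-segment boundary, are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .simulate import CHANNELS, IMU_RATE_HZ, Recording

WINDOW_SIZE = 256
FILTER_ORDER = 4
CUTOFF_HZ = 30.0


def lowpass_filter(channel: np.ndarray, rate_hz: float = IMU_RATE_HZ,
                   cutoff_hz: float = CUTOFF_HZ, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length.

    Bidirectional application squares the magnitude response, so the
    effective attenuation at any frequency is the single-pass attenuation
    twice over.
    """
    x = np.asarray(channel, dtype=float)
    if cutoff_hz >= rate_hz / 2:
        raise ValueError("cutoff must be below Nyquist")
    b, a = butter(order, cutoff_hz, btype="low", fs=rate_hz)
    padlen = 3 * max(len(a), len(b))  # filtfilt default
    if x.size <= padlen:
        raise ValueError(f"series too short for filter warm-up ({x.size} <= {padlen})")
    return filtfilt(b, a, x)


@dataclass
class Window:
    """One 256-sample multi-channel slice centered on a speed sample.

    ``samples[(location, channel)]`` are views into the filtered streams.
    """

    samples: dict[tuple[str, str], np.ndarray]
    center_time: float
    target_speed: float
    gait: str
    subject_id: str
    breed: str

    def __post_init__(self) -> None:
        for key, arr in self.samples.items():
            if arr.shape[-1] != WINDOW_SIZE:
                raise ValueError(f"window {key} has length {arr.shape[-1]} != {WINDOW_SIZE}")

    @property
    def locations(self) -> set[str]:
        return {loc for loc, _ in self.samples}


def filter_recording(rec: Recording) -> dict[tuple[str, str], np.ndarray]:
    """Apply the low-pass filter to every channel of every location."""
    return {(loc, ch): lowpass_filter(rec.imu[loc][ch].to_numpy())
            for loc in rec.imu for ch in CHANNELS}


def extract_windows(rec: Recording, window_size: int = WINDOW_SIZE,
                    locations: tuple[str, ...] | None = None) -> list[Window]:
    """Cut one window per admissible speed sample from a recording.

    Filtering happens first on the full series (filter -> window order), so
    windowing commutes with it.  A speed sample is admissible when the
    window's full support lies inside the recording and inside a single gait
    segment.
    """
    if len(rec.speed) == 0:
        raise ValueError("empty speed series")
    locations = locations or tuple(rec.imu.keys())
    filtered = {(loc, ch): lowpass_filter(rec.imu[loc][ch].to_numpy())
                for loc in locations for ch in CHANNELS}

    t_imu = rec.imu[locations[0]]["t"].to_numpy()
    n = t_imu.size
    half = window_size // 2
    windows: list[Window] = []
    for t_c, v in zip(rec.speed["t"].to_numpy(), rec.speed["speed"].to_numpy()):
        center = int(np.argmin(np.abs(t_imu - t_c)))  # nearest IMU sample
        lo, hi = center - half, center + half
        if lo < 0 or hi > n:
            continue
        gait_lo = rec.gait_at(t_imu[lo])
        gait_hi = rec.gait_at(t_imu[hi - 1])
        if gait_lo is None or gait_lo != gait_hi:
            continue  # straddles a gait boundary
        samples = {key: arr[lo:hi] for key, arr in filtered.items()}
        windows.append(Window(samples=samples, center_time=float(t_c),
                              target_speed=float(v), gait=gait_lo,
                              subject_id=rec.subject_id, breed=rec.breed))
    return windows


def extract_cohort_windows(recs: list[Recording], **kwargs) -> list[Window]:
    out: list[Window] = []
    for rec in recs:
        out.extend(extract_windows(rec, **kwargs))
    return out
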