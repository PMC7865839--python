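"""Stride-frequency baseline: hoof-on detection and polynomial speed fits.

Hoof-on events of the right-front limb are detected as peaks of the
band-passed limb gyroscope z-channel (the axis carrying the reciprocating
limb rotation): local maxima separated by at least 0.25 s that exceed an
adaptive threshold, a fraction of the rolling signal amplitude.  Stride
frequency is the reciprocal of the inter-event interval, paired with the
speed sample nearest the stride midpoint.  Second- and third-degree
polynomials ``speed = P(stride frequency)`` are then fit by least squares
and scored in-sample (MAE, RMSE, R^2) — the simple baseline the full
feature-based pipeline is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, find_peaks

from .simulate import IMU_RATE_HZ, Recording

MIN_EVENT_SEPARATION_S = 0.25
BANDPASS_HZ = (0.5, 8.0)       # covers the plausible stride-frequency range
THRESHOLD_FRACTION = 0.8        # of the rolling amplitude envelope
ENVELOPE_WINDOW_S = 4.0


def detect_hoof_on(limb_channels: pd.DataFrame | np.ndarray,
                   rate_hz: float = IMU_RATE_HZ,
                   threshold_fraction: float = THRESHOLD_FRACTION) -> np.ndarray:
    """Detect hoof-on event times from a limb's gyroscope z channel.

    Accepts the limb's channel DataFrame (uses ``gyr_z`` and ``t``) or a bare
    gyr_z array (times then start at 0).  Returns event times in seconds;
    empty (with a warning) when nothing crosses the threshold.
    """
    if isinstance(limb_channels, pd.DataFrame):
        x = limb_channels["gyr_z"].to_numpy(dtype=float)
        t = limb_channels["t"].to_numpy(dtype=float)
    else:
        x = np.asarray(limb_channels, dtype=float)
        t = np.arange(x.size) / rate_hz
    if x.size < 2 * rate_hz:
        raise ValueError("need at least 2 s of limb signal")

    b, a = butter(2, BANDPASS_HZ, btype="band", fs=rate_hz)
    xf = filtfilt(b, a, x)

    # rolling amplitude envelope (max of |x| over the envelope window)
    w = int(ENVELOPE_WINDOW_S * rate_hz)
    absx = np.abs(xf)
    pad = w // 2
    padded = np.pad(absx, pad, mode="edge")
    env = np.array([padded[i:i + w].max() for i in range(absx.size)]) \
        if absx.size < 4 * w else _rolling_max(padded, w)[: absx.size]

    min_dist = int(MIN_EVENT_SEPARATION_S * rate_hz)
    peaks, _ = find_peaks(xf, distance=min_dist)
    peaks = peaks[xf[peaks] > threshold_fraction * env[peaks]]
    if peaks.size == 0:
        warnings.warn("no hoof-on events detected", stacklevel=2)
        return np.empty(0)
    return t[peaks]


def _rolling_max(x: np.ndarray, w: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view
    return sliding_window_view(x, w).max(axis=1)


@dataclass
class StrideSeries:
    """Per-stride frequency paired with the nearest-in-time speed sample."""
    hoof_on_times: np.ndarray       # s
    stride_frequency: np.ndarray    # Hz, one per inter-event interval
    paired_speed: np.ndarray        # m/s

    def __post_init__(self) -> None:
        if self.hoof_on_times.size and not np.all(np.diff(self.hoof_on_times) > 0):
            raise ValueError("hoof_on_times must be strictly increasing")
        if np.any(self.stride_frequency <= 0):
            raise ValueError("stride frequency must be positive")


def stride_series(rec: Recording, limb: str = "RF",
                  threshold_fraction: float = THRESHOLD_FRACTION) -> StrideSeries:
    """Detect strides on one limb and pair each with its nearest speed sample.

    Strides whose interval spans a gait-segment boundary are discarded (the
    interval is then not a single-gait stride).
    """
    events = detect_hoof_on(rec.imu[limb], threshold_fraction=threshold_fraction)
    if events.size < 2:
        return StrideSeries(events, np.empty(0), np.empty(0))
    t_speed = rec.speed["t"].to_numpy()
    v_speed = rec.speed["speed"].to_numpy()

    freqs, speeds, keep_times = [], [], []
    for t0, t1 in zip(events, events[1:]):
        g0, g1 = rec.gait_at(t0), rec.gait_at(t1)
        if g0 is None or g0 != g1:
            continue
        mid = 0.5 * (t0 + t1)
        i = int(np.argmin(np.abs(t_speed - mid)))
        freqs.append(1.0 / (t1 - t0))
        speeds.append(v_speed[i])
        keep_times.append(t0)
    return StrideSeries(np.asarray(keep_times), np.asarray(freqs), np.asarray(speeds))


def cohort_stride_series(recs: list[Recording], **kwargs) -> StrideSeries:
    parts = [stride_series(r, **kwargs) for r in recs]
    times = np.concatenate([p.hoof_on_times for p in parts]) if parts else np.empty(0)
    # times from different subjects overlap; keep per-subject ordering only
    freqs = np.concatenate([p.stride_frequency for p in parts])
    speeds = np.concatenate([p.paired_speed for p in parts])
    out = StrideSeries.__new__(StrideSeries)
    out.hoof_on_times = times
    out.stride_frequency = freqs
    out.paired_speed = speeds
    return out


@dataclass
class PolyFitResult:
    degree: int
    coefficients: np.ndarray  # highest power first (numpy convention)
    mae: float                # m/s
    rmse: float               # m/s
    r2: float

    def __post_init__(self) -> None:
        if self.degree not in (2, 3):
            raise ValueError("degree must be 2 or 3")

    def to_dict(self) -> dict:
        return {"degree": self.degree,
                "coefficients": list(self.coefficients),
                "mae": self.mae, "rmse": self.rmse, "r2": self.r2}


def fit_poly_speed(stride: StrideSeries, degree: int = 2) -> PolyFitResult:
    """Least-squares polynomial speed = P(stride frequency), scored in-sample."""
    if degree not in (2, 3):
        raise ValueError("degree must be 2 or 3")
    f = np.asarray(stride.stride_frequency, dtype=float)
    v = np.asarray(stride.paired_speed, dtype=float)
    if f.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} stride points")
    if np.ptp(f) == 0:
        raise ValueError("degenerate design: constant stride frequency")
    coeffs = np.polyfit(f, v, degree)
    pred = np.polyval(coeffs, f)
    resid = v - pred
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    return PolyFitResult(
        degree=degree,
        coefficients=coeffs,
        mae=float(np.mean(np.abs(resid))),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )
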