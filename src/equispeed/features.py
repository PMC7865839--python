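"""Per-window time- and frequency-domain features and feature-set assembly.

Each 256-sample channel window yields 23 features: nine time-domain
statistics computed on the (filtered, unwindowed) samples, and fourteen
frequency-domain quantities computed after applying a Hann taper.  With six
channels per IMU that is 23 x 6 = 138 features per sensor location; the
eleven named feature sets combine locations (All = 7 locations = 966
columns, Limbs = 4 = 552, two pairs, and the seven singletons).

Conventions (pinned by the Parseval and brute-force DFT oracle tests):

* sd uses the 1/(N-1) denominator; skewness and kurtosis use 1/N with the
  population sigma, kurtosis raw (Gaussian -> 3), not excess.
* percentiles (p25/p75) use linear interpolation between order statistics.
* DFT is the plain ``X_k = sum_n x_n exp(-j 2 pi k n / N)`` of the
  Hann-windowed samples; spectral energy sums |X_k|^2 over all N bins;
  spectral entropy is the Shannon entropy (natural log) of the normalized
  one-sided power distribution (bins 0..N/2).
* the "first six Fourier coefficients" are k = 1..6 (DC excluded); the phase
  angle is the two-argument arctangent of (sum x sin, sum x cos), i.e.
  atan2(-Im X_k, Re X_k).

Windows with zero variance (time) or an all-zero windowed spectrum
(frequency) are flagged degenerate and the affected features set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .preprocess import WINDOW_SIZE, Window
from .simulate import CHANNELS, LIMBS, LOCATIONS

TIME_FEATURE_NAMES = ("max", "min", "mean", "mdn", "sd", "p25", "p75", "krt", "skw")
FREQ_FEATURE_NAMES = ("ent", "enrg",
                      "fft1", "fft2", "fft3", "fft4", "fft5", "fft6",
                      "ang1", "ang2", "ang3", "ang4", "ang5", "ang6")
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES  # 23
N_FEATURES_PER_LOCATION = len(FEATURE_NAMES) * len(CHANNELS)  # 138

#: compact channel tag used in column names, e.g. ``max_gyrz(LH)``
CHANNEL_TAG = {c: c.replace("_", "") for c in CHANNELS}

METADATA_COLUMNS = ("window_id", "subject", "breed", "gait", "speed")


@dataclass(frozen=True)
class FeatureSetDef:
    """A named combination of sensor locations."""
    name: str
    locations: tuple[str, ...]


FEATURE_SETS: dict[str, FeatureSetDef] = {
    "All": FeatureSetDef("All", LOCATIONS),
    "Limbs": FeatureSetDef("Limbs", LIMBS),
    "Sac/Wth": FeatureSetDef("Sac/Wth", ("sacrum", "withers")),
    "Sac/RF": FeatureSetDef("Sac/RF", ("sacrum", "RF")),
    "Sacrum": FeatureSetDef("Sacrum", ("sacrum",)),
    "Withers": FeatureSetDef("Withers", ("withers",)),
    "Poll": FeatureSetDef("Poll", ("poll",)),
    "RF": FeatureSetDef("RF", ("RF",)),
    "LF": FeatureSetDef("LF", ("LF",)),
    "RH": FeatureSetDef("RH", ("RH",)),
    "LH": FeatureSetDef("LH", ("LH",)),
}


def feature_column(feature: str, channel: str, location: str) -> str:
    return f"{feature}_{CHANNEL_TAG[channel]}({location})"


def time_features(x: np.ndarray) -> dict[str, float]:
    """Nine time-domain statistics of one channel window.

    Accepts any length >= 2 (unit tests exercise short vectors); production
    windows have N = 256.  Zero-variance input yields skw = krt = 0 and is
    reported degenerate via :func:`is_degenerate_time`.
    """
    vals, _ = _time_features_block(np.asarray(x, dtype=float)[None, :])
    return {name: float(vals[0, i]) for i, name in enumerate(TIME_FEATURE_NAMES)}


def _time_features_block(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized time features; X is (n_windows, N). Returns (values, degenerate)."""
    n = X.shape[1]
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    sigma_pop = X.std(axis=1, ddof=0)
    degenerate = sigma_pop == 0.0
    centered = X - mean[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = centered / np.where(sigma_pop == 0.0, 1.0, sigma_pop)[:, None]
    krt = np.where(degenerate, 0.0, np.mean(z ** 4, axis=1))
    skw = np.where(degenerate, 0.0, np.mean(z ** 3, axis=1))
    p25, mdn, p75 = np.percentile(X, [25, 50, 75], axis=1)
    out = np.column_stack([X.max(axis=1), X.min(axis=1), mean, mdn, sd,
                           p25, p75, krt, skw])
    return out, degenerate


def is_degenerate_time(x: np.ndarray) -> bool:
    return bool(np.std(np.asarray(x, dtype=float)) == 0.0)


def freq_features(x: np.ndarray) -> dict[str, float]:
    """Fourteen frequency-domain features of one channel window (N = 256)."""
    x = np.asarray(x, dtype=float)
    if x.size != WINDOW_SIZE:
        raise ValueError(f"frequency features require N = {WINDOW_SIZE}, got {x.size}")
    vals, _ = _freq_features_block(x[None, :])
    return {name: float(vals[0, i]) for i, name in enumerate(FREQ_FEATURE_NAMES)}


def _freq_features_block(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized frequency features; X is (n_windows, 256)."""
    n = X.shape[1]
    w = hann(n, sym=True)
    Xw = X * w[None, :]
    F = np.fft.fft(Xw, axis=1)
    power = np.abs(F) ** 2
    energy = power.sum(axis=1)

    one_sided = power[:, : n // 2 + 1]
    total = one_sided.sum(axis=1)
    degenerate = total == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = one_sided / np.where(degenerate, 1.0, total)[:, None]
        logp = np.where(p > 0.0, np.log(np.where(p > 0.0, p, 1.0)), 0.0)
    ent = np.where(degenerate, 0.0, -(p * logp).sum(axis=1))

    mags = np.abs(F[:, 1:7])
    # phase per the sin/cos form: atan2(sum x sin, sum x cos) = atan2(-Im, Re)
    angs = np.arctan2(-F[:, 1:7].imag, F[:, 1:7].real)
    out = np.column_stack([ent, energy, mags, angs])
    return out, degenerate


def spectral_entropy_of_power(p: np.ndarray) -> float:
    """Entropy of an explicit (already one-sided) power distribution; helper
    for degenerate/single-bin unit checks."""
    p = np.asarray(p, dtype=float)
    tot = p.sum()
    if tot == 0.0:
        return 0.0
    q = p / tot
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def hann_window(n: int = WINDOW_SIZE) -> np.ndarray:
    return hann(n, sym=True)


def window_features(window: Window, locations: tuple[str, ...]) -> dict[str, float]:
    """All 138 x |locations| features of one window (non-vectorized path)."""
    out: dict[str, float] = {}
    for loc in locations:
        for ch in CHANNELS:
            x = window.samples[(loc, ch)]
            tf = time_features(x)
            ff = freq_features(x)
            for name, val in {**tf, **ff}.items():
                out[feature_column(name, ch, loc)] = val
    return out


def build_feature_matrix(windows: list[Window],
                         feature_set: FeatureSetDef | str) -> pd.DataFrame:
    """Assemble the feature matrix for one feature set.

    Rows follow window order; the first columns are metadata
    (window_id, subject, breed, gait, speed), then 138 columns per location
    named ``<feature>_<channel>(<location>)``.
    """
    if isinstance(feature_set, str):
        feature_set = FEATURE_SETS[feature_set]
    if not windows:
        raise ValueError("no windows given")
    for loc in feature_set.locations:
        if not all((loc, ch) in w.samples for w in windows[:1] for ch in CHANNELS):
            raise ValueError(f"missing location stream: {loc}")

    meta = pd.DataFrame({
        "window_id": np.arange(len(windows)),
        "subject": [w.subject_id for w in windows],
        "breed": [w.breed for w in windows],
        "gait": [w.gait for w in windows],
        "speed": [w.target_speed for w in windows],
    })

    blocks = [meta]
    for loc in feature_set.locations:
        for ch in CHANNELS:
            X = np.stack([w.samples[(loc, ch)] for w in windows])
            tvals, _ = _time_features_block(X)
            fvals, _ = _freq_features_block(X)
            cols = ([feature_column(n, ch, loc) for n in TIME_FEATURE_NAMES]
                    + [feature_column(n, ch, loc) for n in FREQ_FEATURE_NAMES])
            blocks.append(pd.DataFrame(np.hstack([tvals, fvals]), columns=cols))
    return pd.concat(blocks, axis=1)


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Feature (non-metadata) column names of a feature matrix."""
    return [c for c in matrix.columns if c not in METADATA_COLUMNS]
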