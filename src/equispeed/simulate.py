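"""Synthetic multi-IMU horse gait recordings with known ground-truth speed.

The generator emulates the measurement setup of a body-mounted sensor study:
seven inertial measurement units (poll, withers, sacrum and the four cannon
bones), each streaming a tri-axial accelerometer (m/s^2) and tri-axial
gyroscope (deg/s) at 200 Hz, alongside a Doppler-GPS-style ground-truth speed
series at 5 Hz.  Five gaits are covered (walk, trot, toelt, pace, canter),
each with its own speed distribution and a stride frequency that increases
linearly with speed.

Signal model, per channel::

    x(t) = sum_{h=1..3} A_h * (1 + c * v(t)) * cos(h * theta(t) + psi_h) + noise

where ``theta(t) = 2*pi * integral of f(v)`` accumulates phase at the
instantaneous stride frequency ``f(v) = a_g + b_g * v``, the harmonic shape
coefficients ``(A_h, psi_h)`` depend on sensor location, channel and gait, and
the multiplicative term ``1 + c*v`` couples signal energy to speed.  Speed
itself follows a mean-reverting (Ornstein-Uhlenbeck) walk sampled at 5 Hz and
held piecewise constant at 200 Hz.  Per-subject amplitude factors and phase
offsets, drawn once per subject, create the between-individual variability
that leave-one-subject-out evaluation must generalize across.

Limb sensors carry their largest fundamental on the z-axis of angular
velocity (reciprocating limb rotation); upper-body sensors carry theirs on
vertical acceleration.  The poll is given a deliberately weak speed coupling
and low signal-to-noise ratio, reflecting its distance from the limbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

IMU_RATE_HZ = 200.0
SPEED_RATE_HZ = 5.0
SAMPLES_PER_SPEED = int(IMU_RATE_HZ / SPEED_RATE_HZ)  # 40

LOCATIONS = ("poll", "withers", "sacrum", "RF", "LF", "RH", "LH")
LIMBS = ("RF", "LF", "RH", "LH")
UPPER_BODY = ("poll", "withers", "sacrum")
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")
ACC_CHANNELS = CHANNELS[:3]
GYR_CHANNELS = CHANNELS[3:]
GAITS = ("walk", "trot", "tölt", "pace", "canter")

#: channel units recorded in file headers
CHANNEL_UNITS = {c: ("m/s^2" if c.startswith("acc") else "deg/s") for c in CHANNELS}


@dataclass(frozen=True)
class GaitParams:
    """Per-gait generative parameters.

    ``speed_mean``/``speed_sd`` (m/s) set the stationary speed distribution;
    ``stride_intercept``/``stride_slope`` give stride frequency
    ``f(v) = a + b*v`` in Hz with ``b > 0`` so that stride frequency rises
    with speed; ``speed_coupling`` is the ``c`` of the amplitude term
    ``1 + c*v``; ``noise_sd`` holds additive Gaussian noise SD per channel
    family; ``subject_sd`` is the relative SD of the per-subject amplitude
    factor.
    """

    gait: str
    speed_mean: float
    speed_sd: float
    stride_intercept: float  # a_g, Hz
    stride_slope: float      # b_g, Hz per (m/s)
    speed_coupling: float = 0.15
    noise_sd_acc: float = 0.3    # m/s^2
    noise_sd_gyr: float = 1.5    # deg/s
    subject_sd: float = 0.10
    #: optional override: (location, channel) -> (A1, A2, A3); falls back to
    #: the built-in per-location-class amplitude tables
    harmonic_amplitudes: dict | None = None

    def __post_init__(self) -> None:
        if self.gait not in GAITS:
            raise ValueError(f"unknown gait label: {self.gait!r}")
        if self.speed_sd <= 0:
            raise ValueError("speed_sd must be > 0")
        if self.stride_slope <= 0:
            raise ValueError("stride_slope must be > 0 (stride frequency increases with speed)")

    def stride_frequency(self, speed: np.ndarray | float) -> np.ndarray | float:
        return self.stride_intercept + self.stride_slope * np.asarray(speed, dtype=float)


def default_gait_params() -> dict[str, GaitParams]:
    """Default per-gait parameters.

    Speed means and SDs follow the measured per-gait distributions of the
    study population (walk 1.70+-0.17 ... pace 7.52+-1.43 m/s).  Stride
    coefficients are simulator choices spanning roughly 0.8-2.2 Hz over that
    speed range, a plausible equine range.  The poll gets a weaker speed
    coupling (its motion is furthest removed from limb kinematics).
    """
    table = {
        # gait: (speed_mean, speed_sd, a_g, b_g)
        "walk":   (1.70, 0.17, 0.55, 0.15),
        "trot":   (3.30, 0.23, 0.80, 0.18),
        "tölt":   (3.90, 0.23, 0.85, 0.19),
        "canter": (4.95, 0.43, 0.90, 0.18),
        "pace":   (7.52, 1.43, 1.00, 0.15),
    }
    return {
        g: GaitParams(gait=g, speed_mean=m, speed_sd=s, stride_intercept=a, stride_slope=b)
        for g, (m, s, a, b) in table.items()
    }


# Harmonic amplitude templates: (A1, A2, A3) per location class and channel.
# Limb gyr_z dominates the limb channels (reciprocating protraction/
# retraction); upper-body acc_z dominates the upper-body channels (vertical
# oscillation at stride frequency).  Poll amplitudes are small relative to its
# noise floor, giving it the weakest usable speed information.
_LIMB_AMPLITUDES = {
    "acc_x": (8.0, 3.0, 1.0),
    "acc_y": (5.0, 2.0, 0.8),
    "acc_z": (6.0, 2.5, 1.0),
    "gyr_x": (30.0, 10.0, 4.0),
    "gyr_y": (25.0, 8.0, 3.0),
    "gyr_z": (120.0, 40.0, 15.0),
}
_TRUNK_AMPLITUDES = {
    "acc_x": (2.5, 1.0, 0.3),
    "acc_y": (1.5, 0.6, 0.2),
    "acc_z": (4.0, 1.5, 0.5),
    "gyr_x": (12.0, 4.0, 1.5),
    "gyr_y": (15.0, 5.0, 2.0),
    "gyr_z": (10.0, 3.5, 1.2),
}
_POLL_AMPLITUDES = {
    "acc_x": (0.20, 0.08, 0.03),
    "acc_y": (0.15, 0.06, 0.02),
    "acc_z": (0.40, 0.15, 0.05),
    "gyr_x": (1.5, 0.5, 0.2),
    "gyr_y": (2.0, 0.8, 0.3),
    "gyr_z": (1.8, 0.6, 0.2),
}

# Channel informativeness profile.  The primary oscillation channel of each
# sensor (limb gyr_z: protraction/retraction; upper-body acc_z: vertical
# displacement) scales directly with stride kinematics, so it gets the full
# speed coupling and low between-subject amplitude variability.  Secondary
# channels reflect conformation and individual movement style more than
# speed: weaker coupling, larger subject-to-subject variability.  The poll,
# furthest from the limbs, is idiosyncratic on every channel.
_PRIMARY_CHANNEL = {**{limb: "gyr_z" for limb in LIMBS},
                    **{loc: "acc_z" for loc in UPPER_BODY}}
_SECONDARY_COUPLING_FACTOR = 0.3
_PRIMARY_SUBJECT_SD_FACTOR = 0.5
_SECONDARY_SUBJECT_SD_FACTOR = 2.5
_POLL_SUBJECT_SD_FACTOR = 3.0

# Fixed per-harmonic shape phases (radians); shared so the waveform shape is a
# stable property of a channel, while the per-subject offset shifts it in time.
_HARMONIC_SHAPE_PHASE = (0.0, 0.35, 0.9)

# Per-gait amplitude scale: modest, so the speed-coupling term (not gait
# identity) carries most of the within-channel energy gradient.
_GAIT_AMPLITUDE_SCALE = {"walk": 0.9, "trot": 1.0, "tölt": 1.0, "pace": 1.1, "canter": 1.05}

# Base phase lag per limb approximating footfall sequencing (radians).
_LOCATION_PHASE = {
    "poll": 0.0, "withers": 0.3, "sacrum": 0.6,
    "RF": 0.0, "LF": np.pi, "RH": np.pi / 2, "LH": 3 * np.pi / 2,
}

#: default poll speed-coupling override (weak coupling)
POLL_SPEED_COUPLING = 0.05


def harmonic_amplitudes(location: str, channel: str, gait: str,
                        params: "GaitParams | None" = None) -> np.ndarray:
    """Amplitudes of harmonics 1-3 for one (location, channel, gait)."""
    if params is not None and params.harmonic_amplitudes is not None:
        override = params.harmonic_amplitudes.get((location, channel))
        if override is not None:
            amps = np.asarray(override, dtype=float)
            if np.any(amps < 0):
                raise ValueError("harmonic amplitudes must be >= 0")
            return amps
    if location in LIMBS:
        base = _LIMB_AMPLITUDES[channel]
    elif location == "poll":
        base = _POLL_AMPLITUDES[channel]
    else:
        base = _TRUNK_AMPLITUDES[channel]
    return np.asarray(base, dtype=float) * _GAIT_AMPLITUDE_SCALE[gait]


@dataclass(frozen=True)
class GaitSegment:
    start: float  # s
    end: float    # s
    gait: str

    def __post_init__(self) -> None:
        if self.gait not in GAITS:
            raise ValueError(f"unknown gait label: {self.gait!r}")
        if self.end - self.start <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class Recording:
    """One subject's synchronized IMU streams, speed series and gait labels.

    ``imu[location]`` is a DataFrame with columns ``t, acc_x..gyr_z`` at
    200 Hz; ``speed`` has columns ``t, speed`` at 5 Hz; ``gait_segments`` are
    non-overlapping and cover the speed samples.
    """

    subject_id: str
    breed: str
    imu: dict[str, pd.DataFrame]
    speed: pd.DataFrame
    gait_segments: list[GaitSegment]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.imu.values())))

    def gait_at(self, t: float) -> str | None:
        for seg in self.gait_segments:
            if seg.start <= t < seg.end:
                return seg.gait
        return None

    def validate(self) -> None:
        lengths = {loc: len(df) for loc, df in self.imu.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"IMU stream lengths differ: {lengths}")
        for loc, df in self.imu.items():
            if not np.all(np.diff(df["t"].to_numpy()) > 0):
                raise ValueError(f"non-increasing timestamps in {loc}")
        if (self.speed["speed"] < 0).any():
            raise ValueError("negative speed")
        segs = sorted(self.gait_segments, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError("overlapping gait segments")


def _ou_speed(rng: np.random.Generator, n: int, mean: float, sd: float,
              dt: float, theta: float = 0.5) -> np.ndarray:
    """Mean-reverting speed path at the speed rate; clipped to stay >= 0."""
    v = np.empty(n)
    v[0] = rng.normal(mean, sd)
    sigma = sd * np.sqrt(2.0 * theta)
    noise = rng.normal(0.0, 1.0, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        v[i] = v[i - 1] + theta * (mean - v[i - 1]) * dt + sigma * np.sqrt(dt) * noise[i - 1]
    return np.clip(v, 0.05, None)


@dataclass
class _SubjectTraits:
    """Per-subject random effects drawn once per subject."""
    amp_factor: dict[tuple[str, str], float]   # (location, channel) -> factor
    phase_offset: dict[str, float]             # location -> radians


def _subject_sd_factor(loc: str, ch: str) -> float:
    if loc == "poll":
        return _POLL_SUBJECT_SD_FACTOR
    if ch == _PRIMARY_CHANNEL[loc]:
        return _PRIMARY_SUBJECT_SD_FACTOR
    return _SECONDARY_SUBJECT_SD_FACTOR


def _coupling_for(loc: str, ch: str, c: float) -> float:
    if loc == "poll":
        return POLL_SPEED_COUPLING
    if ch == _PRIMARY_CHANNEL[loc]:
        return c
    return c * _SECONDARY_COUPLING_FACTOR


def _draw_subject_traits(rng: np.random.Generator, subject_sd: float) -> _SubjectTraits:
    amp = {(loc, ch): max(0.1, 1.0 + rng.normal(0.0, subject_sd * _subject_sd_factor(loc, ch)))
           for loc in LOCATIONS for ch in CHANNELS}
    phase = {loc: rng.uniform(0.0, 2.0 * np.pi) for loc in LOCATIONS}
    return _SubjectTraits(amp_factor=amp, phase_offset=phase)


def simulate_recording(
    params: dict[str, GaitParams],
    schedule: list[GaitSegment] | list[tuple[float, float, str]],
    subject_id: str = "S00",
    seed: int | np.random.Generator = 0,
    breed: str = "Icelandic",
    traits: _SubjectTraits | None = None,
) -> Recording:
    """Synthesize one subject's recording for a schedule of gait segments.

    Parameters
    ----------
    params
        Mapping gait -> :class:`GaitParams`; see :func:`default_gait_params`.
    schedule
        Ordered, non-overlapping gait segments; each must last more than 2 s.
    seed
        Integer seed or a Generator; fixed seed gives bit-identical output.
    traits
        Per-subject random effects; drawn from ``seed`` if not given (cohort
        simulation draws them once per subject).
    """
    segments = [s if isinstance(s, GaitSegment) else GaitSegment(*s) for s in schedule]
    if not segments:
        raise ValueError("empty schedule")
    for seg in segments:
        if seg.gait not in params:
            raise ValueError(f"no GaitParams for gait {seg.gait!r}")
        if seg.end - seg.start <= 2.0:
            raise ValueError(f"segment duration must exceed 2 s, got {seg.end - seg.start}")
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValueError("overlapping gait segments")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if traits is None:
        traits = _draw_subject_traits(rng, next(iter(params.values())).subject_sd)

    dt_speed = 1.0 / SPEED_RATE_HZ
    dt_imu = 1.0 / IMU_RATE_HZ

    speed_t: list[np.ndarray] = []
    speed_v: list[np.ndarray] = []
    imu_t: list[np.ndarray] = []
    channels: dict[tuple[str, str], list[np.ndarray]] = {
        (loc, ch): [] for loc in LOCATIONS for ch in CHANNELS}

    for seg in segs:
        gp = params[seg.gait]
        n_speed = int(round((seg.end - seg.start) * SPEED_RATE_HZ))
        t5 = seg.start + np.arange(n_speed) * dt_speed
        v5 = _ou_speed(rng, n_speed, gp.speed_mean, gp.speed_sd, dt_speed)

        # hold speed piecewise-constant at the IMU rate
        v200 = np.repeat(v5, SAMPLES_PER_SPEED)
        n_imu = v200.size
        t200 = seg.start + np.arange(n_imu) * dt_imu

        # accumulated phase at the instantaneous stride frequency
        f200 = gp.stride_frequency(v200)
        theta = 2.0 * np.pi * np.cumsum(f200) * dt_imu

        # per-segment random phase start keeps segments independent
        seg_phase = rng.uniform(0.0, 2.0 * np.pi)

        # noise drawn in a fixed channel order for reproducibility
        for loc in LOCATIONS:
            base_phase = seg_phase + _LOCATION_PHASE[loc] + traits.phase_offset[loc]
            for ch in CHANNELS:
                c = _coupling_for(loc, ch, gp.speed_coupling)
                coupling = 1.0 + c * v200
                amps = harmonic_amplitudes(loc, ch, seg.gait, gp) * traits.amp_factor[(loc, ch)]
                sig = np.zeros(n_imu)
                for h, (A, psi) in enumerate(zip(amps, _HARMONIC_SHAPE_PHASE), start=1):
                    if A > 0:
                        sig += A * np.cos(h * (theta + base_phase) + psi)
                sig *= coupling
                nsd = gp.noise_sd_acc if ch.startswith("acc") else gp.noise_sd_gyr
                if nsd > 0:
                    sig += rng.normal(0.0, nsd, size=n_imu)
                channels[(loc, ch)].append(sig)

        speed_t.append(t5)
        speed_v.append(v5)
        imu_t.append(t200)

    t200_all = np.concatenate(imu_t)
    imu = {}
    for loc in LOCATIONS:
        cols = {"t": t200_all}
        cols.update({ch: np.concatenate(channels[(loc, ch)]) for ch in CHANNELS})
        imu[loc] = pd.DataFrame(cols)
    speed = pd.DataFrame({"t": np.concatenate(speed_t), "speed": np.concatenate(speed_v)})

    rec = Recording(subject_id=subject_id, breed=breed, imu=imu, speed=speed,
                    gait_segments=segs)
    rec.validate()
    return rec


def default_schedule(seconds_per_gait: float = 21.0,
                     gaits: tuple[str, ...] = GAITS) -> list[GaitSegment]:
    """One segment per gait, back to back."""
    out, t = [], 0.0
    for g in gaits:
        out.append(GaitSegment(t, t + seconds_per_gait, g))
        t += seconds_per_gait
    return out


def simulate_cohort(
    n_subjects: int,
    breed_mix: dict[str, int] | None = None,
    schedule_template: list[GaitSegment] | None = None,
    seed: int = 0,
    params: dict[str, GaitParams] | None = None,
) -> list[Recording]:
    """Simulate a cohort; per-subject seeds spawn deterministically from ``seed``.

    ``breed_mix`` maps breed name -> subject count (defaults to an
    Icelandic/Franches-Montagnes split in 15:25 proportion).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (leave-one-subject-out undefined otherwise)")
    params = params or default_gait_params()
    schedule = schedule_template or default_schedule()
    if breed_mix is None:
        n_ice = max(1, round(n_subjects * 15 / 40))
        breed_mix = {"Icelandic": n_ice, "Franches-Montagnes": n_subjects - n_ice}
    if sum(breed_mix.values()) != n_subjects:
        raise ValueError("breed_mix counts must sum to n_subjects")

    breeds = [b for b, k in breed_mix.items() for _ in range(k)]
    ss = np.random.SeedSequence(seed)
    recs = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        subj = f"S{i:02d}"
        recs.append(simulate_recording(params, schedule, subject_id=subj,
                                       seed=rng, breed=breeds[i]))
    return recs


# ---------------------------------------------------------------------------
# on-disk format: one CSV per location, one speed CSV, one JSON sidecar
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, out_dir: str | Path) -> Path:
    out = Path(out_dir) / rec.subject_id
    out.mkdir(parents=True, exist_ok=True)
    for loc, df in rec.imu.items():
        path = out / f"imu_{loc}.csv"
        with open(path, "w") as fh:
            fh.write(f"# location={loc} rate_hz={IMU_RATE_HZ:g} "
                     f"units=t:s,acc:m/s^2,gyr:deg/s\n")
            df.to_csv(fh, index=False, float_format="%.6f")
    with open(out / "speed.csv", "w") as fh:
        fh.write(f"# rate_hz={SPEED_RATE_HZ:g} units=t:s,speed:m/s\n")
        rec.speed.to_csv(fh, index=False, float_format="%.6f")
    meta = {
        "subject_id": rec.subject_id,
        "breed": rec.breed,
        "gait_segments": [{"start": s.start, "end": s.end, "gait": s.gait}
                          for s in rec.gait_segments],
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, ensure_ascii=False))
    return out


def read_recording(subject_dir: str | Path) -> Recording:
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "meta.json").read_text())
    imu = {loc: pd.read_csv(subject_dir / f"imu_{loc}.csv", comment="#")
           for loc in LOCATIONS}
    speed = pd.read_csv(subject_dir / "speed.csv", comment="#")
    segs = [GaitSegment(s["start"], s["end"], s["gait"]) for s in meta["gait_segments"]]
    rec = Recording(subject_id=meta["subject_id"], breed=meta["breed"],
                    imu=imu, speed=speed, gait_segments=segs)
    rec.validate()
    return rec


def write_cohort(recs: list[Recording], out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recs:
        write_recording(rec, out)
    (out / "cohort.json").write_text(json.dumps(
        {"subjects": [r.subject_id for r in recs]}, indent=2))
    return out


def read_cohort(cohort_dir: str | Path) -> list[Recording]:
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "cohort.json").read_text())
    return [read_recording(cohort_dir / s) for s in manifest["subjects"]]
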