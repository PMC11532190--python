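"""Synthetic protocol cohort: the study conditions in silico.

Generates complete synthetic subjects undergoing a three-activity laboratory
protocol — isometric handgrip (2 min at 30% MVC, three repetitions with
2-min pauses), serial-subtraction mental stress (5 min) and a cold pressor
test (2 min) — each preceded by a 4-min rest and followed by 1 min of
recovery. A configurable subset of subjects repeats the handgrip session on
a second day, exercising the Stability analysis.

Per subject the generator emits, per session:

* a true per-beat SBP/DBP/MAP/HR series (activity responses as smooth
  onset/offset ramps on top of a personal baseline, plus AR(1) beat noise),
* a continuous pressure waveform built from a parametric pulse template,
  with R-peak times,
* three brachial cuff readings from the pre-activity rest,
* a per-15-s-segment PPG-like feature stream that is a linear function of
  the (device-side) segment-mean BP/HR, and the device-side error draws
  that perturbed it.

Physiology emulated (and its limits) is documented in the package's methods
note: handgrip raises SBP and DBP together; mental stress predominantly
raises SBP and HR with a smaller DBP rise; the cold pressor evokes a rapid
SBP surge. Response amplitudes are drawn per subject from lognormal
distributions calibrated so the cohort's within-subject segment-range
changes land near published laboratory values for these stressors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .beats import BP_PARAMS, BeatSeries, WaveformRecord, aggregate_segments
from .calibration import BrachialTriplet

__all__ = [
    "SessionSpec",
    "ProtocolSpec",
    "SubjectParams",
    "DeviceErrorModel",
    "SessionData",
    "SimulatedSubject",
    "default_protocol",
    "simulate_bp_trajectory",
    "simulate_session_trajectory",
    "simulate_waveform",
    "simulate_brachial_readings",
    "simulate_ppg_features",
    "simulate_cohort",
    "inject_artifacts",
    "pulse_template",
    "MAP_FRACTION",
    "DEFAULT_FEATURE_COEFFS",
    "DEFAULT_FEATURE_INTERCEPTS",
    "DEFAULT_FEATURE_NOISE_SD",
    "FEATURE_NAMES",
    "ACTIVITIES",
]

ACTIVITIES = ("handgrip", "mental_stress", "cold_pressor")

# ---------------------------------------------------------------------------
# protocol

@dataclass(frozen=True)
class SessionSpec:
    """One recorded activity session: rest, repeated activity bouts, recovery."""

    activity: str
    duration_s: float          # one activity bout
    reps: int = 1
    pause_s: float = 0.0       # between repetitions
    rest_s: float = 240.0      # pre-activity rest
    recovery_s: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rest_s < 0 or self.recovery_s < 0:
            raise ValueError("session durations must be positive")
        if self.reps < 1 or (self.reps > 1 and self.pause_s <= 0):
            raise ValueError("invalid repetition structure")

    @property
    def total_duration(self) -> float:
        return (
            self.rest_s
            + self.reps * self.duration_s
            + (self.reps - 1) * self.pause_s
            + self.recovery_s
        )

    def active_intervals(self) -> list[tuple[float, float]]:
        out = []
        t = self.rest_s
        for _ in range(self.reps):
            out.append((t, t + self.duration_s))
            t += self.duration_s + self.pause_s
        return out


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered list of activity sessions for one laboratory day."""

    sessions: tuple[SessionSpec, ...]

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("protocol needs at least one session")


def default_protocol() -> ProtocolSpec:
    """The day-1 protocol: handgrip x3, mental stress, cold pressor."""
    return ProtocolSpec(
        sessions=(
            SessionSpec("handgrip", 120.0, reps=3, pause_s=120.0),
            SessionSpec("mental_stress", 300.0),
            SessionSpec("cold_pressor", 120.0),
        )
    )


# ---------------------------------------------------------------------------
# subject parameters

# onset/offset ramp of the pressor response, seconds; the cold pressor's
# sympathetic surge is modelled with a faster onset
RAMP_S = {"handgrip": 20.0, "mental_stress": 20.0, "cold_pressor": 10.0}

# cohort parameter distributions (documented in the methods note):
# baselines mean (SD); response-amplitude lognormal medians per activity,
# (dSBP, dDBP, dHR), with log-SD AMP_SIGMA shared
BASELINE_SBP = (119.3, 9.4)
BASELINE_DBP = (72.6, 7.1)
BASELINE_HR = (65.0, 8.0)
AMP_MEDIANS = {
    "handgrip": (21.0, 14.0, 13.0),
    "mental_stress": (18.0, 10.0, 19.0),
    "cold_pressor": (31.0, 18.0, 11.0),
}
AMP_SIGMA = 0.55
SESSION_OFFSET_SD = 3.0     # between-session baseline wander, mmHg
BEAT_NOISE_SD = 3.0         # AR(1) stationary SD of SBP beat noise, mmHg
AR1_COEFF = 0.7
DBP_NOISE_SCALE = 0.7       # DBP beat noise relative to SBP's
HR_NOISE_SD = 1.5           # slow HR wander SD, beats/min
BRACHIAL_NOISE_SD = 1.5     # per cuff reading, mmHg


@dataclass
class SubjectParams:
    """Per-subject physiology and noise configuration (seeded)."""

    subject_id: str
    sbp0: float
    dbp0: float
    hr0: float
    # activity -> (dSBP, dDBP, dHR) plateau amplitudes, mmHg / bpm
    amplitudes: dict[str, tuple[float, float, float]]
    noise_sd: float = BEAT_NOISE_SD
    hr_noise_sd: float = HR_NOISE_SD
    # (activity, day) -> additive whole-BP session baseline offset, mmHg
    session_offsets: dict[tuple[str, int], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dbp0 < self.sbp0:
            raise ValueError("baseline DBP must be below baseline SBP")
        for a, amps in self.amplitudes.items():
            if any(x < 0 for x in amps):
                raise ValueError(f"negative response amplitude for {a}")
        if self.noise_sd < 0 or self.hr_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


# ---------------------------------------------------------------------------
# pulse template

UPSTROKE_FRACTION = 0.3   # systolic upstroke occupies this fraction of the cycle
DECAY_RATE = 3.0          # exponential decay constant over the remaining cycle


def pulse_template(u: np.ndarray) -> np.ndarray:
    """Normalized pulse shape on cycle phase ``u in [0, 1)``.

    Raised-cosine upstroke from 0 to 1 over the first ``UPSTROKE_FRACTION``
    of the cycle, then an exponential decay back to 0 at the cycle end.
    """
    u = np.asarray(u, dtype=float)
    s = np.empty_like(u)
    up = u < UPSTROKE_FRACTION
    s[up] = 0.5 * (1.0 - np.cos(np.pi * u[up] / UPSTROKE_FRACTION))
    v = u[~up] - UPSTROKE_FRACTION
    span = 1.0 - UPSTROKE_FRACTION
    e0 = math.exp(-DECAY_RATE * span)
    s[~up] = (np.exp(-DECAY_RATE * v) - e0) / (1.0 - e0)
    return s


def _template_mean() -> float:
    u = np.linspace(0.0, 1.0, 20001)
    return float(np.trapezoid(pulse_template(u), u))


#: time-weighted mean of the normalized template; the true MAP of a beat is
#: defined as DBP + MAP_FRACTION * (SBP - DBP) so generator truth and
#: waveform-derived MAP agree by construction
MAP_FRACTION = _template_mean()


# ---------------------------------------------------------------------------
# trajectory

def _response(t: np.ndarray, spec: SessionSpec) -> np.ndarray:
    """Stressor response shape in [0, 1]: linear on/off ramps per bout."""
    ramp = RAMP_S.get(spec.activity, 20.0)
    r = np.zeros_like(t, dtype=float)
    for a, b in spec.active_intervals():
        rise = np.clip((t - a) / ramp, 0.0, 1.0)
        fall = np.clip(1.0 - (t - b) / ramp, 0.0, 1.0)
        r += rise * fall
    return np.clip(r, 0.0, 1.0)


def _ar1(n: int, sd: float, rng: np.random.Generator, phi: float = AR1_COEFF) -> np.ndarray:
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x


def simulate_session_trajectory(
    params: SubjectParams,
    spec: SessionSpec,
    rng: np.random.Generator,
    day: int = 1,
) -> BeatSeries:
    """True per-beat BP/HR series for one session.

    Beat times come from integrating the instantaneous heart rate (baseline
    plus ramped activity response plus slow AR(1) wander); SBP/DBP are the
    baseline plus the ramped response amplitude plus AR(1) beat noise; the
    true MAP is ``DBP + MAP_FRACTION * (SBP - DBP)``.
    """
    T = spec.total_duration
    if T <= 0:
        raise ValueError("session has zero duration: empty series")
    d_sbp, d_dbp, d_hr = params.amplitudes.get(spec.activity, (0.0, 0.0, 0.0))

    # dense HR grid -> beat times where the cumulative phase crosses integers
    grid_dt = 0.25
    tg = np.arange(0.0, T + grid_dt, grid_dt)
    hr_g = params.hr0 + d_hr * _response(tg, spec)
    if params.hr_noise_sd > 0:
        hr_g = hr_g + _ar1(tg.size, params.hr_noise_sd, rng, phi=0.95)
    hr_g = np.clip(hr_g, 30.0, 220.0)
    phase = np.concatenate(
        [[0.0], np.cumsum((hr_g[1:] + hr_g[:-1]) / 2.0 * grid_dt / 60.0)]
    )
    n_beats_total = int(np.floor(phase[-1]))
    peaks = np.interp(np.arange(n_beats_total + 1), phase, tg)
    peaks = peaks[peaks <= T + 1e-9]
    if peaks.size < 2:
        raise ValueError("session too short for a single cardiac cycle")

    t = peaks[:-1]
    r = _response(t, spec)
    off = params.session_offsets.get((spec.activity, day), 0.0)
    sbp = params.sbp0 + off + d_sbp * r + _ar1(t.size, params.noise_sd, rng)
    dbp = (
        params.dbp0 + off + d_dbp * r
        + _ar1(t.size, params.noise_sd * DBP_NOISE_SCALE, rng)
    )
    dbp = np.minimum(dbp, sbp - 5.0)  # physiological pulse-pressure floor
    map_ = dbp + MAP_FRACTION * (sbp - dbp)
    hr = 60.0 / np.diff(peaks)
    return BeatSeries(
        t, peaks[1:], sbp, dbp, map_, hr,
        np.ones(t.size, dtype=bool), spec.activity, params.subject_id, day,
    )


def simulate_bp_trajectory(
    params: SubjectParams, protocol: ProtocolSpec, day: int = 1
) -> list[BeatSeries]:
    """True per-beat series for every session of a protocol day (seeded)."""
    rng = np.random.default_rng(params.seed)
    return [
        simulate_session_trajectory(params, spec, rng, day=day)
        for spec in protocol.sessions
    ]


# ---------------------------------------------------------------------------
# waveform

def simulate_waveform(
    beats: BeatSeries, sampling_rate: float = 125.0
) -> WaveformRecord:
    """Continuous pressure waveform from a per-beat truth series.

    Each cycle ``[R_i, R_{i+1})`` carries one template pulse rescaled so the
    emitted samples' maximum equals that beat's true SBP and minimum its
    true DBP exactly (the rescale absorbs the sampling grid's miss of the
    template peak). R-peak times are emitted alongside.
    """
    if sampling_rate < 100.0:
        raise ValueError("sampling rate must be at least 100 Hz")
    peaks = np.concatenate([beats.t_start, beats.t_end[-1:]])
    fs = float(sampling_rate)
    j0 = int(np.ceil(peaks[0] * fs - 1e-9))
    j1 = int(np.ceil(peaks[-1] * fs - 1e-9))
    t = np.arange(j0, j1) / fs
    idx = np.searchsorted(peaks, t, side="right") - 1
    idx = np.clip(idx, 0, len(beats) - 1)
    durations = (beats.t_end - beats.t_start)[idx]
    u = (t - beats.t_start[idx]) / durations
    s = pulse_template(np.clip(u, 0.0, 1.0 - 1e-12))

    # per-beat sample counts for exact max/min renormalization
    bounds = np.ceil(peaks * fs - 1e-9).astype(int) - j0
    starts = bounds[:-1]
    if np.any(np.diff(bounds) < 2):
        raise ValueError("a beat spans fewer than 2 samples at this rate")
    smax = np.maximum.reduceat(s, starts)
    smin = np.minimum.reduceat(s, starts)
    scale = np.where(smax > smin, smax - smin, 1.0)
    s_norm = (s - smin[idx]) / scale[idx]
    pressure = beats.dbp[idx] + (beats.sbp[idx] - beats.dbp[idx]) * s_norm
    return WaveformRecord(
        pressure, fs, peaks,
        activity=beats.activity, subject_id=beats.subject_id, day=beats.day,
        t0=j0 / fs,
    )


# ---------------------------------------------------------------------------
# brachial readings

def simulate_brachial_readings(
    truth: BeatSeries,
    rest_window: tuple[float, float] = (0.0, 240.0),
    noise_sd: float = BRACHIAL_NOISE_SD,
    rng: np.random.Generator | None = None,
) -> BrachialTriplet:
    """Three cuff (SBP, DBP) readings at 60-s spacing during the rest.

    Reading k (at ``rest_start + 60*k`` for k = 1, 2, 3) is the mean of the
    true beat values over the preceding 60 s plus Gaussian reading noise.
    """
    rng = rng or np.random.default_rng(0)
    lo, hi = rest_window
    if hi - lo < 180.0:
        raise ValueError("rest window must be at least 3 min for a triplet")
    times = lo + 60.0 * np.arange(1, 4)
    sbp = np.empty(3)
    dbp = np.empty(3)
    for k, tk in enumerate(times):
        sel = (truth.t_start >= tk - 60.0) & (truth.t_start < tk)
        if not sel.any():
            raise ValueError("no beats in a brachial reading window")
        sbp[k] = truth.sbp[sel].mean() + rng.normal(0.0, noise_sd)
        dbp[k] = truth.dbp[sel].mean() + rng.normal(0.0, noise_sd)
    return BrachialTriplet(times, sbp, dbp)


# ---------------------------------------------------------------------------
# PPG-like features

FEATURE_NAMES = (
    "pulse_amplitude",
    "half_width_s",
    "rise_time_s",
    "decay_time_s",
    "max_slope",
    "reflection_index",
    "segment_hr",
)

# rows: features, columns: (SBP, DBP, MAP, HR) -> feature units. A documented
# open stand-in for the device's proprietary feature set: amplitude tracks
# pulse pressure, the width/timing features shorten with HR and stiffen with
# pressure, the slope and reflection surrogates mix SBP and MAP, and the last
# feature is the segment HR itself. The matrix has full column rank so a
# linear regressor can in principle invert it.
DEFAULT_FEATURE_COEFFS = np.array(
    [
        [0.010, -0.010, 0.000, 0.0000],
        [0.000, 0.000, 0.000, -0.0030],
        [0.000, 0.000, -0.001, -0.0015],
        [0.000, 0.002, 0.003, -0.0040],
        [0.020, -0.015, 0.005, 0.0010],
        [0.002, 0.001, 0.004, -0.0010],
        [0.000, 0.000, 0.000, 1.0000],
    ]
)
DEFAULT_FEATURE_INTERCEPTS = np.array([0.0, 0.70, 0.35, 0.40, 0.0, 0.30, 0.0])
DEFAULT_FEATURE_NOISE_SD = np.array(
    [0.005, 0.005, 0.005, 0.005, 0.010, 0.005, 0.5]
)


def simulate_ppg_features(
    truth: BeatSeries,
    duration_s: float,
    coeffs: np.ndarray = DEFAULT_FEATURE_COEFFS,
    intercepts: np.ndarray | None = None,
    noise_sd: np.ndarray | float = 0.0,
    rng: np.random.Generator | None = None,
    latent_error: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-15-s-segment feature stream, linear in segment-mean (SBP, DBP, MAP, HR).

    ``latent_error`` (n_segments x 3, mmHg) is added to the (SBP, DBP, MAP)
    segment means before the linear map — the hook through which the device
    error model perturbs what the device "sees". With zero noise and zero
    error the features are an exact linear function of the truth, so a
    linear regressor can recover BP exactly.
    """
    rng = rng or np.random.default_rng(0)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 2 or coeffs.shape[1] != 4:
        raise ValueError("coefficient matrix must be (n_features, 4)")
    if intercepts is None:
        intercepts = (
            DEFAULT_FEATURE_INTERCEPTS
            if coeffs.shape == DEFAULT_FEATURE_COEFFS.shape
            else np.zeros(coeffs.shape[0])
        )
    intercepts = np.asarray(intercepts, dtype=float)
    if intercepts.shape != (coeffs.shape[0],):
        raise ValueError("intercepts do not match the coefficient matrix")

    seg = aggregate_segments(truth, duration_s)
    latent = seg[["sbp", "dbp", "map", "hr"]].to_numpy()
    if latent_error is not None:
        latent_error = np.asarray(latent_error, dtype=float)
        if latent_error.shape != (latent.shape[0], 3):
            raise ValueError("latent_error must be (n_segments, 3)")
        latent = latent.copy()
        latent[:, :3] += latent_error
    feats = latent @ coeffs.T + intercepts
    noise_sd = np.broadcast_to(
        np.asarray(noise_sd, dtype=float), (coeffs.shape[0],)
    )
    if np.any(noise_sd > 0):
        feats = feats + rng.normal(0.0, 1.0, feats.shape) * noise_sd
    names = (
        list(FEATURE_NAMES)
        if coeffs.shape[0] == len(FEATURE_NAMES)
        else [f"f{i + 1}" for i in range(coeffs.shape[0])]
    )
    out = pd.DataFrame(feats, columns=names)
    out.insert(0, "segment_start_s", seg["window_start_s"].to_numpy())
    out["missing"] = seg["missing"].to_numpy()
    out.loc[out["missing"], names] = np.nan
    return out


# ---------------------------------------------------------------------------
# device error model

@dataclass(frozen=True)
class DeviceErrorModel:
    """Error structure of the simulated cuffless device.

    Per BP parameter (SBP, DBP, MAP): a fixed bias, a per-subject random
    effect SD, per-segment white noise SD, a within-day drift and a fixed
    day-2 shift (all mmHg; drift in mmHg/h). ``feature_noise_sd`` is the
    additive noise on the emitted feature stream itself. With every field
    zero the simulated device sees the truth exactly.
    """

    bias: tuple[float, float, float] = (0.3, 0.3, 0.3)
    subject_sd: tuple[float, float, float] = (6.0, 4.5, 5.5)
    segment_sd: tuple[float, float, float] = (6.0, 4.5, 5.5)
    drift_per_hour: tuple[float, float, float] = (0.0, 0.0, 0.0)
    day2_shift: tuple[float, float, float] = (2.0, 2.0, 2.0)
    feature_noise_sd: np.ndarray | float = field(
        default_factory=lambda: DEFAULT_FEATURE_NOISE_SD.copy()
    )

    def __post_init__(self) -> None:
        for name in ("subject_sd", "segment_sd"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def zero(cls) -> "DeviceErrorModel":
        z = (0.0, 0.0, 0.0)
        return cls(z, z, z, z, z, 0.0)


# ---------------------------------------------------------------------------
# cohort

@dataclass
class SessionData:
    """Everything generated for one subject-session."""

    activity: str
    day: int
    start_of_day_s: float
    spec: SessionSpec
    waveform: WaveformRecord
    truth: BeatSeries
    brachial: BrachialTriplet
    features: pd.DataFrame
    device_error: pd.DataFrame  # per-segment latent error draws (sbp,dbp,map)


@dataclass
class SimulatedSubject:
    subject_id: str
    params: SubjectParams
    sessions: list[SessionData]
    has_day2: bool
    subject_effect: tuple[float, float, float]  # device random effect, mmHg

    def day_sessions(self, day: int) -> list[SessionData]:
        return [s for s in self.sessions if s.day == day]


def _draw_params(
    subject_id: str,
    rng: np.random.Generator,
    seed: int,
    beat_noise_sd: float = BEAT_NOISE_SD,
    hr_noise_sd: float = HR_NOISE_SD,
    amplitude_scale: float = 1.0,
) -> SubjectParams:
    sbp0 = rng.normal(*BASELINE_SBP)
    dbp0 = rng.normal(*BASELINE_DBP)
    dbp0 = min(dbp0, sbp0 - 25.0)
    hr0 = rng.normal(*BASELINE_HR)
    amps = {
        a: tuple(
            amplitude_scale * m * rng.lognormal(0.0, AMP_SIGMA)
            for m in AMP_MEDIANS[a]
        )
        for a in ACTIVITIES
    }
    return SubjectParams(
        subject_id, float(sbp0), float(dbp0), float(np.clip(hr0, 45.0, 100.0)),
        amps, noise_sd=beat_noise_sd, hr_noise_sd=hr_noise_sd, seed=seed,
    )


INTER_SESSION_BREAK_S = 420.0  # nominal break between recordings within a day


def _build_session(
    params: SubjectParams,
    spec: SessionSpec,
    day: int,
    start_of_day: float,
    error: DeviceErrorModel,
    subject_effect: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    brachial_noise_sd: float = BRACHIAL_NOISE_SD,
) -> SessionData:
    truth = simulate_session_trajectory(params, spec, rng, day=day)
    waveform = simulate_waveform(truth, fs)
    brachial = simulate_brachial_readings(
        truth, (0.0, spec.rest_s), noise_sd=brachial_noise_sd, rng=rng
    )
    duration = spec.total_duration
    n_seg = int(np.floor(duration / 15.0))
    seg_t = np.arange(n_seg) * 15.0
    err = np.empty((n_seg, 3))
    for j in range(3):
        hours = (start_of_day + seg_t) / 3600.0
        err[:, j] = (
            error.bias[j]
            + subject_effect[j]
            + rng.normal(0.0, error.segment_sd[j], n_seg)
            + error.drift_per_hour[j] * hours
            + (error.day2_shift[j] if day == 2 else 0.0)
        )
    features = simulate_ppg_features(
        truth, duration,
        noise_sd=error.feature_noise_sd,
        rng=rng,
        latent_error=err,
    )
    device_error = pd.DataFrame(
        err, columns=["sbp", "dbp", "map"]
    )
    device_error.insert(0, "segment_start_s", seg_t)
    return SessionData(
        spec.activity, day, start_of_day, spec, waveform, truth, brachial,
        features, device_error,
    )


def simulate_cohort(
    n_subjects: int = 38,
    protocol: ProtocolSpec | None = None,
    error_model: DeviceErrorModel | None = None,
    seed: int = 0,
    n_day2: int | None = None,
    sampling_rate: float = 125.0,
    beat_noise_sd: float = BEAT_NOISE_SD,
    hr_noise_sd: float = HR_NOISE_SD,
    brachial_noise_sd: float = BRACHIAL_NOISE_SD,
    session_offset_sd: float = SESSION_OFFSET_SD,
    amplitude_scale: float = 1.0,
) -> list[SimulatedSubject]:
    """Generate a full synthetic cohort (seeded, bit-reproducible).

    ``n_day2`` subjects (default: the same 11-of-38 proportion as the study
    cohort) additionally receive a day-2 handgrip session. The ``*_sd``
    overrides exist so noiseless limiting cases can be simulated; the
    module-level defaults are the study conditions.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    protocol = protocol or default_protocol()
    error = error_model or DeviceErrorModel()
    if n_day2 is None:
        n_day2 = int(round(n_subjects * 11 / 38))
    n_day2 = min(n_day2, n_subjects)
    master = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    day2_handgrip = next(
        (s for s in protocol.sessions if s.activity == "handgrip"),
        protocol.sessions[0],
    )
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        params = _draw_params(
            sid, rng, sub_seed, beat_noise_sd, hr_noise_sd, amplitude_scale
        )
        sessions_specs = [(spec, 1) for spec in protocol.sessions]
        has_day2 = i < n_day2
        if has_day2:
            sessions_specs.append((day2_handgrip, 2))
        for spec, day in sessions_specs:
            params.session_offsets[(spec.activity, day)] = (
                rng.normal(0.0, session_offset_sd) if session_offset_sd else 0.0
            )
        subject_effect = np.array(
            [rng.normal(0.0, sd) for sd in error.subject_sd]
        )
        sessions = []
        start = {1: 0.0, 2: 0.0}
        for spec, day in sessions_specs:
            sessions.append(
                _build_session(
                    params, spec, day, start[day], error, subject_effect,
                    sampling_rate, rng, brachial_noise_sd,
                )
            )
            start[day] += spec.total_duration + INTER_SESSION_BREAK_S
        subjects.append(
            SimulatedSubject(sid, params, sessions, has_day2,
                             tuple(subject_effect))
        )
    return subjects


# ---------------------------------------------------------------------------
# artifact injection

def inject_artifacts(
    record: WaveformRecord,
    fraction: float,
    pattern: str = "mixed",
    seed: int = 0,
    burst_s: tuple[float, float] = (0.8, 2.5),
    noise_sd: float = 25.0,
) -> WaveformRecord:
    """Corrupt a stated fraction of samples, recording ground truth.

    Replaces random non-overlapping runs with either flat lines
    (calibration-gap-like) or added high-frequency white noise, per
    ``pattern`` ("flat" | "noise" | "mixed"), until at least ``fraction`` of
    the samples are affected. Injected positions are flagged in
    ``artifact_truth`` so filter recall is computable. ``fraction = 0``
    returns an untouched copy. New runs never overlap previously injected
    ones, so masking stays monotone under repeated injection.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if pattern not in ("flat", "noise", "mixed"):
        raise ValueError(f"unknown artifact pattern {pattern!r}")
    p = record.pressure.copy()
    truth = (
        record.artifact_truth.copy()
        if record.artifact_truth is not None
        else np.zeros(p.size, dtype=bool)
    )
    rng = np.random.default_rng(seed)
    target = int(round(fraction * p.size))
    flat_next = pattern in ("flat", "mixed")
    attempts = 0
    injected = 0
    while injected < target and attempts < 100000:
        attempts += 1
        n_run = int(rng.uniform(*burst_s) * record.fs)
        n_run = min(max(n_run, 2), p.size)
        start = int(rng.integers(0, p.size - n_run + 1))
        sl = slice(start, start + n_run)
        if truth[sl].any():
            continue
        use_flat = flat_next if pattern == "mixed" else (pattern == "flat")
        if use_flat:
            p[sl] = p[start]
        else:
            p[sl] = p[sl] + rng.normal(0.0, noise_sd, n_run)
        if pattern == "mixed":
            flat_next = not flat_next
        truth[sl] = True
        injected += n_run
    return replace(record, pressure=p, artifact_truth=truth)
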