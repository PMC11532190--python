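"""Beat-to-beat processing of continuous arterial-pressure waveforms.

Turns a uniformly sampled pressure trace plus ECG R-peak times into
quality-filtered per-cardiac-cycle SBP/DBP/MAP/HR values and per-15-second
segment means, the analysis unit of the downstream agreement statistics.

Conventions
-----------
* A cardiac cycle is the half-open interval ``[R_i, R_{i+1})`` between
  consecutive R-peaks; the trailing partial cycle after the last peak is
  discarded.
* SBP is the cycle maximum, DBP the cycle minimum, MAP the time-weighted
  (trapezoidal) mean of the pressure over the cycle.
* 15-s segment windows are aligned to the session start (time 0) and a final
  partial window is dropped; a window with no accepted beat is flagged
  missing, never zero-valued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WaveformRecord",
    "BeatMeasurement",
    "BeatSeries",
    "FilterThresholds",
    "ExclusionDecision",
    "segment_cycles",
    "compute_beat_bp",
    "compute_hr",
    "process_record",
    "filter_artifacts",
    "aggregate_segments",
    "subject_exclusion",
]

SEGMENT_WINDOW_S = 15.0

BP_PARAMS = ("sbp", "dbp", "map")


@dataclass
class WaveformRecord:
    """One activity session's continuous pressure trace with R-peak times.

    ``pressure`` is uniformly sampled at ``fs`` Hz; sample ``j`` is at time
    ``t0 + j / fs`` seconds on the session clock. ``r_peaks`` are ECG R-peak
    times (seconds, session clock), strictly increasing and within the
    sampled span (± one sample spacing at the edges).
    """

    pressure: np.ndarray
    fs: float
    r_peaks: np.ndarray
    activity: str = ""
    subject_id: str = ""
    day: int = 1
    t0: float = 0.0
    # ground-truth mask of injected artifacts (True = artifact); set by the
    # synthetic generator, None for real data
    artifact_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.pressure.ndim != 1:
            raise ValueError("pressure must be a 1-D sample array")
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        dt = 1.0 / self.fs
        lo, hi = self.t0 - dt, self.t0 + self.pressure.size * dt + dt
        if self.r_peaks.size and (
            self.r_peaks[0] < lo or self.r_peaks[-1] > hi
        ):
            raise ValueError("R-peak outside the sampled span")

    @property
    def n_samples(self) -> int:
        return self.pressure.size

    @property
    def duration(self) -> float:
        """Sampled span in seconds."""
        return self.pressure.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.pressure.size) / self.fs

    def shifted(self, offset_mmhg: float) -> "WaveformRecord":
        """Return a copy with ``offset_mmhg`` added to every sample."""
        return replace(self, pressure=self.pressure + offset_mmhg)


@dataclass
class BeatMeasurement:
    """SBP/DBP/MAP/HR of a single cardiac cycle."""

    t_start: float
    t_end: float
    sbp: float
    dbp: float
    map: float
    hr: float
    quality: bool = True

    def __post_init__(self) -> None:
        if self.quality and not (
            self.dbp - 1e-9 <= self.map <= self.sbp + 1e-9
        ):
            raise ValueError("MAP must lie between DBP and SBP")


@dataclass
class BeatSeries:
    """Per-beat BP/HR values for one session (arrays share one length)."""

    t_start: np.ndarray
    t_end: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    hr: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]
    activity: str = ""
    subject_id: str = ""
    day: int = 1

    def __post_init__(self) -> None:
        for name in ("t_start", "t_end", "sbp", "dbp", "map", "hr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.quality is None:
            self.quality = np.ones(self.t_start.size, dtype=bool)
        self.quality = np.asarray(self.quality, dtype=bool)

    def __len__(self) -> int:
        return self.t_start.size

    def accepted(self) -> "BeatSeries":
        m = self.quality
        return BeatSeries(
            self.t_start[m], self.t_end[m], self.sbp[m], self.dbp[m],
            self.map[m], self.hr[m], np.ones(m.sum(), dtype=bool),
            self.activity, self.subject_id, self.day,
        )

    def shifted(self, offset_mmhg: float) -> "BeatSeries":
        """Additive BP shift (SBP, DBP and MAP move together)."""
        return replace(
            self,
            sbp=self.sbp + offset_mmhg,
            dbp=self.dbp + offset_mmhg,
            map=self.map + offset_mmhg,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_start": self.t_start,
                "t_end": self.t_end,
                "sbp": self.sbp,
                "dbp": self.dbp,
                "map": self.map,
                "hr": self.hr,
                "quality": self.quality,
            }
        )


def segment_cycles(record: WaveformRecord) -> list[tuple[int, int]]:
    """Half-open sample-index windows ``[R_i, R_{i+1})`` per cycle.

    Returns one ``(start, end)`` index pair per consecutive R-peak pair; the
    trailing partial cycle (after the last peak) is discarded. Fewer than two
    R-peaks yields an empty list with a warning.
    """
    peaks = record.r_peaks
    if peaks.size < 2:
        warnings.warn("fewer than 2 R-peaks: no complete cardiac cycle")
        return []
    idx = np.ceil((peaks - record.t0) * record.fs - 1e-9).astype(int)
    idx = np.clip(idx, 0, record.n_samples)
    return [(int(idx[i]), int(idx[i + 1])) for i in range(idx.size - 1)]


def compute_beat_bp(
    samples: np.ndarray,
    fs: float,
    *,
    t_start: float = 0.0,
    duration_s: float | None = None,
) -> BeatMeasurement:
    """SBP/DBP/MAP for one cycle's samples.

    SBP/DBP are the sample maximum/minimum; MAP is the trapezoidal time
    integral of pressure over the sampled span divided by that span. HR is
    60 / cycle duration (``duration_s``, defaulting to ``n / fs``).
    Non-finite samples fail the quality flag.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("a cycle needs at least 2 samples")
    if duration_s is None:
        duration_s = samples.size / fs
    hr = 60.0 / duration_s
    if not np.all(np.isfinite(samples)):
        return BeatMeasurement(
            t_start, t_start + duration_s, np.nan, np.nan, np.nan, hr,
            quality=False,
        )
    dt = 1.0 / fs
    mean = float(np.trapezoid(samples, dx=dt) / ((samples.size - 1) * dt))
    return BeatMeasurement(
        t_start,
        t_start + duration_s,
        float(samples.max()),
        float(samples.min()),
        mean,
        hr,
    )


def compute_hr(r_peaks: np.ndarray) -> np.ndarray:
    """Per-beat heart rate, ``HR_i = 60 / (R_{i+1} - R_i)`` beats/min."""
    r_peaks = np.asarray(r_peaks, dtype=float)
    if r_peaks.size < 2:
        raise ValueError("need at least 2 R-peaks")
    rr = np.diff(r_peaks)
    if np.any(rr <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    return 60.0 / rr


def process_record(
    record: WaveformRecord, sample_mask: np.ndarray | None = None
) -> BeatSeries:
    """Vectorized per-beat extraction over a whole record.

    ``sample_mask`` marks artifact samples (True = masked); any beat whose
    window overlaps a masked or non-finite sample gets ``quality=False``
    (its values are still computed when finite, but excluded downstream).
    Matches :func:`compute_beat_bp` beat-by-beat to machine precision.
    """
    windows = segment_cycles(record)
    if not windows:
        z = np.empty(0)
        return BeatSeries(z, z, z, z, z, z, np.empty(0, dtype=bool),
                          record.activity, record.subject_id, record.day)
    p = record.pressure
    dt = 1.0 / record.fs
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    n_per = ends - starts
    if np.any(n_per < 2):
        raise ValueError("a cycle shorter than 2 samples was found")

    last = ends[-1]
    sbp = np.maximum.reduceat(p[:last], starts)
    dbp = np.minimum.reduceat(p[:last], starts)
    # cumulative trapezoid -> per-beat time-weighted mean
    ct = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) * (dt / 2.0))])
    integ = ct[ends - 1] - ct[starts]
    mean = integ / ((n_per - 1) * dt)

    peaks = record.r_peaks
    durations = np.diff(peaks)
    hr = 60.0 / durations

    finite = np.isfinite(p[:last])
    bad = ~finite
    if sample_mask is not None:
        bad = bad | np.asarray(sample_mask, dtype=bool)[:last]
    cum_bad = np.concatenate([[0], np.cumsum(bad)])
    quality = (cum_bad[ends] - cum_bad[starts]) == 0

    return BeatSeries(
        peaks[:-1], peaks[1:], sbp, dbp, mean, hr, quality,
        record.activity, record.subject_id, record.day,
    )


@dataclass(frozen=True)
class FilterThresholds:
    """Defaults for the automatic artifact filter.

    * ``flat_min_s`` — a run of (near-)zero sample-to-sample change at least
      this long is treated as a calibration gap (Physiocal/AutoCal-like).
    * ``range_lo/range_hi`` — samples outside this mmHg band are
      physiologically impossible.
    * ``hf_*`` — a short-time window whose spectral power above
      ``hf_cutoff_hz`` exceeds ``hf_ratio`` of total (DC removed) is
      high-frequency noise.
    """

    flat_min_s: float = 0.5
    flat_eps: float = 1e-6
    range_lo: float = 20.0
    range_hi: float = 300.0
    hf_cutoff_hz: float = 20.0
    hf_ratio: float = 0.3
    hf_window_s: float = 1.0


def filter_artifacts(
    record: WaveformRecord, thresholds: FilterThresholds | None = None
) -> np.ndarray:
    """Boolean artifact mask over samples (True = masked).

    Applies the three filter rules of :class:`FilterThresholds`; the
    high-frequency rule is skipped when the sampling rate cannot resolve the
    cutoff band (``fs <= 2 * hf_cutoff_hz``).
    """
    th = thresholds or FilterThresholds()
    p = record.pressure
    mask = np.zeros(p.size, dtype=bool)

    mask |= ~np.isfinite(p)
    with np.errstate(invalid="ignore"):
        mask |= (p < th.range_lo) | (p > th.range_hi)

    # flat-line runs: |dp| < eps for >= flat_min_s
    min_run = max(int(round(th.flat_min_s * record.fs)), 2)
    flat = np.abs(np.diff(p)) < th.flat_eps
    if flat.any():
        edges = np.diff(np.concatenate([[0], flat.view(np.int8), [0]]))
        run_starts = np.flatnonzero(edges == 1)
        run_ends = np.flatnonzero(edges == -1)
        for s, e in zip(run_starts, run_ends):
            if e - s + 1 >= min_run:  # run of e-s flat diffs spans e-s+1 samples
                mask[s : e + 1] = True

    if record.fs > 2 * th.hf_cutoff_hz:
        win = max(int(round(th.hf_window_s * record.fs)), 8)
        n_win = p.size // win
        if n_win:
            seg = p[: n_win * win].reshape(n_win, win)
            seg = np.where(np.isfinite(seg), seg, 0.0)
            seg = seg - seg.mean(axis=1, keepdims=True)
            spec = np.abs(np.fft.rfft(seg, axis=1)) ** 2
            freqs = np.fft.rfftfreq(win, d=1.0 / record.fs)
            total = spec.sum(axis=1)
            high = spec[:, freqs > th.hf_cutoff_hz].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                noisy = np.where(total > 0, high / total, 0.0) > th.hf_ratio
            mask[: n_win * win] |= np.repeat(noisy, win)
    return mask


def aggregate_segments(
    beats: BeatSeries,
    duration_s: float,
    window_s: float = SEGMENT_WINDOW_S,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-window means of accepted beats over non-overlapping windows.

    Windows are ``[k*window_s, (k+1)*window_s)`` from the session start; a
    final partial window (beyond ``floor(duration/window)``) is dropped.
    Each accepted beat contributes to the window containing its cycle start,
    with an unweighted mean per window. A window whose accepted beats cover
    less than ``min_coverage`` of its span (in particular one with no
    accepted beat at all) is flagged ``missing`` — removed reference data —
    and is never zero-valued. Returns a DataFrame with columns
    ``window_start_s, sbp, dbp, map, hr, n_beats, coverage, missing``.
    """
    n_windows = int(np.floor(duration_s / window_s + 1e-9))
    starts = np.arange(n_windows) * window_s
    out = pd.DataFrame(
        {
            "window_start_s": starts,
            "sbp": np.nan,
            "dbp": np.nan,
            "map": np.nan,
            "hr": np.nan,
            "n_beats": 0,
            "coverage": 0.0,
            "missing": True,
        }
    )
    acc = beats.accepted()
    if len(acc) == 0 or n_windows == 0:
        return out
    win = np.floor(acc.t_start / window_s + 1e-9).astype(int)
    keep = (win >= 0) & (win < n_windows)
    win = win[keep]
    df = pd.DataFrame(
        {
            "win": win,
            "sbp": acc.sbp[keep],
            "dbp": acc.dbp[keep],
            "map": acc.map[keep],
            "hr": acc.hr[keep],
            "dur": (acc.t_end - acc.t_start)[keep],
        }
    )
    g = df.groupby("win")
    means = g[["sbp", "dbp", "map", "hr"]].mean()
    counts = g.size()
    covered = g["dur"].sum() / window_s
    out.loc[means.index, ["sbp", "dbp", "map", "hr"]] = means.to_numpy()
    out.loc[counts.index, "n_beats"] = counts.to_numpy()
    out.loc[covered.index, "coverage"] = covered.to_numpy()
    out["missing"] = (out["n_beats"] == 0) | (out["coverage"] < min_coverage)
    return out


@dataclass(frozen=True)
class ExclusionDecision:
    excluded: bool
    removed_fraction: float
    reason: str


def subject_exclusion(n_removed: int, n_total: int) -> ExclusionDecision:
    """Exclude a subject iff strictly more than 50% of reference segments
    were removed; exactly 50% is retained. Zero total data is excluded with
    its own reason."""
    if n_total == 0:
        return ExclusionDecision(True, 1.0, "no reference data")
    frac = n_removed / n_total
    if frac > 0.5:
        return ExclusionDecision(True, frac, "more than 50% of reference data removed")
    return ExclusionDecision(False, frac, "retained")
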