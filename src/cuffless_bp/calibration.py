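"""Calibration procedures.

Two distinct calibrations exist in this pipeline and must not be conflated:

1. **Reference (per activity).** The continuous finger-cuff waveform is
   re-anchored before every activity: the brachial calibration value is the
   mean of the *last two* of three cuff readings taken during the
   pre-activity rest, and the whole waveform is shifted additively so that
   the mean systolic peak in the rest window matches it. Because the whole
   waveform shifts, DBP and MAP move by the same constant.

2. **Device (once per subject).** The cuffless estimate receives a single
   additive offset per BP parameter, computed during the initial rest of the
   first session against the calibrated reference, and applied to every
   later segment on every day. It is never recomputed; a second application
   is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beats import BP_PARAMS, BeatSeries, WaveformRecord, process_record

__all__ = [
    "BrachialTriplet",
    "CalibrationOffset",
    "brachial_calibration_value",
    "calibrate_reference_waveform",
    "calibrate_reference_beats",
    "calibrate_device_once",
    "apply_device_calibration",
]


@dataclass
class BrachialTriplet:
    """Three timestamped brachial cuff (SBP, DBP) readings from one rest."""

    times: np.ndarray  # s, session clock
    sbp: np.ndarray    # mmHg
    dbp: np.ndarray    # mmHg

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if not (self.times.size == self.sbp.size == self.dbp.size == 3):
            raise ValueError("a brachial triplet has exactly three readings")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("reading timestamps must be ascending")


@dataclass
class CalibrationOffset:
    """Additive offset(s) in mmHg with provenance."""

    offsets: dict[str, float]  # per BP parameter
    source: str                # "reference-brachial" | "device-one-point"
    anchor_time_s: float

    def __post_init__(self) -> None:
        for k, v in self.offsets.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite calibration offset for {k}")


def brachial_calibration_value(
    triplet: BrachialTriplet, param: str = "sbp"
) -> float:
    """Mean of the last two of the three cuff readings (default: SBP)."""
    vals = getattr(triplet, param)
    return float(np.mean(vals[1:3]))


def _rest_window_peak_mean(
    record: WaveformRecord,
    rest_window: tuple[float, float],
    mask: np.ndarray | None,
) -> float:
    beats = process_record(record, sample_mask=mask).accepted()
    lo, hi = rest_window
    sel = (beats.t_start >= lo) & (beats.t_start < hi)
    if not sel.any():
        raise ValueError("no accepted beats in the rest window")
    return float(beats.sbp[sel].mean())


def calibrate_reference_waveform(
    record: WaveformRecord,
    triplet: BrachialTriplet,
    rest_window: tuple[float, float] = (0.0, 240.0),
    mask: np.ndarray | None = None,
) -> tuple[WaveformRecord, CalibrationOffset]:
    """Shift the waveform so rest-window systolic peaks match the brachial value.

    offset = brachial calibration SBP − mean(accepted cycle maxima in the
    rest window); the offset is added to every sample of the record.
    """
    target = brachial_calibration_value(triplet, "sbp")
    peak_mean = _rest_window_peak_mean(record, rest_window, mask)
    off = target - peak_mean
    offset = CalibrationOffset(
        {p: off for p in BP_PARAMS}, "reference-brachial", rest_window[0]
    )
    return record.shifted(off), offset


def calibrate_reference_beats(
    beats: BeatSeries,
    triplet: BrachialTriplet,
    rest_window: tuple[float, float] = (0.0, 240.0),
) -> tuple[BeatSeries, CalibrationOffset]:
    """Beat-level equivalent of :func:`calibrate_reference_waveform`.

    Shifting the waveform by +c shifts every beat's SBP/DBP/MAP by exactly
    +c, so the per-activity recalibration can be applied to an already
    extracted (quality-filtered) beat series without reprocessing samples.
    """
    target = brachial_calibration_value(triplet, "sbp")
    acc = beats.accepted()
    lo, hi = rest_window
    sel = (acc.t_start >= lo) & (acc.t_start < hi)
    if not sel.any():
        raise ValueError("no accepted beats in the rest window")
    off = target - float(acc.sbp[sel].mean())
    offset = CalibrationOffset(
        {p: off for p in BP_PARAMS}, "reference-brachial", rest_window[0]
    )
    return beats.shifted(off), offset


def calibrate_device_once(
    device_segments: pd.DataFrame,
    reference_segments: pd.DataFrame,
    anchor_window: tuple[float, float] = (180.0, 240.0),
    params: tuple[str, ...] = BP_PARAMS,
) -> CalibrationOffset:
    """One-time per-subject offset of the device against the reference.

    Both inputs are segment tables (``window_start_s`` plus one column per
    BP parameter, NaN where missing) for the *first* session, whose initial
    rest contains the anchor window (default: its last 60 s). Per parameter,
    offset = mean(reference) − mean(device) over anchor windows where both
    are present. The offset is meant to be added to all of the subject's
    device segments on all days and never recomputed.
    """
    lo, hi = anchor_window
    offsets: dict[str, float] = {}
    dsel = device_segments[
        (device_segments["window_start_s"] >= lo)
        & (device_segments["window_start_s"] < hi)
    ]
    rsel = reference_segments[
        (reference_segments["window_start_s"] >= lo)
        & (reference_segments["window_start_s"] < hi)
    ]
    merged = dsel.merge(
        rsel, on="window_start_s", suffixes=("_dev", "_ref"), how="inner"
    )
    for p in params:
        both = merged[[f"{p}_dev", f"{p}_ref"]].dropna()
        if both.empty:
            raise ValueError(
                f"subject uncalibratable: no paired anchor data for {p}"
            )
        offsets[p] = float(both[f"{p}_ref"].mean() - both[f"{p}_dev"].mean())
    return CalibrationOffset(offsets, "device-one-point", lo)


def apply_device_calibration(
    device_segments: pd.DataFrame, offset: CalibrationOffset
) -> pd.DataFrame:
    """Apply the one-point offset to a device segment table.

    Guards idempotence: a table that was already calibrated once is
    rejected (the device offset is computed exactly once per subject).
    """
    if offset.source != "device-one-point":
        raise ValueError("expected a device-one-point offset")
    if device_segments.attrs.get("one_point_calibrated", False):
        raise RuntimeError(
            "device segments were already one-point calibrated; "
            "the offset is never recomputed or reapplied"
        )
    out = device_segments.copy()
    for p, v in offset.offsets.items():
        if p in out.columns:
            out[p] = out[p] + v
    out.attrs["one_point_calibrated"] = True
    return out
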