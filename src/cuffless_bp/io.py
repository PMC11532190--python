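"""Columnar on-disk dialect for synthetic cohorts.

One directory per subject; per session (``<activity>_d<day>``) the files

* ``*_waveform.csv`` — ``time_s, pressure_mmhg``
* ``*_r_peaks.csv`` — ``time_s``
* ``*_truth.csv`` — ``beat_time_s, beat_end_s, sbp, dbp, map, hr``
* ``*_brachial.csv`` — ``time_s, sbp, dbp``
* ``*_features.csv`` — ``segment_start_s, <feature columns>, missing``
* ``*_device_error.csv`` — ``segment_start_s, sbp, dbp, map``

plus a cohort-level ``manifest.yaml`` describing subjects, session specs and
sampling rates. All timestamps are seconds from the session start (0-based,
half-open windows).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beats import BeatSeries, WaveformRecord
from .calibration import BrachialTriplet
from .synthetic import (
    SessionData,
    SessionSpec,
    SimulatedSubject,
    SubjectParams,
)

__all__ = ["write_cohort", "read_cohort"]


def _tag(sess: SessionData) -> str:
    return f"{sess.activity}_d{sess.day}"


def write_cohort(cohort: list[SimulatedSubject], outdir) -> Path:
    """Write a simulated cohort to ``outdir`` (created if needed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for subj in cohort:
        sdir = outdir / subj.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {
            "subject_id": subj.subject_id,
            "has_day2": bool(subj.has_day2),
            "subject_effect": [float(x) for x in subj.subject_effect],
            "params": {
                "sbp0": subj.params.sbp0,
                "dbp0": subj.params.dbp0,
                "hr0": subj.params.hr0,
                "noise_sd": subj.params.noise_sd,
                "hr_noise_sd": subj.params.hr_noise_sd,
                "seed": subj.params.seed,
                "amplitudes": {
                    k: list(v) for k, v in subj.params.amplitudes.items()
                },
            },
            "sessions": [],
        }
        for sess in subj.sessions:
            tag = _tag(sess)
            wf = sess.waveform
            pd.DataFrame(
                {"time_s": wf.times(), "pressure_mmhg": wf.pressure}
            ).to_csv(sdir / f"{tag}_waveform.csv", index=False)
            pd.DataFrame({"time_s": wf.r_peaks}).to_csv(
                sdir / f"{tag}_r_peaks.csv", index=False
            )
            tr = sess.truth
            pd.DataFrame(
                {
                    "beat_time_s": tr.t_start,
                    "beat_end_s": tr.t_end,
                    "sbp": tr.sbp,
                    "dbp": tr.dbp,
                    "map": tr.map,
                    "hr": tr.hr,
                }
            ).to_csv(sdir / f"{tag}_truth.csv", index=False)
            br = sess.brachial
            pd.DataFrame(
                {"time_s": br.times, "sbp": br.sbp, "dbp": br.dbp}
            ).to_csv(sdir / f"{tag}_brachial.csv", index=False)
            sess.features.to_csv(sdir / f"{tag}_features.csv", index=False)
            sess.device_error.to_csv(
                sdir / f"{tag}_device_error.csv", index=False
            )
            entry["sessions"].append(
                {
                    "tag": tag,
                    "activity": sess.activity,
                    "day": sess.day,
                    "start_of_day_s": sess.start_of_day_s,
                    "fs": wf.fs,
                    "spec": {
                        "activity": sess.spec.activity,
                        "duration_s": sess.spec.duration_s,
                        "reps": sess.spec.reps,
                        "pause_s": sess.spec.pause_s,
                        "rest_s": sess.spec.rest_s,
                        "recovery_s": sess.spec.recovery_s,
                    },
                }
            )
        manifest["subjects"].append(entry)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def read_cohort(indir) -> list[SimulatedSubject]:
    """Load a cohort directory written by :func:`write_cohort`."""
    indir = Path(indir)
    with open(indir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    cohort: list[SimulatedSubject] = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        sdir = indir / sid
        p = entry["params"]
        params = SubjectParams(
            sid, p["sbp0"], p["dbp0"], p["hr0"],
            {k: tuple(v) for k, v in p["amplitudes"].items()},
            noise_sd=p["noise_sd"], hr_noise_sd=p["hr_noise_sd"],
            seed=p["seed"],
        )
        sessions = []
        for se in entry["sessions"]:
            tag = se["tag"]
            spec = SessionSpec(**se["spec"])
            wf_df = pd.read_csv(sdir / f"{tag}_waveform.csv")
            peaks = pd.read_csv(sdir / f"{tag}_r_peaks.csv")[
                "time_s"
            ].to_numpy()
            t = wf_df["time_s"].to_numpy()
            record = WaveformRecord(
                wf_df["pressure_mmhg"].to_numpy(), se["fs"], peaks,
                activity=se["activity"], subject_id=sid, day=se["day"],
                t0=float(t[0]) if t.size else 0.0,
            )
            tr_df = pd.read_csv(sdir / f"{tag}_truth.csv")
            truth = BeatSeries(
                tr_df["beat_time_s"].to_numpy(),
                tr_df["beat_end_s"].to_numpy(),
                tr_df["sbp"].to_numpy(),
                tr_df["dbp"].to_numpy(),
                tr_df["map"].to_numpy(),
                tr_df["hr"].to_numpy(),
                np.ones(len(tr_df), dtype=bool),
                se["activity"], sid, se["day"],
            )
            br_df = pd.read_csv(sdir / f"{tag}_brachial.csv")
            brachial = BrachialTriplet(
                br_df["time_s"].to_numpy(),
                br_df["sbp"].to_numpy(),
                br_df["dbp"].to_numpy(),
            )
            features = pd.read_csv(sdir / f"{tag}_features.csv")
            dev_err = pd.read_csv(sdir / f"{tag}_device_error.csv")
            sessions.append(
                SessionData(
                    se["activity"], se["day"], se["start_of_day_s"], spec,
                    record, truth, brachial, features, dev_err,
                )
            )
        cohort.append(
            SimulatedSubject(
                sid, params, sessions, entry["has_day2"],
                tuple(entry["subject_effect"]),
            )
        )
    return cohort
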