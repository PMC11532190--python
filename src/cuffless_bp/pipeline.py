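"""End-to-end pipeline: simulate → process → calibrate → train → evaluate.

A run is fully reproducible from a :class:`RunConfig` plus its seed: the
cohort simulation, fold split, pair selection and change-pair capping all
derive their randomness from it, and identical configs produce identical
report JSON.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import beats as bt
from . import calibration as cal
from . import evaluation as ev
from . import model as md
from . import synthetic as syn

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("cuffless_bp")

BP_PARAMS = bt.BP_PARAMS


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (serializable to YAML)."""

    seed: int = 0
    n_subjects: int = 38
    n_day2: int | None = None
    sampling_rate: float = 125.0
    mode: str = "strict"                   # "strict" | "paper"
    ridge_alpha: float = 1e-3

    # device error structure
    error_bias: tuple[float, float, float] = (0.3, 0.3, 0.3)
    error_subject_sd: tuple[float, float, float] = (6.0, 4.5, 5.5)
    error_segment_sd: tuple[float, float, float] = (6.0, 4.5, 5.5)
    error_drift_per_hour: tuple[float, float, float] = (0.0, 0.0, 0.0)
    error_day2_shift: tuple[float, float, float] = (2.0, 2.0, 2.0)
    feature_noise_scale: float = 1.0

    # physiological noise (None -> generator defaults)
    beat_noise_sd: float | None = None
    hr_noise_sd: float | None = None
    brachial_noise_sd: float | None = None
    session_offset_sd: float | None = None

    # evaluation
    accuracy_pairs_per_subject: int = 22
    stability_pairs_per_subject: int = 44
    change_cap_per_subject: int = 200
    anchor_len_s: float = 60.0

    # test-side artifact injection
    artifact_fraction: float = 0.0
    artifact_subjects: tuple[str, ...] = ()
    artifact_pattern: str = "mixed"

    def error_model(self) -> syn.DeviceErrorModel:
        return syn.DeviceErrorModel(
            bias=tuple(self.error_bias),
            subject_sd=tuple(self.error_subject_sd),
            segment_sd=tuple(self.error_segment_sd),
            drift_per_hour=tuple(self.error_drift_per_hour),
            day2_shift=tuple(self.error_day2_shift),
            feature_noise_sd=(
                syn.DEFAULT_FEATURE_NOISE_SD * self.feature_noise_scale
            ),
        )

    @classmethod
    def zero_error(cls, **kw) -> "RunConfig":
        """The noiseless limiting configuration: exact device, no noise."""
        z = (0.0, 0.0, 0.0)
        return cls(
            error_bias=z, error_subject_sd=z, error_segment_sd=z,
            error_drift_per_hour=z, error_day2_shift=z,
            feature_noise_scale=0.0, beat_noise_sd=0.0, hr_noise_sd=0.0,
            brachial_noise_sd=0.0, session_offset_sd=0.0, **kw,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class PipelineResult:
    config: RunConfig
    report: ev.CriteriaReport
    segments: pd.DataFrame                 # per-window ref_* / dev_* table
    accuracy_pairs: dict[str, pd.DataFrame]
    stability: dict[str, ev.AgreementResult] | None
    change_table: pd.DataFrame
    bland_altman: dict[str, ev.BlandAltmanResult]
    icc: dict[str, ev.ICCResult]
    within_change: pd.DataFrame            # per subject x param x scope
    excluded: dict[str, bt.ExclusionDecision]
    calibration_log: list[dict]
    stage_log: list[str] = field(default_factory=list)


def _session_tag(activity: str, day: int) -> str:
    return f"{activity}" if day == 1 else f"{activity}_day2"


def _process_cohort(cohort, cfg: RunConfig, stage_log, excluded, calibration_log):
    """Filter, beat-extract, segment and reference-calibrate every subject.

    Returns the long segment table with reference values and features.
    """
    rows = []
    for subj in cohort:
        processed = []
        n_removed = n_total = 0
        for sess in subj.sessions:
            wf = sess.waveform
            if (
                cfg.artifact_fraction > 0
                and subj.subject_id in cfg.artifact_subjects
            ):
                wf = syn.inject_artifacts(
                    wf, cfg.artifact_fraction, cfg.artifact_pattern,
                    seed=cfg.seed + 7,
                )
            mask = bt.filter_artifacts(wf)
            raw_beats = bt.process_record(wf, sample_mask=mask)
            seg_raw = bt.aggregate_segments(raw_beats, sess.spec.total_duration)
            n_removed += int(seg_raw["missing"].sum())
            n_total += len(seg_raw)
            processed.append((sess, raw_beats))
        decision = bt.subject_exclusion(n_removed, n_total)
        if decision.excluded:
            excluded[subj.subject_id] = decision
            stage_log.append(
                f"process: excluded {subj.subject_id}: {decision.reason} "
                f"({decision.removed_fraction:.0%} of segments removed)"
            )
            continue
        try:
            for sess, raw_beats in processed:
                beats_c, offset = cal.calibrate_reference_beats(
                    raw_beats, sess.brachial, (0.0, sess.spec.rest_s)
                )
                calibration_log.append(
                    {
                        "subject": subj.subject_id,
                        "session": _session_tag(sess.activity, sess.day),
                        "kind": offset.source,
                        "offset_mmhg": offset.offsets["sbp"],
                        "brachial_sbp": cal.brachial_calibration_value(
                            sess.brachial
                        ),
                    }
                )
                seg = bt.aggregate_segments(beats_c, sess.spec.total_duration)
                # removed (missing) reference windows carry no values downstream
                seg.loc[seg["missing"], ["sbp", "dbp", "map", "hr"]] = np.nan
                feat = sess.features
                merged = seg.merge(
                    feat, left_on="window_start_s", right_on="segment_start_s",
                    how="left", suffixes=("", "_feat"),
                )
                frame = pd.DataFrame(
                    {
                        "subject_id": subj.subject_id,
                        "day": sess.day,
                        "session": sess.activity,
                        "window_start_s": merged["window_start_s"],
                        "rest_s": sess.spec.rest_s,
                        "first_session": sess is subj.sessions[0],
                        "ref_sbp": merged["sbp"],
                        "ref_dbp": merged["dbp"],
                        "ref_map": merged["map"],
                        "ref_hr": merged["hr"],
                        "ref_missing": merged["missing"].astype(bool),
                    }
                )
                for fn in syn.FEATURE_NAMES:
                    frame[fn] = merged.get(fn, np.nan)
                rows.append(frame)
        except ValueError as exc:
            excluded[subj.subject_id] = bt.ExclusionDecision(
                True, np.nan, f"uncalibratable: {exc}"
            )
            stage_log.append(
                f"calibrate: excluded {subj.subject_id}: {exc}"
            )
    table = (
        pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    )
    stage_log.append(
        f"process: {table['subject_id'].nunique() if len(table) else 0} "
        f"subjects retained, {len(excluded)} excluded"
    )
    return table


def _predict_device(table: pd.DataFrame, cfg: RunConfig, stage_log):
    """Train the per-parameter ensembles on day-1 data and predict all rows."""
    feature_cols = list(syn.FEATURE_NAMES)
    train_tab = table[table["day"] == 1].rename(
        columns={f"ref_{p}": p for p in BP_PARAMS}
    )
    split = md.subject_kfold_split(
        sorted(train_tab["subject_id"].unique()), k=3, seed=cfg.seed
    )
    ensembles = md.train_ensembles(
        train_tab, targets=BP_PARAMS, split=split, alpha=cfg.ridge_alpha
    )
    out = table.copy()
    for p in BP_PARAMS:
        out[f"dev_{p}"] = md.predict(
            ensembles[p], table, mode=cfg.mode, subject_ids=table["subject_id"]
        )
    fold_sizes = [len(split.subjects_in(m)) for m in range(split.k)]
    stage_log.append(
        f"train: 3-fold subject split sizes {fold_sizes}, mode={cfg.mode}, "
        f"{len(train_tab)} training segments"
    )
    return out, ensembles


def _one_point_calibrate(table: pd.DataFrame, cfg: RunConfig, stage_log,
                         excluded, calibration_log) -> pd.DataFrame:
    """Per subject, anchor the device to the reference once and apply the
    offset to all of that subject's segments on all days."""
    out = []
    for sid, grp in table.groupby("subject_id", sort=True):
        first = grp[grp["first_session"]]
        rest_s = float(first["rest_s"].iloc[0])
        anchor = (rest_s - cfg.anchor_len_s, rest_s)
        dev = first[["window_start_s"] + [f"dev_{p}" for p in BP_PARAMS]]
        dev = dev.rename(columns={f"dev_{p}": p for p in BP_PARAMS})
        ref = first[["window_start_s"] + [f"ref_{p}" for p in BP_PARAMS]]
        ref = ref.rename(columns={f"ref_{p}": p for p in BP_PARAMS})
        try:
            offset = cal.calibrate_device_once(dev, ref, anchor_window=anchor)
        except ValueError as exc:
            excluded[sid] = bt.ExclusionDecision(True, np.nan, str(exc))
            stage_log.append(f"calibrate: excluded {sid}: {exc}")
            continue
        g = grp.copy()
        for p in BP_PARAMS:
            g[f"dev_{p}"] = g[f"dev_{p}"] + offset.offsets[p]
        calibration_log.append(
            {
                "subject": sid,
                "session": "initial_rest",
                "kind": offset.source,
                "offsets_mmhg": dict(offset.offsets),
                "anchor_window_s": list(anchor),
            }
        )
        out.append(g)
    if not out:
        raise RuntimeError("evaluate: no calibratable subjects remain")
    return pd.concat(out, ignore_index=True)


def _param_pairs(table: pd.DataFrame, p: str) -> pd.DataFrame:
    cols = {
        "subject_id": table["subject_id"],
        "day": table["day"],
        "session": table["session"],
        "window_start_s": table["window_start_s"],
        "reference": table[f"ref_{p}"],
        "device": table[f"dev_{p}"],
    }
    df = pd.DataFrame(cols).dropna(subset=["reference", "device"])
    return df.reset_index(drop=True)


def run_pipeline(cfg: RunConfig, cohort=None) -> PipelineResult:
    """Execute the full evaluation pipeline under one configuration.

    ``cohort`` may be a pre-built (or disk-loaded) list of simulated
    subjects; by default one is generated from the config.
    """
    stage_log: list[str] = []
    excluded: dict[str, bt.ExclusionDecision] = {}
    calibration_log: list[dict] = []

    if cohort is None:
        kw = {}
        for name in ("beat_noise_sd", "hr_noise_sd", "brachial_noise_sd",
                     "session_offset_sd"):
            v = getattr(cfg, name)
            if v is not None:
                kw[name] = v
        cohort = syn.simulate_cohort(
            n_subjects=cfg.n_subjects,
            error_model=cfg.error_model(),
            seed=cfg.seed,
            n_day2=cfg.n_day2,
            sampling_rate=cfg.sampling_rate,
            **kw,
        )
    stage_log.append(
        f"simulate: {len(cohort)} subjects, "
        f"{sum(s.has_day2 for s in cohort)} with a day-2 session"
    )

    table = _process_cohort(cohort, cfg, stage_log, excluded, calibration_log)
    if table.empty:
        raise RuntimeError("process: all subjects excluded")
    table, _ = _predict_device(table, cfg, stage_log)
    table = _one_point_calibrate(
        table, cfg, stage_log, excluded, calibration_log
    )

    # ---- evaluation ----------------------------------------------------
    accuracy: dict[str, ev.AgreementResult] = {}
    icc_res: dict[str, ev.ICCResult] = {}
    ba: dict[str, ev.BlandAltmanResult] = {}
    acc_pairs: dict[str, pd.DataFrame] = {}
    day1 = table[table["day"] == 1]
    day2 = table[table["day"] == 2]
    for k, p in enumerate(BP_PARAMS):
        pairs = _param_pairs(day1, p)
        sel = ev.select_pairs(
            pairs, cfg.accuracy_pairs_per_subject, seed=cfg.seed + k
        )
        acc_pairs[p] = sel
        accuracy[p] = ev.accuracy_statistic(sel)
        icc_res[p] = ev.icc(
            (sel["device"] - sel["reference"]).to_numpy(),
            sel["subject_id"].to_numpy(),
        )
        ba[p] = ev.bland_altman(pairs)
    stage_log.append(
        "evaluate: accuracy over "
        + ", ".join(f"{p}:{r.n} pairs" for p, r in accuracy.items())
    )

    stability: dict[str, ev.AgreementResult] | None = None
    if len(day2):
        stability = {}
        for k, p in enumerate(BP_PARAMS):
            stability[p] = ev.stability_statistic(
                _param_pairs(day1, p), _param_pairs(day2, p),
                cfg.stability_pairs_per_subject, seed=cfg.seed + 10 + k,
            )
        stage_log.append(
            f"evaluate: stability over {stability['sbp'].n} pairs "
            f"({day2['subject_id'].nunique()} day-2 subjects)"
        )
    else:
        stage_log.append("evaluate: no day-2 subjects, stability skipped")

    seg_for_change = day1.rename(columns=str).copy()
    change_tab = ev.change_pairs(
        seg_for_change, cap_per_subject=cfg.change_cap_per_subject,
        seed=cfg.seed + 20,
    )
    change: dict[str, ev.ChangeResult] = {}
    for p in BP_PARAMS:
        rates = change_tab.loc[change_tab["param"] == p, "error_rate"]
        change[p] = ev.change_percentiles(rates.to_numpy())
    stage_log.append(
        "evaluate: change pairs "
        + ", ".join(f"{p}:{r.n}" for p, r in change.items())
    )

    wc_rows = []
    for sid, grp in table.groupby("subject_id", sort=True):
        for p in BP_PARAMS + ("hr",):
            res = ev.within_subject_change(grp, value_col=f"ref_{p}")
            for scope, val in res.items():
                wc_rows.append(
                    {"subject_id": sid, "param": p, "scope": scope,
                     "change_mmhg": val}
                )
    within_change = pd.DataFrame(wc_rows)

    report = ev.criteria_report(accuracy, stability, change)
    for line in stage_log:
        log.info(line)
    return PipelineResult(
        cfg, report, table, acc_pairs, stability, change_tab, ba, icc_res,
        within_change, excluded, calibration_log, stage_log,
    )
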