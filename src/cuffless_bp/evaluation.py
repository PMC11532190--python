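"""Agreement statistics in the style of ISO 81060-3.

Implements the three requirements against which a continuous cuffless
device is judged, plus the supporting statistics:

* **Accuracy** — pooled mean (SD) of device − reference over randomly
  selected paired 15-s segments; pass iff |mean| <= 6 mmHg and SD <= 10 mmHg.
* **Stability** — the same statistic over pairs drawn from the first day
  plus a later (day-2) session, with the original one-point calibration
  still in force; same bounds.
* **Change** — for within-activity intervals whose reference change exceeds
  the per-parameter minimum (15 mmHg SBP, 10 DBP, 12 MAP), the error rate
  |Δdev − Δref| / |Δref| x 100; pass iff the 50th percentile <= 25% and the
  85th percentile <= 50%.

Also: one-way random-effects ICC on per-pair differences, Bland-Altman bias
and 95% limits of agreement (with ±30 mmHg clamping for plotting only), and
the per-subject within-protocol BP range (max − min).

No claim of ISO 81060-3 conformity is made: these are the standard's
statistics applied to a laboratory protocol, not its validation procedure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACCURACY_BOUNDS",
    "CHANGE_BOUNDS",
    "CHANGE_THRESHOLDS",
    "AgreementResult",
    "ChangeResult",
    "BlandAltmanResult",
    "ICCResult",
    "CriteriaReport",
    "icc",
    "select_pairs",
    "accuracy_statistic",
    "stability_statistic",
    "change_pairs",
    "change_percentiles",
    "bland_altman",
    "bland_altman_plot",
    "within_subject_change",
    "criteria_report",
]

ACCURACY_BOUNDS = (6.0, 10.0)      # |mean| <=, SD <=
CHANGE_BOUNDS = (25.0, 50.0)       # p50 <=, p85 <=
CHANGE_THRESHOLDS = {"sbp": 15.0, "dbp": 10.0, "map": 12.0}
BA_CLAMP_MMHG = 30.0


@dataclass
class AgreementResult:
    """Pooled mean/SD of paired differences vs the 6 (10) mmHg bounds."""

    n: int
    mean: float
    sd: float
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        self.passed = (
            abs(self.mean) <= ACCURACY_BOUNDS[0] and self.sd <= ACCURACY_BOUNDS[1]
        )


@dataclass
class ChangeResult:
    """Percentiles of change error rate vs the 25% / 50% bounds."""

    n: int
    p50: float
    p85: float
    pass_p50: bool = field(init=False)
    pass_p85: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.p50 > self.p85 + 1e-9:
            raise ValueError("p50 cannot exceed p85")
        self.pass_p50 = self.p50 <= CHANGE_BOUNDS[0]
        self.pass_p85 = self.p85 <= CHANGE_BOUNDS[1]


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    n: int
    clamp_mmhg: float = BA_CLAMP_MMHG


@dataclass
class ICCResult:
    """One-way random-effects ICC(1,1) with its variance components.

    Negative estimates (within-subject variance exceeding between-subject)
    are reported as-is, per the note field.
    """

    icc: float
    var_between: float
    var_within: float
    n_subjects: int
    mean_repeats: float
    note: str = ""


def icc(values: np.ndarray, subjects: np.ndarray) -> ICCResult:
    """One-way random-effects ICC(1,1) via ANOVA variance components.

    ``values`` are per-pair differences, ``subjects`` the grouping labels.
    Requires at least two subjects with at least two repeats each (unbalanced
    groups use the standard k0 correction).
    """
    values = np.asarray(values, dtype=float)
    subjects = np.asarray(subjects)
    labels, inverse = np.unique(subjects, return_inverse=True)
    a = labels.size
    counts = np.bincount(inverse)
    if a < 2 or np.all(counts < 2):
        raise ValueError("ICC needs >= 2 subjects with >= 2 repeats")
    N = values.size
    grand = values.mean()
    group_means = np.bincount(inverse, weights=values) / counts
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[inverse]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    k0 = (N - np.sum(counts**2) / N) / (a - 1)
    est = (ms_between - ms_within) / (ms_between + (k0 - 1) * ms_within)
    var_within = ms_within
    var_between = max((ms_between - ms_within) / k0, 0.0)
    note = "negative estimate reported as-is" if est < 0 else ""
    return ICCResult(
        float(est), var_between, var_within, int(a), float(N / a), note
    )


def select_pairs(
    pairs: pd.DataFrame, n_per_subject: int, seed: int = 0
) -> pd.DataFrame:
    """Uniform per-subject sample of paired segments, without replacement.

    Draws exactly ``n_per_subject`` valid pairs from every subject (seeded),
    so the total is ``n_per_subject x n_subjects``; a subject with too few
    pairs raises an error naming it.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid, grp in pairs.groupby("subject_id", sort=True):
        if len(grp) < n_per_subject:
            raise ValueError(
                f"subject {sid} has only {len(grp)} valid pairs "
                f"(need {n_per_subject})"
            )
        take = rng.choice(len(grp), size=n_per_subject, replace=False)
        out.append(grp.iloc[np.sort(take)])
    return pd.concat(out, ignore_index=True)


def accuracy_statistic(pairs: pd.DataFrame) -> AgreementResult:
    """Pooled mean and sample SD (n−1) of device − reference differences."""
    d = (pairs["device"] - pairs["reference"]).to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    return AgreementResult(int(d.size), float(d.mean()), float(d.std(ddof=1)))


def stability_statistic(
    day1_pairs: pd.DataFrame,
    day2_pairs: pd.DataFrame,
    n_per_subject: int = 44,
    seed: int = 0,
) -> AgreementResult:
    """Accuracy statistic over day-1 + day-2 pairs of the day-2 subjects.

    Restricted to subjects present in the day-2 table (the 24-h wearers);
    each subject contributes ``n_per_subject`` pairs drawn uniformly from
    the union of its day-1 and day-2 valid pairs, with the original day-1
    one-point calibration still applied (the caller guarantees this).
    """
    day2_subjects = set(day2_pairs["subject_id"].unique())
    if not day2_subjects:
        raise ValueError("no subjects with a day-2 session")
    pool = pd.concat(
        [
            day1_pairs[day1_pairs["subject_id"].isin(day2_subjects)],
            day2_pairs,
        ],
        ignore_index=True,
    )
    return accuracy_statistic(select_pairs(pool, n_per_subject, seed))


def change_pairs(
    segments: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    params: tuple[str, ...] = ("sbp", "dbp", "map"),
    cap_per_subject: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-activity change intervals with their error rates.

    ``segments`` has one row per (subject, day, activity-session, window)
    with ``ref_<param>`` / ``dev_<param>`` columns. For every
    subject-session, all ordered window pairs (start < end) whose reference
    change satisfies |Δref| >= the per-parameter minimum are retained, the
    device change is computed over the same two windows and
    error rate = |Δdev − Δref| / |Δref| x 100. Per subject and parameter the
    candidate list is capped by a seeded subsample to bound combinatorics.
    """
    thresholds = thresholds or CHANGE_THRESHOLDS
    rng = np.random.default_rng(seed)
    rows = []
    for (sid, day, sess), grp in segments.groupby(
        ["subject_id", "day", "session"], sort=True
    ):
        for p in params:
            g = grp.dropna(subset=[f"ref_{p}", f"dev_{p}"])
            ref = g[f"ref_{p}"].to_numpy(dtype=float)
            dev = g[f"dev_{p}"].to_numpy(dtype=float)
            t = g["window_start_s"].to_numpy(dtype=float)
            n = ref.size
            if n < 2:
                continue
            i, j = np.triu_indices(n, k=1)
            dref = ref[j] - ref[i]
            keep = np.abs(dref) >= thresholds[p]
            if not keep.any():
                continue
            i, j, dref = i[keep], j[keep], dref[keep]
            ddev = dev[j] - dev[i]
            rate = np.abs(ddev - dref) / np.abs(dref) * 100.0
            sub = pd.DataFrame(
                {
                    "subject_id": sid,
                    "day": day,
                    "session": sess,
                    "param": p,
                    "t_start": t[i],
                    "t_end": t[j],
                    "delta_ref": dref,
                    "delta_dev": ddev,
                    "error_rate": rate,
                }
            )
            rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=[
                "subject_id", "day", "session", "param",
                "t_start", "t_end", "delta_ref", "delta_dev", "error_rate",
            ]
        )
    out = pd.concat(rows, ignore_index=True)
    if cap_per_subject:
        capped = []
        for (sid, p), grp in out.groupby(["subject_id", "param"], sort=True):
            if len(grp) > cap_per_subject:
                take = rng.choice(len(grp), cap_per_subject, replace=False)
                grp = grp.iloc[np.sort(take)]
            capped.append(grp)
        out = pd.concat(capped, ignore_index=True)
    return out


def change_percentiles(error_rates: np.ndarray) -> ChangeResult:
    """50th and 85th percentiles of the error rates (linear interpolation)."""
    r = np.asarray(error_rates, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no change pairs")
    p50, p85 = np.percentile(r, [50.0, 85.0], method="linear")
    return ChangeResult(int(r.size), float(p50), float(p85))


def bland_altman(pairs: pd.DataFrame) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of device − reference.

    LoA = bias ± 1.96 x SD of the differences, computed on the *unclamped*
    values; the ±30 mmHg clamp applies to plotting only.
    """
    d = (pairs["device"] - pairs["reference"]).to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, d.size)


def bland_altman_plot(pairs: pd.DataFrame, param: str = "sbp", path=None):
    """Bland-Altman figure; differences beyond ±30 mmHg are drawn at the
    bound (statistics remain unclamped). Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    mean = (pairs["device"] + pairs["reference"]) / 2.0
    diff = pairs["device"] - pairs["reference"]
    clamped = diff.clip(-res.clamp_mmhg, res.clamp_mmhg)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, clamped, s=6, alpha=0.4)
    ax.axhline(res.bias, color="red", lw=1)
    for y in (res.loa_lower, res.loa_upper):
        ax.axhline(np.clip(y, -res.clamp_mmhg, res.clamp_mmhg),
                   color="blue", lw=1, ls="--")
    ax.set_xlabel(f"mean of reference and device {param.upper()} (mmHg)")
    ax.set_ylabel("device − reference (mmHg)")
    ax.set_title(
        f"{param.upper()}: bias {res.bias:.2f} "
        f"[{res.loa_lower:.1f}, {res.loa_upper:.1f}] mmHg, n={res.n}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def within_subject_change(segments: pd.DataFrame, value_col: str = "ref_sbp") -> dict:
    """Max − min of a subject's reference segment values.

    Computed over all day-1 sessions together ("overall") and within each
    activity session separately; empty series yield NaN.
    """
    day1 = segments[segments["day"] == 1]
    out: dict[str, float] = {}
    vals = day1[value_col].dropna()
    out["overall"] = float(vals.max() - vals.min()) if len(vals) else float("nan")
    for sess, grp in day1.groupby("session", sort=True):
        v = grp[value_col].dropna()
        out[str(sess)] = float(v.max() - v.min()) if len(v) else float("nan")
    return out


@dataclass
class CriteriaReport:
    """Accuracy / Stability / Change per BP parameter, with pass/fail."""

    accuracy: dict[str, AgreementResult]
    stability: dict[str, AgreementResult] | None
    change: dict[str, ChangeResult]

    def passed(self) -> bool:
        ok = all(r.passed for r in self.accuracy.values())
        if self.stability is not None:
            ok &= all(r.passed for r in self.stability.values())
        ok &= all(
            r.pass_p50 and r.pass_p85 for r in self.change.values()
        )
        return ok

    def to_dict(self) -> dict:
        return {
            "accuracy": {k: asdict(v) for k, v in self.accuracy.items()},
            "stability": (
                {k: asdict(v) for k, v in self.stability.items()}
                if self.stability is not None
                else None
            ),
            "change": {k: asdict(v) for k, v in self.change.items()},
            "bounds": {
                "accuracy_mean": ACCURACY_BOUNDS[0],
                "accuracy_sd": ACCURACY_BOUNDS[1],
                "change_p50": CHANGE_BOUNDS[0],
                "change_p85": CHANGE_BOUNDS[1],
            },
            "all_passed": self.passed(),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        lines = [
            f"{'parameter':<6} {'Accuracy mean (SD)':<22} "
            f"{'Stability mean (SD)':<22} {'Change p50, p85 %':<20} verdicts"
        ]
        for p, acc in self.accuracy.items():
            st = self.stability.get(p) if self.stability else None
            ch = self.change.get(p)
            sts = f"{st.mean:.1f} ({st.sd:.1f})" if st else "-"
            chs = f"{ch.p50:.0f}, {ch.p85:.0f}" if ch else "-"
            verdict = [
                "acc:" + ("pass" if acc.passed else "FAIL"),
            ]
            if st:
                verdict.append("stab:" + ("pass" if st.passed else "FAIL"))
            if ch:
                verdict.append("p50:" + ("pass" if ch.pass_p50 else "FAIL"))
                verdict.append("p85:" + ("pass" if ch.pass_p85 else "FAIL"))
            lines.append(
                f"{p:<6} {acc.mean:.2f} ({acc.sd:.2f})".ljust(30)
                + f"{sts:<22} {chs:<20} " + " ".join(verdict)
            )
        return "\n".join(lines)


def criteria_report(
    accuracy: dict[str, AgreementResult],
    stability: dict[str, AgreementResult] | None,
    change: dict[str, ChangeResult],
) -> CriteriaReport:
    """Assemble the structured pass/fail report (bounds are inclusive)."""
    return CriteriaReport(accuracy, stability, change)
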