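"""PPG feature extraction and the subject-wise 3-fold regression ensemble.

The device-side BP estimate comes from a documented, open set of seven
per-segment pulse features (amplitude, half-amplitude width, rise and decay
time, maximum upstroke slope, a reflection-index surrogate, and segment HR)
fed to ridge-regularized linear regression. Subjects are split into three
disjoint folds; one model per fold-complement is trained for each BP
parameter, and the final estimate averages the three members.

Two evaluation modes exist:

* ``strict`` (default) — a subject's predictions come from the single member
  that never saw that subject's fold (no test-time leakage);
* ``paper`` — the averaged three-member ensemble predicts for everyone,
  which is in-sample with respect to the folds and therefore optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .synthetic import FEATURE_NAMES

__all__ = [
    "PulseFeatures",
    "FoldSplit",
    "ModelEnsemble",
    "extract_features",
    "subject_kfold_split",
    "train_ensemble",
    "train_ensembles",
    "predict",
]


@dataclass
class PulseFeatures:
    """Segment-mean pulse-wave features; ``usable`` is False for degenerate
    (e.g. constant) segments."""

    pulse_amplitude: float
    half_width_s: float
    rise_time_s: float
    decay_time_s: float
    max_slope: float
    reflection_index: float
    segment_hr: float
    usable: bool = True

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES])


def _time_above_level(x: np.ndarray, level: float, dt: float) -> float:
    """Total time the piecewise-linear signal spends at or above ``level``,
    with sub-sample interpolation at the crossings."""
    above = x >= level
    total = 0.0
    for i in range(x.size - 1):
        a, b = x[i], x[i + 1]
        if above[i] and above[i + 1]:
            total += dt
        elif above[i] != above[i + 1] and b != a:
            frac = (level - a) / (b - a)
            total += dt * (1.0 - frac) if above[i] else dt * frac
    return total


def _pulse_features(x: np.ndarray, fs: float) -> PulseFeatures | None:
    amp = float(x.max() - x.min())
    duration = x.size / fs
    if amp <= 1e-12 or x.size < 3:
        return None
    dt = 1.0 / fs
    i_peak = int(np.argmax(x))
    half = float(x.min() + amp / 2.0)
    width = _time_above_level(x, half, dt)
    rise = i_peak * dt
    decay = (x.size - 1 - i_peak) * dt
    slope = float(np.max(np.diff(x)) * fs)
    late = x[int(np.floor(0.6 * x.size)):]
    refl = float((late.max() - x.min()) / amp) if late.size else 0.0
    return PulseFeatures(amp, width, rise, decay, slope, refl, 60.0 / duration)


def extract_features(
    samples: np.ndarray, fs: float, pulse_bounds: list[tuple[int, int]]
) -> PulseFeatures:
    """Segment features averaged over its pulses.

    ``pulse_bounds`` are half-open sample-index windows, one per accepted
    pulse (e.g. from R-peak segmentation of a PPG-like waveform). A segment
    whose every pulse is degenerate (constant signal) is flagged unusable
    with NaN features.
    """
    if not pulse_bounds:
        raise ValueError("segment has no accepted pulses")
    samples = np.asarray(samples, dtype=float)
    rows = []
    for s, e in pulse_bounds:
        f = _pulse_features(samples[s:e], fs)
        if f is not None:
            rows.append(f.as_array())
    if not rows:
        nan = float("nan")
        return PulseFeatures(nan, nan, nan, nan, nan, nan, nan, usable=False)
    mean = np.mean(rows, axis=0)
    return PulseFeatures(*mean.tolist())


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldSplit:
    """Subject-disjoint assignment of each subject id to one of k folds."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]

    def subjects_in(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)


def subject_kfold_split(
    subject_ids: list[str], k: int = 3, seed: int = 0
) -> FoldSplit:
    """Seeded shuffle of subjects into k folds with sizes differing by <= 1."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold splitting")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: i % k for i, j in enumerate(order)}
    return FoldSplit(assignment, k)


# ---------------------------------------------------------------------------
# ensemble

@dataclass
class ModelEnsemble:
    """Three fitted linear models for one BP parameter.

    Member ``m`` was trained on the two folds excluding fold ``m``; the
    plain prediction is the arithmetic mean of the members, and the
    held-out prediction for a subject uses only its own fold's member.
    """

    param: str
    members: list[Ridge]
    split: FoldSplit
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.members) != self.split.k:
            raise ValueError("one member per fold is required")


def _design(features: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    return features[feature_names].to_numpy(dtype=float)


def train_ensemble(
    table: pd.DataFrame,
    target: str,
    split: FoldSplit,
    feature_names: list[str] | None = None,
    alpha: float = 1e-3,
) -> ModelEnsemble:
    """Fit the per-parameter ensemble from a training table.

    ``table`` holds one row per (subject, segment) with a ``subject_id``
    column, the feature columns and the calibrated-reference target column.
    Rows with any NaN among features or target are dropped. Member m is a
    ridge regression fitted on all subjects outside fold m.
    """
    feature_names = feature_names or list(FEATURE_NAMES)
    cols = feature_names + [target]
    clean = table.dropna(subset=cols)
    if clean.empty:
        raise ValueError(f"no usable training rows for target {target!r}")
    members = []
    for m in range(split.k):
        train = clean[clean["subject_id"].map(split.fold_of) != m]
        if train.empty:
            raise ValueError(f"fold complement {m} has no training rows")
        model = Ridge(alpha=alpha)
        model.fit(_design(train, feature_names), train[target].to_numpy())
        members.append(model)
    return ModelEnsemble(target, members, split, feature_names)


def train_ensembles(
    table: pd.DataFrame,
    targets: tuple[str, ...] = ("sbp", "dbp", "map"),
    split: FoldSplit | None = None,
    seed: int = 0,
    alpha: float = 1e-3,
) -> dict[str, ModelEnsemble]:
    """Separate ensembles for each BP parameter over a shared fold split."""
    if split is None:
        split = subject_kfold_split(
            sorted(table["subject_id"].unique()), seed=seed
        )
    return {
        t: train_ensemble(table, t, split, alpha=alpha) for t in targets
    }


def predict(
    ensemble: ModelEnsemble,
    features: pd.DataFrame,
    mode: str = "strict",
    subject_ids: pd.Series | None = None,
) -> np.ndarray:
    """Per-segment BP estimates.

    ``paper`` mode averages all members. ``strict`` mode requires
    ``subject_ids`` (aligned with ``features``) and uses, for each row, the
    member whose training excluded that subject's fold; unknown subjects
    fall back to the member average. Rows with missing features predict NaN.
    """
    X = _design(features, ensemble.feature_names)
    ok = np.isfinite(X).all(axis=1)
    out = np.full(X.shape[0], np.nan)
    if not ok.any():
        return out
    preds = np.column_stack([m.predict(X[ok]) for m in ensemble.members])
    if mode == "paper":
        out[ok] = preds.mean(axis=1)
        return out
    if mode != "strict":
        raise ValueError(f"unknown prediction mode {mode!r}")
    if subject_ids is None:
        raise ValueError("strict mode needs subject ids for fold lookup")
    sid = np.asarray(subject_ids)[ok]
    folds = np.array(
        [ensemble.split.assignment.get(s, -1) for s in sid]
    )
    vals = preds.mean(axis=1)
    for m in range(ensemble.split.k):
        vals = np.where(folds == m, preds[:, m], vals)
    out[ok] = vals
    return out
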