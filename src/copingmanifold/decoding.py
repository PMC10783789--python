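"""Balanced, cross-validated decoding of behavior from population activity.

Frame-by-frame decoding of context (baseline vs suspension), coping style
(struggle vs immobility) and speed, within and across conditions/days, with
circular-shift surrogate controls:

* binary tasks use class-balanced frame sets (all minority frames plus a
  random equal-size subset of the majority class) and report mean fold
  accuracy, so chance is 0.5 by construction;
* speed decoding uses ridge regression and reports the mean per-fold Pearson
  correlation between predicted and true speed;
* folds are contiguous temporal blocks by default (guards against
  autocorrelation leakage); every paired comparison (real vs surrogate,
  condition A vs B, day d vs d') reuses one fold-index template, recorded as
  a hash on the result;
* surrogates circularly rotate each neuron's trace by an independent random
  offset, preserving single-neuron marginals and autocorrelation while
  destroying trace-behavior timing.

Standardization is fit on training folds only (a config switch exposes the
global variant).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge, RidgeClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .config import AnalysisConfig
from .session import (BASELINE, IMMOBILITY, STRUGGLE, TS, RegistrationMap,
                      SessionRecording, repeatedly_identified)

logger = logging.getLogger("copingmanifold")


@dataclass
class DecodingResult:
    """Scores of one train->test decoding configuration."""

    task: str                     # context | coping | speed
    model: str
    train_condition: str
    test_condition: str
    fold_scores: np.ndarray
    surrogate_scores: np.ndarray | None = None
    n_frames: int = 0
    seed: int | None = None
    fold_hash: str = ""

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def surrogate_mean(self) -> float | None:
        if self.surrogate_scores is None or len(self.surrogate_scores) == 0:
            return None
        return float(np.mean(self.surrogate_scores))

    def to_dict(self) -> dict:
        return dict(task=self.task, model=self.model,
                    train_condition=self.train_condition,
                    test_condition=self.test_condition,
                    mean_score=self.mean_score,
                    fold_scores=[float(s) for s in self.fold_scores],
                    surrogate_mean=self.surrogate_mean,
                    surrogate_scores=None if self.surrogate_scores is None
                    else [float(s) for s in self.surrogate_scores],
                    n_frames=self.n_frames, seed=self.seed,
                    fold_hash=self.fold_hash)


def make_classifier(model: str, config: AnalysisConfig, task: str = "coping"):
    """The four classifiers of the study, with its regularization constants."""
    if model == "logistic":
        c = config.logistic_c_context if task == "context" else config.logistic_c_coping
        return LogisticRegression(C=c, max_iter=2000)
    if model == "svc":
        return LinearSVC(C=config.svc_c)
    if model == "ridge":
        return RidgeClassifier(alpha=config.ridge_alpha)
    if model == "gnb":
        return GaussianNB()
    raise ValueError(f"unknown model {model!r}")


def balance_binary(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices keeping all minority-class frames and an equal-size random
    subset of the majority class, sorted (temporal order preserved)."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    if len(idx_a) > len(idx_b):
        idx_a, idx_b = idx_b, idx_a
    keep_b = rng.choice(idx_b, size=len(idx_a), replace=False)
    return np.sort(np.concatenate([idx_a, keep_b]))


def circular_shift_surrogate(traces: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently rotate each neuron's trace by a random circular offset.

    Offsets are uniform in [1, n_frames - 1]; per-neuron marginals and
    (circular) autocovariance are preserved exactly.
    """
    traces = np.asarray(traces)
    n = traces.shape[-1]
    if n < 1:
        raise ValueError("need at least 1 frame")
    out = np.empty_like(traces)
    arr = np.atleast_2d(traces)
    o = np.atleast_2d(out)
    shifts = rng.integers(1, max(n, 2), size=arr.shape[0])
    for i, s in enumerate(shifts):
        o[i] = np.roll(arr[i], int(s))
    return out


def fold_indices(n: int, folds: int, contiguous: bool = True,
                 rng: np.random.Generator | None = None,
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index pairs over range(n): contiguous temporal blocks by
    default, or a seeded frame shuffle."""
    order = np.arange(n)
    if not contiguous:
        if rng is None:
            raise ValueError("shuffled folds need an rng")
        order = rng.permutation(n)
    bounds = np.linspace(0, n, folds + 1).astype(int)
    out = []
    for f in range(folds):
        test = order[bounds[f]:bounds[f + 1]]
        train = np.concatenate([order[: bounds[f]], order[bounds[f + 1]:]])
        out.append((np.sort(train), np.sort(test)))
    return out


def hash_folds(folds: list[tuple[np.ndarray, np.ndarray]]) -> str:
    h = hashlib.sha256()
    for train, test in folds:
        h.update(train.tobytes())
        h.update(b"|")
        h.update(test.tobytes())
    return h.hexdigest()[:16]


def _standardize(train: np.ndarray, test: np.ndarray,
                 global_fit: bool) -> tuple[np.ndarray, np.ndarray]:
    scaler = StandardScaler()
    if global_fit:
        scaler.fit(np.concatenate([train, test], axis=0))
        return scaler.transform(train), scaler.transform(test)
    scaler.fit(train)
    return scaler.transform(train), scaler.transform(test)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def cross_condition_decode(train_data: np.ndarray, train_target: np.ndarray,
                           test_data: np.ndarray, test_target: np.ndarray,
                           task: str, model: str = "logistic",
                           config: AnalysisConfig | None = None,
                           folds_ix: list[tuple[np.ndarray, np.ndarray]] | None = None,
                           train_condition: str = "", test_condition: str = "",
                           rng: np.random.Generator | None = None,
                           ) -> DecodingResult:
    """Fit on train-condition frames of each fold's training indices, score on
    test-condition frames of the fold's test indices.

    ``train_data`` and ``test_data`` are (n_frames, n_features) with equal
    frame counts so one fold-index template applies to both; the
    within-condition case (identical arrays) reduces exactly to plain
    cross-validated decoding.
    """
    config = config or AnalysisConfig()
    if train_data.shape[0] != test_data.shape[0]:
        raise ValueError("train and test conditions must have equal frame counts")
    n = train_data.shape[0]
    if folds_ix is None:
        folds_ix = fold_indices(n, config.folds, config.contiguous_folds, rng)
    scores = []
    for f, (tr, te) in enumerate(folds_ix):
        Xt, Xv = _standardize(train_data[tr], test_data[te], config.standardize_global)
        if task == "speed":
            est = Ridge(alpha=config.ridge_alpha)
            yv = test_target[te]
            if np.std(yv) == 0:
                warnings.warn(f"fold {f}: constant speed, skipped")
                continue
            est.fit(Xt, train_target[tr])
            scores.append(_pearson(est.predict(Xv), yv))
        else:
            if len(np.unique(train_target[tr])) < 2:
                raise ValueError(f"fold {f}: single class in training data")
            est = make_classifier(model, config, task)
            est.fit(Xt, train_target[tr])
            scores.append(float(np.mean(est.predict(Xv) == test_target[te])))
    return DecodingResult(task=task, model=model if task != "speed" else "ridge",
                          train_condition=train_condition,
                          test_condition=test_condition,
                          fold_scores=np.array(scores), n_frames=n,
                          fold_hash=hash_folds(folds_ix))


def decode_binary(X: np.ndarray, y: np.ndarray, task: str = "coping",
                  model: str = "logistic", config: AnalysisConfig | None = None,
                  folds_ix: list[tuple[np.ndarray, np.ndarray]] | None = None,
                  rng: np.random.Generator | None = None) -> DecodingResult:
    """Within-condition cross-validated classification on a balanced set."""
    return cross_condition_decode(X, y, X, y, task=task, model=model,
                                  config=config, folds_ix=folds_ix, rng=rng,
                                  train_condition="within", test_condition="within")


def decode_speed(X: np.ndarray, speed: np.ndarray,
                 config: AnalysisConfig | None = None,
                 folds_ix: list[tuple[np.ndarray, np.ndarray]] | None = None,
                 rng: np.random.Generator | None = None) -> DecodingResult:
    """Within-condition ridge decoding of speed (mean per-fold Pearson r)."""
    return cross_condition_decode(X, speed, X, speed, task="speed",
                                  config=config, folds_ix=folds_ix, rng=rng,
                                  train_condition="within", test_condition="within")


def decode_with_surrogates(X: np.ndarray, y: np.ndarray, task: str,
                           model: str = "logistic",
                           config: AnalysisConfig | None = None,
                           n_surrogates: int | None = None,
                           rng: np.random.Generator | None = None,
                           surrogate_source: tuple[np.ndarray, np.ndarray] | None = None,
                           ) -> DecodingResult:
    """Decode and attach a circular-shift surrogate score distribution.

    Each surrogate rotates every neuron independently in time *before* the
    train/test frames are extracted: ``surrogate_source`` supplies the full
    trace matrix (neurons x all frames) and the frame indices that produced
    ``X``; without it the rotation falls back to the supplied frame set.
    Real and surrogate runs share one fold-index template.
    """
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(0)
    n_surrogates = config.decode_surrogates if n_surrogates is None else n_surrogates
    folds_ix = fold_indices(X.shape[0], config.folds, config.contiguous_folds, rng)
    if task == "speed":
        real = decode_speed(X, y, config, folds_ix=folds_ix)
    else:
        real = decode_binary(X, y, task, model, config, folds_ix=folds_ix)
    surr = []
    for _ in range(n_surrogates):
        if surrogate_source is not None:
            full, frames = surrogate_source
            Xs = circular_shift_surrogate(full, rng)[:, frames].T
        else:
            Xs = circular_shift_surrogate(X.T, rng).T
        if task == "speed":
            r = decode_speed(Xs, y, config, folds_ix=folds_ix)
        else:
            r = decode_binary(Xs, y, task, model, config, folds_ix=folds_ix)
        surr.append(r.mean_score)
    real.surrogate_scores = np.array(surr)
    return real


# ---------------------------------------------------------------------------
# session-level tasks


def coping_frames_and_labels(session: SessionRecording,
                             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Balanced struggle/immobility frame indices and binary labels
    (ambiguous frames excluded; 1 = struggle)."""
    beh = session.behavior
    labeled = np.concatenate([beh.frames_of_coping(STRUGGLE),
                              beh.frames_of_coping(IMMOBILITY)])
    labeled = np.sort(labeled)
    y = (beh.coping[labeled] == STRUGGLE).astype(int)
    keep = balance_binary(y, rng)
    return labeled[keep], y[keep]


def decode_coping(session: SessionRecording, model: str = "logistic",
                  config: AnalysisConfig | None = None,
                  n_surrogates: int = 0,
                  rng: np.random.Generator | None = None) -> DecodingResult:
    """Balanced struggle-vs-immobility decoding for one session."""
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    frames, y = coping_frames_and_labels(session, rng)
    X = session.calcium.values[:, frames].T
    return decode_with_surrogates(X, y, "coping", model, config, n_surrogates, rng,
                                  surrogate_source=(session.calcium.values, frames))


def decode_context(session: SessionRecording, model: str = "logistic",
                   config: AnalysisConfig | None = None,
                   n_surrogates: int = 0,
                   rng: np.random.Generator | None = None) -> DecodingResult:
    """Balanced baseline-vs-suspension decoding for one session."""
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    y_all = session.behavior.context
    keep = balance_binary(y_all, rng)
    X = session.calcium.values[:, keep].T
    return decode_with_surrogates(X, y_all[keep], "context", model, config,
                                  n_surrogates, rng,
                                  surrogate_source=(session.calcium.values, keep))


def speed_condition_matrix(session: SessionRecording,
                           config: AnalysisConfig | None = None,
                           n_surrogates: int = 0,
                           rng: np.random.Generator | None = None,
                           ) -> dict[tuple[str, str], DecodingResult]:
    """All four train/test combinations of baseline and suspension speed.

    The baseline segment is truncated at the end to the suspension length so
    one fold template applies to both; surrogate controls are attached to the
    within-condition entries.
    """
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    beh = session.behavior
    base = beh.frames_of_context(BASELINE)
    ts = beh.frames_of_context(TS)
    n = min(len(base), len(ts))
    base, ts = base[:n], ts[:n]
    data = {"baseline": session.calcium.values[:, base].T,
            "TS": session.calcium.values[:, ts].T}
    target = {"baseline": beh.speed_mean[base], "TS": beh.speed_mean[ts]}
    folds_ix = fold_indices(n, config.folds, config.contiguous_folds, rng)
    out = {}
    for train in ("baseline", "TS"):
        for test in ("baseline", "TS"):
            res = cross_condition_decode(data[train], target[train],
                                         data[test], target[test],
                                         task="speed", config=config,
                                         folds_ix=folds_ix,
                                         train_condition=train, test_condition=test)
            if train == test and n_surrogates > 0:
                surr = []
                for _ in range(n_surrogates):
                    Xs = circular_shift_surrogate(data[train].T, rng).T
                    r = cross_condition_decode(Xs, target[train], Xs, target[test],
                                               task="speed", config=config,
                                               folds_ix=folds_ix)
                    surr.append(r.mean_score)
                res.surrogate_scores = np.array(surr)
            out[(train, test)] = res
    return out


def across_day_decode(sessions: list[SessionRecording], regmap: RegistrationMap,
                      task: str = "coping", model: str = "logistic",
                      config: AnalysisConfig | None = None,
                      n_surrogates: int = 0,
                      rng: np.random.Generator | None = None,
                      ) -> dict[int, DecodingResult]:
    """Train on day 1, test on every day, using repeatedly identified neurons.

    Rows are ordered by global id identically across days; per-day frame sets
    are balanced (binary task) and truncated to a common length so the same
    fold-index template applies to every day.  The train-day entry equals
    within-day decoding.
    """
    config = config or AnalysisConfig()
    rng = rng or np.random.default_rng(config.seed)
    days = [s.day for s in sessions]
    ids = repeatedly_identified(regmap, days)
    if not ids:
        raise ValueError("no repeatedly identified neurons")
    mats, targets = {}, {}
    for s in sessions:
        rows = regmap.local_rows(s.day, ids)
        if task == "coping":
            frames, y = coping_frames_and_labels(s, rng)
        elif task == "context":
            y_all = s.behavior.context
            frames = balance_binary(y_all, rng)
            y = y_all[frames]
        elif task == "speed":
            frames = s.behavior.frames_of_context(TS)
            y = s.behavior.speed_mean[frames]
        else:
            raise ValueError(f"unknown task {task!r}")
        mats[s.day] = s.calcium.values[np.ix_(rows, frames)].T
        targets[s.day] = y
    n = min(m.shape[0] for m in mats.values())
    for d in days:
        mats[d], targets[d] = mats[d][:n], targets[d][:n]
    folds_ix = fold_indices(n, config.folds, config.contiguous_folds, rng)
    train_day = days[0]
    out = {}
    for d in days:
        res = cross_condition_decode(mats[train_day], targets[train_day],
                                     mats[d], targets[d], task=task, model=model,
                                     config=config, folds_ix=folds_ix,
                                     train_condition=f"day{train_day}",
                                     test_condition=f"day{d}")
        if n_surrogates > 0:
            surr = []
            for _ in range(n_surrogates):
                Xs = circular_shift_surrogate(mats[train_day].T, rng).T
                Xt = circular_shift_surrogate(mats[d].T, rng).T
                r = cross_condition_decode(Xs, targets[train_day], Xt, targets[d],
                                           task=task, model=model, config=config,
                                           folds_ix=folds_ix)
                surr.append(r.mean_score)
            res.surrogate_scores = np.array(surr)
        out[d] = res
    return out
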