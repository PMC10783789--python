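"""Per-neuron tuning scores and classifications.

* Suspension selectivity: the session is min-max scaled to [0, 1] per neuron
  (baseline and suspension concatenated), and the score is
  ``(m_TS - m_base) / (m_TS + m_base)`` of the segment means -- -1 means
  activity only at baseline, +1 only under suspension.  A transient-based
  variant uses transient rates in the same ratio (the rate's time unit
  cancels).  Scores beyond +-0.2 classify a neuron as TS- or
  baseline-selective.
* Movement score: Pearson correlation between a neuron's trace and the
  animal's speed within one context; |r| > 0.2 classifies struggle- (r > 0)
  or immobility-tuned (r < 0) cells.
* Explained variance: out-of-fold EV of a single-variable linear regression
  of the trace on speed (contiguous 10-fold CV), with significance from
  circular-shift surrogates of the speed trace, and a population variant
  regressing on 50 random other neurons.
* Onset-lag analysis: event-triggered averages around coping onsets,
  cross-correlated with speed to estimate each tuned neuron's lead/lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .session import (BASELINE, IMMOBILITY, STRUGGLE, TS, RegistrationMap,
                      SessionRecording, repeatedly_identified)


@dataclass
class PethResult:
    """Onset-lag analysis output, one row per analyzed neuron."""

    table: pd.DataFrame           # neuron, coping_type, lag_s, peak_corr, significant, class
    responses: np.ndarray         # (n_analyzed, window frames) event-averaged traces
    grid_s: np.ndarray            # lag grid in seconds


def minmax_scale_rows(x: np.ndarray) -> np.ndarray:
    """Scale each row to [0, 1]; zero-range rows become NaN."""
    x = np.asarray(x, dtype=np.float64)
    lo = x.min(axis=-1, keepdims=True)
    rng = x.max(axis=-1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - lo) / rng
    out[np.broadcast_to(rng == 0, out.shape)] = np.nan
    return out


def ts_selectivity(baseline_seg: np.ndarray, ts_seg: np.ndarray,
                   mode: str = "raw") -> np.ndarray:
    """Suspension-selectivity score in [-1, 1] (NaN when undefined).

    ``mode='raw'``: the two segments are concatenated, min-max scaled per
    neuron, and the score is the difference over the sum of the segment
    means.  ``mode='transient'``: segments are boolean transient masks and
    the score uses transient rates directly.
    """
    b = np.atleast_2d(np.asarray(baseline_seg, dtype=np.float64))
    t = np.atleast_2d(np.asarray(ts_seg, dtype=np.float64))
    if b.shape[-1] == 0 or t.shape[-1] == 0:
        raise ValueError("both segments must be non-empty")
    if mode == "raw":
        both = minmax_scale_rows(np.concatenate([b, t], axis=-1))
        b, t = both[:, : b.shape[1]], both[:, b.shape[1]:]
    elif mode != "transient":
        raise ValueError(f"unknown mode {mode!r}")
    m_b = b.mean(axis=-1)
    m_t = t.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = (m_t - m_b) / (m_t + m_b)
    score = np.where(m_t + m_b == 0, np.nan, score)
    if np.asarray(baseline_seg).ndim == 1:
        return float(score[0])
    return score


def classify_selectivity(score: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """'baseline' below -threshold, 'TS' above +threshold, else 'none'.

    Boundary values are exclusive; missing scores classify as 'none'.
    """
    score = np.asarray(score, dtype=np.float64)
    out = np.full(score.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        out[score > threshold] = "TS"
        out[score < -threshold] = "baseline"
    return out.astype(str) if score.ndim else str(out[()])


def movement_score(speed: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Pearson r between speed and each trace row (NaN for constant input)."""
    speed = np.asarray(speed, dtype=np.float64)
    tr = np.atleast_2d(np.asarray(trace, dtype=np.float64))
    if tr.shape[-1] != len(speed):
        raise ValueError("speed and trace lengths differ")
    s = speed - speed.mean()
    s_sd = np.sqrt((s ** 2).sum())
    t = tr - tr.mean(axis=-1, keepdims=True)
    t_sd = np.sqrt((t ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (t @ s) / (t_sd * s_sd)
    r = np.where((t_sd == 0) | (s_sd == 0), np.nan, r)
    if np.asarray(trace).ndim == 1:
        return float(r[0])
    return r


def classify_movement(score: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    score = np.asarray(score, dtype=np.float64)
    out = np.full(score.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        out[score > threshold] = "struggle"
        out[score < -threshold] = "immobility"
    return out.astype(str) if score.ndim else str(out[()])


# ---------------------------------------------------------------------------
# cross-validated explained variance


def _contiguous_folds(n: int, folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    bounds = np.linspace(0, n, folds + 1).astype(int)
    idx = np.arange(n)
    out = []
    for f in range(folds):
        test = idx[bounds[f]:bounds[f + 1]]
        train = np.concatenate([idx[: bounds[f]], idx[bounds[f + 1]:]])
        out.append((train, test))
    return out


def _cv_ev_single(xs: np.ndarray, y: np.ndarray, folds: int) -> np.ndarray:
    """Out-of-fold EV of single-predictor OLS, vectorized over predictor rows.

    ``xs`` is (n_models, n_frames): each row is one candidate predictor
    (e.g. the true speed or one circularly shifted surrogate of it).
    Returns mean EV across folds per row; degenerate folds are skipped.
    """
    xs = np.atleast_2d(xs)
    n = xs.shape[1]
    evs = np.zeros((xs.shape[0], folds))
    valid = np.zeros((xs.shape[0], folds), dtype=bool)
    for f, (train, test) in enumerate(_contiguous_folds(n, folds)):
        xt, yt = xs[:, train], y[train]
        xv, yv = xs[:, test], y[test]
        sstot = ((yv - yv.mean()) ** 2).sum()
        if sstot == 0:
            warnings.warn(f"fold {f}: constant target, skipped")
            continue
        xm = xt.mean(axis=1, keepdims=True)
        ym = yt.mean()
        var = ((xt - xm) ** 2).mean(axis=1)
        cov = ((xt - xm) * (yt - ym)).mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(var > 0, cov / var, 0.0)
        intercept = ym - slope * xm[:, 0]
        pred = slope[:, None] * xv + intercept[:, None]
        sse = ((yv[None, :] - pred) ** 2).sum(axis=1)
        evs[:, f] = 1 - sse / sstot
        valid[:, f] = True
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_valid > 0, (evs * valid).sum(axis=1) / n_valid, np.nan)
    return out


def movement_ev(trace: np.ndarray, speed: np.ndarray, folds: int = 10) -> float:
    """Mean out-of-fold explained variance of trace ~ speed (may be < 0)."""
    trace = np.asarray(trace, dtype=np.float64)
    if len(trace) < folds:
        raise ValueError("need at least `folds` frames")
    return float(_cv_ev_single(np.asarray(speed)[None, :], trace, folds)[0])


def circular_shifts(n_frames: int, n_surrogates: int, frame_rate: float,
                    shift_range_s: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Uniform random circular offsets in +-[min, max] seconds, in frames."""
    lo = int(round(shift_range_s[0] * frame_rate))
    hi = int(round(shift_range_s[1] * frame_rate))
    if hi >= n_frames:
        raise ValueError("shift range exceeds trace length")
    mag = rng.integers(lo, hi + 1, size=n_surrogates)
    sign = rng.choice([-1, 1], size=n_surrogates)
    return mag * sign


def ev_significance(trace: np.ndarray, speed: np.ndarray,
                    n_surrogates: int = 1000,
                    shift_range_s: tuple[float, float] = (20.0, 120.0),
                    alpha_percentile: float = 95.0,
                    frame_rate: float = 20.0, folds: int = 10,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[bool, float, np.ndarray]:
    """Is trace ~ speed EV significant against circularly shifted speed?

    The speed trace is circularly shifted by a uniform random offset in
    +-[20 s, 120 s] per surrogate; significance requires the real EV to
    exceed the 95th percentile of the surrogate EVs.  Returns
    (significant, real EV, surrogate EVs).
    """
    rng = rng or np.random.default_rng(0)
    speed = np.asarray(speed, dtype=np.float64)
    shifts = circular_shifts(len(speed), n_surrogates, frame_rate, shift_range_s, rng)
    rows = np.empty((n_surrogates + 1, len(speed)))
    rows[0] = speed
    for i, s in enumerate(shifts):
        rows[i + 1] = np.roll(speed, s)
    evs = _cv_ev_single(rows, np.asarray(trace, dtype=np.float64), folds)
    real, surr = evs[0], evs[1:]
    return bool(real > np.percentile(surr, alpha_percentile)), float(real), surr


def population_ev(target: np.ndarray, others: np.ndarray, n_predictors: int = 50,
                  folds: int = 10, rng: np.random.Generator | None = None) -> float:
    """CV explained variance of a linear model on random other neurons."""
    from sklearn.linear_model import LinearRegression
    rng = rng or np.random.default_rng(0)
    others = np.atleast_2d(others)
    if others.shape[0] < n_predictors:
        raise ValueError(f"need >= {n_predictors} other neurons")
    pick = rng.choice(others.shape[0], size=n_predictors, replace=False)
    X = others[pick].T
    y = np.asarray(target, dtype=np.float64)
    evs = []
    for f, (train, test) in enumerate(_contiguous_folds(len(y), folds)):
        sstot = ((y[test] - y[test].mean()) ** 2).sum()
        if sstot == 0:
            warnings.warn(f"fold {f}: constant target, skipped")
            continue
        model = LinearRegression().fit(X[train], y[train])
        sse = ((y[test] - model.predict(X[test])) ** 2).sum()
        evs.append(1 - sse / sstot)
    return float(np.mean(evs))


# ---------------------------------------------------------------------------
# onset-lag (peri-event) analysis


def _event_average(trace: np.ndarray, onsets: np.ndarray, half: int) -> np.ndarray:
    """Per-event z-scored windows around onsets, averaged over events."""
    segs = []
    for t in onsets:
        seg = trace[t - half: t + half + 1].astype(np.float64)
        sd = seg.std()
        segs.append((seg - seg.mean()) / sd if sd > 0 else seg - seg.mean())
    return np.mean(segs, axis=0)


def _lagged_correlations(resp: np.ndarray, speed: np.ndarray, max_lag: int) -> np.ndarray:
    """Pearson r between resp(t) and speed(t - lag) over the overlap, per lag."""
    out = np.empty(2 * max_lag + 1)
    for i, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            a, b = resp[lag:], speed[: len(speed) - lag]
        else:
            a, b = resp[: len(resp) + lag], speed[-lag:]
        sa, sb = a.std(), b.std()
        out[i] = np.corrcoef(a, b)[0, 1] if sa > 0 and sb > 0 else 0.0
    return out


def peth_lag(traces: np.ndarray, coping: np.ndarray, speed: np.ndarray,
             movement_class: np.ndarray, frame_rate: float = 20.0,
             window_s: float = 0.5) -> PethResult:
    """Onset-lag analysis of struggle/immobility neurons around coping onsets.

    Struggle neurons are analyzed at struggle onsets, immobility neurons at
    immobility onsets.  Per event, the neuron trace and speed are z-scored
    over a +-0.5 s window and averaged over events; the averaged response is
    cross-correlated with the averaged speed and the lag is the argmax
    (struggle) or argmin (immobility) correlation.  Negative lag: activity
    precedes the behavioral change ('early'); positive: follows ('late').
    A lag is significant when its correlation deviates by more than 1 SD from
    the mean of the correlations of all analyzed neurons of that coping type.
    """
    half = int(round(window_s * frame_rate))
    n_frames = traces.shape[1]
    rows = []
    responses = []
    grid = np.arange(-half, half + 1) / frame_rate

    for code, cls_name, pick_max in ((STRUGGLE, "struggle", True),
                                     (IMMOBILITY, "immobility", False)):
        onsets = np.flatnonzero((coping[1:] == code) & (coping[:-1] != code)) + 1
        onsets = onsets[(onsets - half >= 0) & (onsets + half + 1 <= n_frames)]
        neurons = np.flatnonzero(np.asarray(movement_class) == cls_name)
        if len(onsets) == 0 or len(neurons) == 0:
            continue
        speed_avg = _event_average(speed, onsets, half)
        peaks, lags = [], []
        for nrn in neurons:
            resp = _event_average(traces[nrn], onsets, half)
            responses.append(resp)
            corr = _lagged_correlations(resp, speed_avg, half)
            best = int(np.argmax(corr) if pick_max else np.argmin(corr))
            peaks.append(corr[best])
            lags.append((best - half) / frame_rate)
        peaks = np.array(peaks)
        lags = np.array(lags)
        if len(neurons) < 2:
            sig = np.zeros(len(neurons), dtype=bool)
            flagged = True
        else:
            mu, sd = peaks.mean(), peaks.std()
            dev = (peaks - mu) / sd if sd > 0 else np.zeros_like(peaks)
            sig = dev > 1 if pick_max else dev < -1
            flagged = False
        for j, nrn in enumerate(neurons):
            cls = "none"
            if sig[j] and lags[j] < 0:
                cls = "early"
            elif sig[j] and lags[j] > 0:
                cls = "late"
            rows.append(dict(neuron=int(nrn), coping_type=cls_name,
                             lag_s=float(lags[j]), peak_corr=float(peaks[j]),
                             significant=bool(sig[j]), cls=cls,
                             degenerate=flagged))
    table = pd.DataFrame(rows, columns=["neuron", "coping_type", "lag_s",
                                        "peak_corr", "significant", "cls",
                                        "degenerate"])
    responses = np.array(responses) if responses else np.empty((0, 2 * half + 1))
    return PethResult(table=table, responses=responses, grid_s=grid)


# ---------------------------------------------------------------------------
# session-level driver


def score_session(session: SessionRecording, config: AnalysisConfig | None = None,
                  ) -> pd.DataFrame:
    """Compute the per-neuron tuning table for one session.

    Columns: ts_selectivity_raw, ts_selectivity_transient, selectivity_class,
    movement_score_baseline, movement_score_TS, movement_class.
    Explained-variance columns are produced separately (they are much more
    expensive) by :func:`movement_ev` / :func:`ev_significance`.
    """
    config = config or AnalysisConfig()
    beh = session.behavior
    base = beh.frames_of_context(BASELINE)
    ts = beh.frames_of_context(TS)
    values = session.calcium.values
    trans = session.calcium.transients

    sel_raw = ts_selectivity(values[:, base], values[:, ts], mode="raw")
    sel_tr = ts_selectivity(trans[:, base].astype(float),
                            trans[:, ts].astype(float), mode="transient")

    # movement score per context; coping-labeled frames only within suspension
    labeled_ts = np.union1d(beh.frames_of_coping(STRUGGLE),
                            beh.frames_of_coping(IMMOBILITY))
    ms_base = movement_score(beh.speed_mean[base], values[:, base])
    ms_ts = movement_score(beh.speed_mean[labeled_ts], values[:, labeled_ts])

    return pd.DataFrame({
        "neuron_id": session.calcium.neuron_ids,
        "ts_selectivity_raw": sel_raw,
        "ts_selectivity_transient": sel_tr,
        "selectivity_class": classify_selectivity(sel_raw, config.selectivity_threshold),
        "movement_score_baseline": ms_base,
        "movement_score_TS": ms_ts,
        "movement_class": classify_movement(ms_ts, config.movement_threshold),
    })


def selectivity_day_correlation(tables: dict[int, pd.DataFrame],
                                regmap: RegistrationMap, day_a: int, day_b: int,
                                column: str = "ts_selectivity_raw") -> float:
    """Pearson r of a per-neuron score between two days (registered cells)."""
    ids = repeatedly_identified(regmap, [day_a, day_b])
    if len(ids) < 3:
        return float("nan")
    rows_a = regmap.local_rows(day_a, ids)
    rows_b = regmap.local_rows(day_b, ids)
    a = tables[day_a][column].to_numpy()[rows_a]
    b = tables[day_b][column].to_numpy()[rows_b]
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
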