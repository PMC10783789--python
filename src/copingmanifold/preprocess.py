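"""Post-extraction trace conditioning.

Slow drifts are removed with a centered running 10th-percentile filter
(30 s window, truncated at the edges), traces are z-scored over the whole
session (baseline and suspension jointly, so the two contexts share one
scale), and a boolean transient mask marks frames whose frame-to-frame rise
exceeds ``k`` standard deviations of the trace.  Before manifold embedding,
traces are additionally smoothed with a 250 ms Gaussian kernel and
feature-scaled to [0, 1] with a per-neuron quantile transform.

All operations act per neuron and are independent across rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter1d
from sklearn.preprocessing import QuantileTransformer


@dataclass
class ScaledTraces:
    """Smoothed, quantile-scaled traces in [0, 1] (neurons x frames)."""

    values: np.ndarray
    sigma_s: float
    n_quantiles: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("scaled values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _as_2d(trace: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(trace, dtype=np.float64)
    if arr.ndim == 1:
        return arr[None, :], True
    return arr, False


def detrend_percentile(trace: np.ndarray, window_s: float = 30.0,
                       percentile: float = 10.0, frame_rate: float = 20.0) -> np.ndarray:
    """Subtract a centered running percentile from each trace.

    Edge windows are truncated to the available frames rather than padded, so
    the output has exactly the input length.
    """
    arr, squeeze = _as_2d(trace)
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace must be finite")
    n = arr.shape[1]
    half = int(round(window_s * frame_rate)) // 2
    if 2 * half + 1 < 2:
        raise ValueError("window must span at least 2 frames")
    w = min(2 * half + 1, n)
    out = np.empty_like(arr)
    # interior: full centered windows, vectorized per neuron
    win = sliding_window_view(arr, w, axis=1)  # (neurons, n - w + 1, w)
    interior = np.percentile(win, percentile, axis=2)
    lo = (w - 1) // 2
    out[:, lo:lo + interior.shape[1]] = arr[:, lo:lo + interior.shape[1]] - interior
    # truncated edges
    for t in range(lo):
        out[:, t] = arr[:, t] - np.percentile(arr[:, : t + half + 1], percentile, axis=1)
    for t in range(lo + interior.shape[1], n):
        out[:, t] = arr[:, t] - np.percentile(arr[:, t - half:], percentile, axis=1)
    return out[0] if squeeze else out


def zscore(trace: np.ndarray) -> np.ndarray:
    """Z-score each trace over all its frames (population SD, ddof=0)."""
    arr, squeeze = _as_2d(trace)
    sd = arr.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance trace(s) at row(s) {bad.tolist()}")
    out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    return out[0] if squeeze else out


def detect_transients(trace: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Boolean mask of frames whose rise from the previous frame exceeds k SD.

    The threshold is ``k`` times the SD of the (z-scored) trace itself; frame 0
    has no predecessor and is always False.  Mask length equals trace length.
    """
    arr, squeeze = _as_2d(trace)
    sd = arr.std(axis=1, keepdims=True)
    mask = np.zeros(arr.shape, dtype=bool)
    mask[:, 1:] = np.diff(arr, axis=1) > k * sd
    return mask[0] if squeeze else mask


def smooth_quantile_scale(traces: np.ndarray, frame_rate: float = 20.0,
                          sigma_s: float = 0.25, n_quantiles: int = 100) -> ScaledTraces:
    """Gaussian-smooth each trace, then map its empirical quantiles onto [0, 1].

    The quantile map is monotone, so within-neuron rank order is preserved;
    values beyond the fitted range clip to [0, 1].  Constant traces carry no
    rank information and are mapped to 0.5 with a warning.
    """
    arr, _ = _as_2d(traces)
    sigma = sigma_s * frame_rate
    if sigma > 0:
        smoothed = gaussian_filter1d(arr, sigma, axis=1, mode="reflect", truncate=4.0)
    else:
        smoothed = arr.copy()
    out = np.empty_like(smoothed)
    const = smoothed.std(axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant trace(s) mapped to 0.5")
        out[const] = 0.5
    live = ~const
    if live.any():
        nq = min(n_quantiles, smoothed.shape[1])
        qt = QuantileTransformer(n_quantiles=nq, output_distribution="uniform",
                                 subsample=None)
        out[live] = qt.fit_transform(smoothed[live].T).T
    return ScaledTraces(values=out, sigma_s=sigma_s, n_quantiles=n_quantiles)
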