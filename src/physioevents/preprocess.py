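"""Three-stage signal conditioning for wearable autonomic channels.

Each raw 15 Hz channel passes through, in order:

1. artifact flagging (zero-valued samples, or samples more than three
   standard deviations from the mean of the preceding second) followed by
   median-window interpolation of the flagged samples;
2. a non-overlapping 0.5 s moving-average filter, which downsamples every
   channel to 2 Hz;
3. a modality-specific smoother — a one-Euro adaptive low-pass for
   electrodermal activity, a first-order exponential decay for skin
   temperature, and a cubic smoothing spline (csaps p-convention) for
   heart rate.

All stages are causal or window-local, so the same chain could run in a
streaming setting even though this implementation processes complete
sessions in batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .io import PhysioRecording, ValidationError


@dataclass
class CleanSignals:
    """Preprocessed 2 Hz channels on a shared time axis."""

    t2: np.ndarray
    eda: np.ndarray
    temp: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        for name in ("eda", "temp", "hr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != self.t2.size:
                raise ValidationError(f"channel {name!r} length != t2 length")

    def __len__(self) -> int:
        return int(self.t2.size)

    @property
    def fs(self) -> float:
        return 2.0


@dataclass
class FilterConfig:
    """Stage parameters for the preprocessing chain.

    Median interpolation orders are window lengths in samples (centred,
    rounded up to odd). The heart-rate interpolation order is not separately
    specified anywhere and defaults to the temperature setting of 1.
    """

    median_order_eda: int = 75
    median_order_temp: int = 1
    median_order_hr: int = 1
    oneeuro_mincutoff: float = 50.0
    oneeuro_beta: float = 4.0
    oneeuro_dcutoff: float = 1.0
    expdecay_p: float = 0.95
    spline_p: float = 0.001
    ma_window_s: float = 0.5
    flag_lookback_s: float = 1.0
    flag_sd: float = 3.0

    def __post_init__(self) -> None:
        if min(self.median_order_eda, self.median_order_temp, self.median_order_hr) < 1:
            raise ValidationError("median filter orders must be >= 1")
        for p in (self.expdecay_p, self.spline_p):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("smoothing parameters must lie in [0, 1]")
        if self.ma_window_s <= 0:
            raise ValidationError("moving-average window must be positive")


# ---------------------------------------------------------------------------
# Stage 1: artifact flagging and median interpolation


def flag_artifacts(
    x: np.ndarray,
    t: np.ndarray,
    lookback_s: float = 1.0,
    n_sd: float = 3.0,
) -> np.ndarray:
    """Mark hardware-error samples.

    A sample is flagged when its value is exactly zero, or when it deviates
    from the mean of the preceding second of samples by more than ``n_sd``
    standard deviations. Within the first second the available preceding
    samples are used (at least two are required; earlier samples are never
    flagged by the deviation rule). A zero-variance preceding window
    disables the deviation rule for that sample.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot flag artifacts on an empty series")
    if x.size != t.size:
        raise ValidationError("series and time axis lengths differ")

    mask = x == 0.0
    if x.size < 3:
        return mask

    dt = float(np.median(np.diff(t)))
    w = max(int(round(lookback_s / dt)), 1)
    s = pd.Series(x)
    prev = s.shift(1)
    mean = prev.rolling(w, min_periods=2).mean().to_numpy()
    sd = prev.rolling(w, min_periods=2).std(ddof=1).to_numpy()
    with np.errstate(invalid="ignore"):
        dev = np.abs(x - mean) > n_sd * sd
    dev &= np.isfinite(sd) & (sd > 0)
    return mask | dev


def interpolate_median(x: np.ndarray, mask: np.ndarray, order: int) -> np.ndarray:
    """Replace flagged samples by the median of unflagged neighbours.

    The window is centred with length ``order`` samples (even orders rounded
    up to the next odd number). If a run of flagged samples exhausts the
    window, the nearest unflagged neighbour's value is used instead.
    """
    x = np.asarray(x, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if order < 1:
        raise ValidationError("median filter order must be >= 1")
    if mask.all():
        raise ValidationError("all samples flagged; nothing to interpolate from")
    if not mask.any():
        return x.copy()

    if order % 2 == 0:
        order += 1
    half = order // 2
    out = x.copy()
    good_idx = np.flatnonzero(~mask)
    for i in np.flatnonzero(mask):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        window = x[lo:hi][~mask[lo:hi]]
        if window.size:
            out[i] = np.median(window)
        else:
            # run longer than the window: fall back to nearest clean sample
            j = good_idx[np.argmin(np.abs(good_idx - i))]
            out[i] = x[j]
    return out


# ---------------------------------------------------------------------------
# Stage 2: moving-average downsampling


def downsample_movavg(
    x: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    t: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping moving average; returns ``(t_out, y_out)``.

    Output sample ``k`` is the mean of the raw samples whose start times fall
    in ``[k·window_s, (k+1)·window_s)``; a trailing partial window is
    dropped. Windows are delimited by time, so a non-integer ``fs·window_s``
    (7.5 samples at the nominal 15 Hz) alternates window sample counts
    without accumulating drift. The output rate is ``1/window_s`` (2 Hz at
    the default).
    """
    x = np.asarray(x, dtype=float)
    nper = fs * window_s
    if nper < 1:
        raise ValidationError("fs * window_s must be >= 1 sample")
    nout = int(np.floor(x.size / nper + 1e-9))
    t0 = float(t[0]) if t is not None and len(t) else 0.0
    if nout == 0:
        warnings.warn("input shorter than one window; empty output", stacklevel=2)
        return np.empty(0), np.empty(0)
    win = np.floor(np.arange(x.size) / nper).astype(int)
    keep = win < nout
    sums = np.bincount(win[keep], weights=x[keep], minlength=nout)
    counts = np.bincount(win[keep], minlength=nout)
    y = sums / counts
    t_out = t0 + np.arange(nout) * window_s
    return t_out, y


# ---------------------------------------------------------------------------
# Stage 3: modality-specific filters


def _lowpass_alpha(cutoff_hz: float, period_s: float) -> float:
    tau = 1.0 / (2.0 * math.pi * cutoff_hz)
    return 1.0 / (1.0 + tau / period_s)


def one_euro(
    x: np.ndarray,
    mincutoff: float = 50.0,
    beta: float = 4.0,
    rate_hz: float = 2.0,
    dcutoff: float = 1.0,
) -> np.ndarray:
    """Speed-adaptive exponential low-pass (the one-Euro filter).

    The effective cutoff at step ``k`` is ``mincutoff + beta·|dx̂|`` where
    ``dx̂`` is the low-passed signal derivative (its own cutoff fixed at
    ``dcutoff``): slow drifts are smoothed hard, fast transitions pass with
    little lag, which minimises both jitter and lag in the electrodermal
    channel.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("one_euro requires a non-empty series")
    te = 1.0 / rate_hz
    a_d = _lowpass_alpha(dcutoff, te)
    y = np.empty_like(x)
    y[0] = x[0]
    dx_hat = 0.0
    for k in range(1, x.size):
        dx = (x[k] - y[k - 1]) * rate_hz
        dx_hat = a_d * dx + (1.0 - a_d) * dx_hat
        cutoff = mincutoff + beta * abs(dx_hat)
        a = _lowpass_alpha(cutoff, te)
        y[k] = a * x[k] + (1.0 - a) * y[k - 1]
    return y


def exp_decay(x: np.ndarray, p: float = 0.95) -> np.ndarray:
    """First-order exponential smoother ``y[k] = p·y[k−1] + (1−p)·x[k]``."""
    x = np.asarray(x, dtype=float)
    if not 0.0 <= p <= 1.0:
        raise ValidationError("smoothing parameter p must lie in [0, 1]")
    if x.size == 0:
        return x.copy()
    y = np.empty_like(x)
    y[0] = x[0]
    for k in range(1, x.size):
        y[k] = p * y[k - 1] + (1.0 - p) * x[k]
    return y


def smooth_spline(x: np.ndarray, t2: np.ndarray, p: float = 0.001) -> np.ndarray:
    """Cubic smoothing spline in the csaps p-convention, evaluated at the knots.

    Minimises ``p·Σ(y−x)² + (1−p)·∫(y″)²``. ``p = 1`` interpolates, ``p = 0``
    degenerates to the least-squares straight line. Solved with the Reinsch
    banded system on the natural-spline basis; fitted values at the input
    knots are returned.
    """
    x = np.asarray(x, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError("smooth_spline requires at least 4 samples")
    if not 0.0 <= p <= 1.0:
        raise ValidationError("smoothing parameter p must lie in [0, 1]")
    if p == 1.0:
        return x.copy()
    if p == 0.0:
        coef = np.polyfit(t2, x, 1)
        return np.polyval(coef, t2)

    lam = (1.0 - p) / p
    h = np.diff(t2)
    m = n - 2
    # R (m x m, symmetric tridiagonal) and Q^T (m x n, tri-banded):
    # penalty = g' R g with g the interior second derivatives; Q^T maps
    # fitted values to second differences scaled by the knot spacings.
    r_main = (h[:-1] + h[1:]) / 3.0
    r_off = h[1:-1] / 6.0
    inv_h = 1.0 / h
    # rows of Q^T: [1/h_i, -1/h_i - 1/h_{i+1}, 1/h_{i+1}] at columns i, i+1, i+2
    # Build A = R + lam * Q^T Q as a pentadiagonal banded matrix.
    d0 = r_main + lam * (inv_h[:-1] ** 2 + (inv_h[:-1] + inv_h[1:]) ** 2 + inv_h[1:] ** 2)
    d1 = np.zeros(m - 1)
    if m > 1:
        d1 = r_off + lam * (
            -inv_h[1:-1] * (inv_h[:-2] + inv_h[1:-1]) - inv_h[1:-1] * (inv_h[1:-1] + inv_h[2:])
        )
    d2 = np.zeros(max(m - 2, 0))
    if m > 2:
        d2 = lam * inv_h[1:-2] * inv_h[2:-1]

    ab = np.zeros((5, m))
    ab[0, 2:] = d2
    ab[1, 1:] = d1
    ab[2, :] = d0
    ab[3, :-1] = d1
    ab[4, :-2] = d2

    # Q^T x: second divided differences of the data
    qtx = x[:-2] * inv_h[:-1] - x[1:-1] * (inv_h[:-1] + inv_h[1:]) + x[2:] * inv_h[1:]
    gamma = solve_banded((2, 2), ab, qtx)

    # fitted = x - lam * Q gamma
    qg = np.zeros(n)
    qg[:-2] += gamma * inv_h[:-1]
    qg[1:-1] -= gamma * (inv_h[:-1] + inv_h[1:])
    qg[2:] += gamma * inv_h[1:]
    return x - lam * qg


# ---------------------------------------------------------------------------
# Full chain


def preprocess(rec: PhysioRecording, cfg: FilterConfig | None = None) -> CleanSignals:
    """Run the full three-stage chain on all three channels."""
    cfg = cfg or FilterConfig()

    def stage12(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
        mask = flag_artifacts(x, rec.t, cfg.flag_lookback_s, cfg.flag_sd)
        repaired = interpolate_median(x, mask, order)
        return downsample_movavg(repaired, rec.fs, cfg.ma_window_s, rec.t)

    t2, eda = stage12(rec.eda, cfg.median_order_eda)
    _, temp = stage12(rec.temp, cfg.median_order_temp)
    _, hr = stage12(rec.hr, cfg.median_order_hr)

    rate = 1.0 / cfg.ma_window_s
    eda = one_euro(eda, cfg.oneeuro_mincutoff, cfg.oneeuro_beta, rate, cfg.oneeuro_dcutoff)
    temp = exp_decay(temp, cfg.expdecay_p)
    if hr.size >= 4:
        hr = smooth_spline(hr, t2, cfg.spline_p)
    return CleanSignals(t2=t2, eda=eda, temp=temp, hr=hr)
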