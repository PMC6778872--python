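"""Signal-quality scoring for the 2 Hz preprocessed channels.

Each 0.5 s step receives a quality index in [0, 1]: 1 when the reading is
physiologically plausible, lower scores when rule-based evidence of sensor
contamination fires (implausible rate of change, frozen readings, values
outside the physiological range). Rules look back over trailing windows;
when several fire at the same step the minimum score wins. After a session
completes, the per-channel scores are binarised against their session mean
minus one standard deviation to give the validity mask consumed by the
event detector.

No heart-rate quality rules exist; the validity mask uses only the
electrodermal and temperature scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ValidationError

#: every score a rule can assign, plus the clean value 1
REACHABLE_SCORES = (0.0, 0.1, 0.4, 0.5, 0.65, 1.0)


@dataclass
class SQIRules:
    """Rule thresholds and the scores they assign.

    EDA rules: a consecutive-sample change above 3 µS anywhere in the
    trailing 15 s window scores 0.4; a flat trailing 25 s window (all
    consecutive changes ≤ 0.001 µS) scores 0.1; values ≤ 0.02 µS or > 30 µS
    score 0 and values > 20 µS score 0.65. Temperature rules: a flat
    trailing 25 s window (changes ≤ 0.0001 °C) or a value below 15 °C
    scores 0.5.
    """

    eda_deriv_window_s: float = 15.0
    eda_deriv_thresh_us: float = 3.0
    eda_deriv_score: float = 0.4
    eda_flat_window_s: float = 25.0
    eda_flat_eps_us: float = 0.001
    eda_flat_score: float = 0.1
    eda_low_us: float = 0.02
    eda_low_score: float = 0.0
    eda_high1_us: float = 20.0
    eda_high1_score: float = 0.65
    eda_high2_us: float = 30.0
    eda_high2_score: float = 0.0
    temp_flat_window_s: float = 25.0
    temp_flat_eps_c: float = 0.0001
    temp_flat_score: float = 0.5
    temp_low_c: float = 15.0
    temp_low_score: float = 0.5
    step_s: float = 0.5

    def __post_init__(self) -> None:
        if min(self.eda_deriv_window_s, self.eda_flat_window_s, self.temp_flat_window_s) <= 0:
            raise ValidationError("rule windows must be positive")
        if not self.eda_high1_us < self.eda_high2_us:
            raise ValidationError("EDA high-range thresholds must be ordered")


@dataclass
class SQISeries:
    """Per-channel quality scores plus the combined binary validity mask."""

    t2: np.ndarray
    sqi_eda: np.ndarray
    sqi_temp: np.ndarray
    sqi_all: np.ndarray

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        for name in ("sqi_eda", "sqi_temp", "sqi_all"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != self.t2.size:
                raise ValidationError(f"{name} length != t2 length")
        if self.sqi_eda.size and (self.sqi_eda.min() < 0 or self.sqi_eda.max() > 1):
            raise ValidationError("sqi_eda outside [0, 1]")
        if self.sqi_temp.size and (self.sqi_temp.min() < 0 or self.sqi_temp.max() > 1):
            raise ValidationError("sqi_temp outside [0, 1]")
        if not np.isin(self.sqi_all, (0.0, 1.0)).all():
            raise ValidationError("sqi_all must be binary")


def _max_abs_consecutive_diff(x: np.ndarray, win: int) -> np.ndarray:
    """At each step, max |x[j]−x[j−1]| over the trailing ``win``-sample window.

    Steps whose trailing window is not yet complete get NaN (rule not
    evaluated during warm-up).
    """
    n = x.size
    out = np.full(n, np.nan)
    if n < 2:
        return out
    d = np.abs(np.diff(x))
    # window [i-win+1, i] contains diffs d[i-win+1 .. i-1] -> win-1 diffs
    ndiff = win - 1
    if ndiff < 1 or n < win:
        return out
    from numpy.lib.stride_tricks import sliding_window_view

    sw = sliding_window_view(d, ndiff)  # sw[j] = d[j .. j+ndiff-1]
    out[win - 1 :] = sw.max(axis=1)
    return out


def sqi_eda(eda: np.ndarray, rules: SQIRules | None = None) -> np.ndarray:
    """Quality score series for the electrodermal channel."""
    rules = rules or SQIRules()
    eda = np.asarray(eda, dtype=float)
    n = eda.size
    scores = np.ones(n)

    # instantaneous range rules (evaluated from the first step)
    scores = np.where(eda > rules.eda_high1_us, np.minimum(scores, rules.eda_high1_score), scores)
    scores = np.where(eda > rules.eda_high2_us, np.minimum(scores, rules.eda_high2_score), scores)
    scores = np.where(eda <= rules.eda_low_us, np.minimum(scores, rules.eda_low_score), scores)

    # derivative rule over the trailing window
    wd = int(round(rules.eda_deriv_window_s / rules.step_s)) + 1
    md = _max_abs_consecutive_diff(eda, wd)
    fired = np.isfinite(md) & (md > rules.eda_deriv_thresh_us)
    scores = np.where(fired, np.minimum(scores, rules.eda_deriv_score), scores)

    # flatness rule over the trailing window
    wf = int(round(rules.eda_flat_window_s / rules.step_s)) + 1
    mf = _max_abs_consecutive_diff(eda, wf)
    flat = np.isfinite(mf) & (mf <= rules.eda_flat_eps_us)
    scores = np.where(flat, np.minimum(scores, rules.eda_flat_score), scores)
    return scores


def sqi_temp(temp: np.ndarray, rules: SQIRules | None = None) -> np.ndarray:
    """Quality score series for the skin-temperature channel."""
    rules = rules or SQIRules()
    temp = np.asarray(temp, dtype=float)
    scores = np.ones(temp.size)

    scores = np.where(temp < rules.temp_low_c, np.minimum(scores, rules.temp_low_score), scores)

    wf = int(round(rules.temp_flat_window_s / rules.step_s)) + 1
    mf = _max_abs_consecutive_diff(temp, wf)
    flat = np.isfinite(mf) & (mf <= rules.temp_flat_eps_c)
    scores = np.where(flat, np.minimum(scores, rules.temp_flat_score), scores)
    return scores


def combine_sqi(sqi_eda_series: np.ndarray, sqi_temp_series: np.ndarray) -> np.ndarray:
    """Binary session validity: 0 where either channel falls below μ − σ.

    μ and σ are the session mean and (population) standard deviation of the
    respective quality series, computed in batch once the session is
    complete.
    """
    e = np.asarray(sqi_eda_series, dtype=float)
    t = np.asarray(sqi_temp_series, dtype=float)
    if e.size == 0 or t.size == 0:
        raise ValidationError("cannot combine empty SQI series")
    if e.size != t.size:
        raise ValidationError("SQI series lengths differ")
    bad = (e < e.mean() - e.std()) | (t < t.mean() - t.std())
    return np.where(bad, 0.0, 1.0)


def score_quality(t2, eda, temp, rules: SQIRules | None = None) -> SQISeries:
    """Compute both channel scores and the combined validity mask."""
    rules = rules or SQIRules()
    se = sqi_eda(eda, rules)
    st = sqi_temp(temp, rules)
    return SQISeries(t2=t2, sqi_eda=se, sqi_temp=st, sqi_all=combine_sqi(se, st))
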