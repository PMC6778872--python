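"""Per-modality feature extraction and weighted multi-modal event selection.

Three feature series are computed on the 2 Hz preprocessed channels, each
valued at the physical magnitude of the change when its threshold is
crossed and zero otherwise:

- ``edr(t)``   — electrodermal reaction: the rise of the EDA signal above
  the minimum of its trailing ``t_edr`` window, when at least ``a_edr`` µS;
- ``dtemp(t)`` — temperature trend excursion: the max−min range of the
  trailing ``t_temp`` window, when at least ``dt_min`` °C;
- ``hrvar(t)`` — heart-rate variation: the topographic prominence of local
  heart-rate maxima and minima, when at least ``min_peak_prominence`` bpm.

The combined score is the weighted sum ``S = a·edr + b·dtemp + c·hrvar``;
the top-N score steps on quality-valid samples, kept at least 20 s apart so
their video clips never overlap, become the session's candidate salient
moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import Event, DetectorParams, PhysioRecording, ValidationError, clip_window
from .preprocess import CleanSignals, FilterConfig, preprocess
from .quality import SQIRules, SQISeries, score_quality

#: absolute tie tolerance for threshold crossings, so that a feature whose
#: magnitude equals its threshold up to float rounding still fires
THRESH_TIE_TOL = 1e-9

_STEP_S = 0.5


@dataclass
class FeatureSeries:
    """Aligned per-modality feature magnitudes at 0.5 s steps."""

    t2: np.ndarray
    edr: np.ndarray
    dtemp: np.ndarray
    hrvar: np.ndarray

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        for name in ("edr", "dtemp", "hrvar"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != self.t2.size:
                raise ValidationError(f"{name} length != t2 length")
            if arr.size and arr.min() < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class ScoreSeries:
    """Weighted combined score and the per-step dominant modality."""

    t2: np.ndarray
    s: np.ndarray
    dominant: np.ndarray  # one of "eda", "temp", "hr" per step


def _window_samples(window_s: float) -> int:
    # trailing window [t - window_s, t] inclusive of the current step
    return int(round(window_s / _STEP_S)) + 1


def trailing_min(x: np.ndarray, window_s: float) -> np.ndarray:
    return (
        pd.Series(x).rolling(_window_samples(window_s), min_periods=1).min().to_numpy()
    )


def trailing_range(x: np.ndarray, window_s: float) -> np.ndarray:
    s = pd.Series(x).rolling(_window_samples(window_s), min_periods=1)
    return (s.max() - s.min()).to_numpy()


def detect_edr(eda: np.ndarray, t_edr_s: float = 10.0, a_edr_us: float = 0.05) -> np.ndarray:
    """Electrodermal-reaction feature: trailing-window rise above threshold."""
    if t_edr_s < 1.0:
        raise ValidationError("t_edr_s must be at least 1 s")
    eda = np.asarray(eda, dtype=float)
    rise = eda - trailing_min(eda, t_edr_s)
    return np.where(rise >= a_edr_us - THRESH_TIE_TOL, rise, 0.0)


def detect_temp_trend(
    temp: np.ndarray,
    t_temp_s: float = 10.0,
    dt_min_c: float = 0.01,
    require_sign_change: bool = False,
) -> np.ndarray:
    """Temperature-trend feature: trailing-window max−min range above threshold.

    With ``require_sign_change`` the window must additionally contain a slope
    sign reversal (a vasoconstriction/vasodilation switch); the plain range
    test is the default.
    """
    if t_temp_s < 1.0:
        raise ValidationError("t_temp_s must be at least 1 s")
    temp = np.asarray(temp, dtype=float)
    rng = trailing_range(temp, t_temp_s)
    fired = rng >= dt_min_c - THRESH_TIE_TOL
    if require_sign_change and temp.size >= 3:
        sign = np.sign(np.diff(temp))
        flip = np.zeros(temp.size, dtype=bool)
        flip[2:] = sign[1:] * sign[:-1] < 0
        w = _window_samples(t_temp_s)
        has_flip = (
            pd.Series(flip.astype(float)).rolling(w, min_periods=1).max().to_numpy() > 0
        )
        fired &= has_flip
    return np.where(fired, rng, 0.0)


def hr_extrema(hr: np.ndarray, wlen_s: float | None = 60.0) -> tuple[np.ndarray, np.ndarray]:
    """All interior local maxima and minima with their prominences.

    ``wlen_s`` bounds the saddle search to a window around each extremum, so
    prominence is measured against the local heart-rate pattern rather than
    the whole session (pass ``None`` for the global topographic definition).
    """
    hr = np.asarray(hr, dtype=float)
    wlen = None if wlen_s is None else int(round(wlen_s / _STEP_S)) + 1
    idx_max, props_max = find_peaks(hr, prominence=0, wlen=wlen)
    idx_min, props_min = find_peaks(-hr, prominence=0, wlen=wlen)
    idx = np.concatenate([idx_max, idx_min])
    prom = np.concatenate([props_max["prominences"], props_min["prominences"]])
    order = np.argsort(idx)
    return idx[order], prom[order]


def detect_hr_var(
    hr: np.ndarray,
    min_peak_prominence_bpm: float = 10.0,
    wlen_s: float | None = 60.0,
) -> np.ndarray:
    """Heart-rate feature: prominence at sufficiently prominent local extrema."""
    hr = np.asarray(hr, dtype=float)
    if hr.size < 3:
        raise ValidationError("detect_hr_var requires at least 3 samples")
    out = np.zeros(hr.size)
    idx, prom = hr_extrema(hr, wlen_s)
    keep = prom >= min_peak_prominence_bpm - THRESH_TIE_TOL
    out[idx[keep]] = prom[keep]
    return out


def extract_features(clean: CleanSignals, params: DetectorParams) -> FeatureSeries:
    return FeatureSeries(
        t2=clean.t2,
        edr=detect_edr(clean.eda, params.t_edr_s, params.a_edr_us),
        dtemp=detect_temp_trend(clean.temp, params.t_temp_s, params.dt_min_c),
        hrvar=detect_hr_var(clean.hr, params.min_peak_prominence_bpm, params.prominence_wlen_s),
    )


def score(features: FeatureSeries, a: float = 1.0, b: float = 1.0, c: float = 1.0) -> ScoreSeries:
    """Pointwise weighted score ``S = a·edr + b·dtemp + c·hrvar``."""
    if min(a, b, c) < 0:
        raise ValidationError("weights must be non-negative")
    terms = np.vstack([a * features.edr, b * features.dtemp, c * features.hrvar])
    s = terms.sum(axis=0)
    dominant = np.array(("eda", "temp", "hr"))[np.argmax(terms, axis=0)]
    return ScoreSeries(t2=features.t2, s=s, dominant=dominant)


def select_events(
    scores: ScoreSeries,
    sqi_all: np.ndarray,
    max_events: int = 5,
    min_sep_s: float = 20.0,
    clip_halfwidth_s: float = 10.0,
) -> list[Event]:
    """Greedy top-N selection of score peaks on quality-valid steps.

    Repeatedly takes the highest-score valid step (ties broken by earlier
    time) that lies at least ``min_sep_s`` from every already-selected
    event. Returned events are sorted by time and carry their clip window
    and dominant modality.
    """
    s = np.asarray(scores.s, dtype=float)
    t2 = np.asarray(scores.t2, dtype=float)
    valid = (np.asarray(sqi_all) > 0) & (s > 0)
    if s.size != t2.size or np.asarray(sqi_all).size != s.size:
        raise ValidationError("score and validity series must be aligned")
    if max_events == 0 or not valid.any():
        return []
    span = (float(t2[0]), float(t2[-1]))
    order = np.lexsort((t2, -s))
    chosen: list[int] = []
    for i in order:
        if not valid[i]:
            continue
        if all(abs(t2[i] - t2[j]) >= min_sep_s for j in chosen):
            chosen.append(i)
            if len(chosen) >= max_events:
                break
    events = []
    for i in sorted(chosen, key=lambda j: t2[j]):
        start, end = clip_window(float(t2[i]), span, clip_halfwidth_s)
        events.append(
            Event(
                time_s=float(t2[i]),
                score=float(s[i]),
                dominant_modality=str(scores.dominant[i]),
                clip_start_s=start,
                clip_end_s=end,
            )
        )
    return events


def run_detector(
    clean: CleanSignals, sqi: SQISeries, params: DetectorParams | None = None
) -> list[Event]:
    """Feature extraction → weighted scoring → top-N selection."""
    params = params or DetectorParams()
    features = extract_features(clean, params)
    scores = score(features, params.a, params.b, params.c)
    return select_events(
        scores, sqi.sqi_all, params.max_events, params.min_sep_s, params.clip_halfwidth_s
    )


def run_pipeline(
    rec: PhysioRecording,
    params: DetectorParams | None = None,
    filter_cfg: FilterConfig | None = None,
    rules: SQIRules | None = None,
) -> tuple[CleanSignals, SQISeries, list[Event]]:
    """Preprocess a raw recording, score its quality, and detect events."""
    clean = preprocess(rec, filter_cfg)
    sqi = score_quality(clean.t2, clean.eda, clean.temp, rules)
    events = run_detector(clean, sqi, params)
    return clean, sqi, events
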