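"""Per-individual parameter tailoring and agreement scoring.

The detector's thresholds and modality weights are personal: different
people express salient moments through different autonomic channels and at
different magnitudes. This module automates the two tailoring stages that
were originally driven by video review and dyad interviews:

1. ``fit_from_annotations`` — given a session with timestamped
   significant-moment annotations, measure the three feature magnitudes in
   a 10 s epoch around each annotated moment, seed candidate thresholds
   from the observed magnitudes, and grid-search thresholds, windows and
   weights for the parameter set with the best precision at the session's
   configured event budget.
2. ``iterate_feedback`` — given true/false-positive verdicts on detected
   events (and any reported missed moments), search the neighbourhood of
   the current parameters for a set that suppresses the false positives
   and recovers the missed moments without giving up retained true
   positives.

Agreement is scored by ``evaluate``: an event is a true positive when a
significant annotation lies within the matching tolerance (±10 s, the clip
half-width) of its time; precision is TP/(TP+FP).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .detect import (
    THRESH_TIE_TOL,
    FeatureSeries,
    ScoreSeries,
    hr_extrema,
    score,
    select_events,
    trailing_min,
    trailing_range,
)
from .io import AnnotationSet, DetectorParams, Event, ValidationError
from .preprocess import CleanSignals
from .quality import SQISeries


@dataclass(frozen=True)
class FeedbackItem:
    event: Event
    verdict: str  # "TP" or "FP"

    def __post_init__(self) -> None:
        if self.verdict not in ("TP", "FP"):
            raise ValidationError("verdict must be 'TP' or 'FP'")


@dataclass
class Feedback:
    """Dyad verdicts on presented events plus any reported missed moments."""

    items: list[FeedbackItem] = field(default_factory=list)
    missed_times_s: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [it.event.time_s for it in self.items]
        if len(set(times)) != len(times):
            raise ValidationError("each presented event must have exactly one verdict")

    @property
    def tp_times(self) -> list[float]:
        return [it.event.time_s for it in self.items if it.verdict == "TP"]

    @property
    def fp_times(self) -> list[float]:
        return [it.event.time_s for it in self.items if it.verdict == "FP"]


@dataclass
class TailorGrid:
    """Candidate values for the grid search.

    Defaults list only the untailored values; with ``seed_from_annotations``
    the observed per-epoch feature magnitudes extend each threshold list, so
    the grid adapts to the individual's response scale.
    """

    a_edr_candidates: list[float] = field(default_factory=lambda: [0.05])
    dt_min_candidates: list[float] = field(default_factory=lambda: [0.01])
    prominence_candidates: list[float] = field(default_factory=lambda: [10.0])
    t_edr_candidates: list[float] = field(default_factory=lambda: [10.0])
    t_temp_candidates: list[float] = field(default_factory=lambda: [10.0, 25.0])
    weight_candidates: list[float] = field(default_factory=lambda: [0.0, 1.0])
    match_tolerance_s: float = 10.0
    epoch_halfwidth_s: float = 5.0
    seed_from_annotations: bool = True
    prominence_wlen_s: float | None = 60.0

    def __post_init__(self) -> None:
        for name in (
            "a_edr_candidates",
            "dt_min_candidates",
            "prominence_candidates",
            "t_edr_candidates",
            "t_temp_candidates",
            "weight_candidates",
        ):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")
        if self.match_tolerance_s <= 0:
            raise ValidationError("match tolerance must be positive")


class EvalResult(NamedTuple):
    tp: int
    fp: int
    precision: float


class FitResult(NamedTuple):
    params: DetectorParams
    precision: float
    tp: int
    fp: int


# ---------------------------------------------------------------------------
# Agreement scoring


def evaluate(
    events: Sequence[Event], annotations: AnnotationSet, tol_s: float = 10.0
) -> EvalResult:
    """Match events to significant annotations, nearest pairs first.

    Each annotation matches at most one event; matched events are true
    positives, unmatched ones false positives. With no events at all the
    precision is defined as 1.
    """
    if tol_s <= 0:
        raise ValidationError("matching tolerance must be positive")
    sig = sorted(annotations.significant_times)
    pairs = []
    for i, ev in enumerate(events):
        for j, ts in enumerate(sig):
            d = abs(ev.time_s - ts)
            if d <= tol_s:
                pairs.append((d, ev.time_s, i, j))
    pairs.sort()
    used_ev: set[int] = set()
    used_ann: set[int] = set()
    for _, _, i, j in pairs:
        if i in used_ev or j in used_ann:
            continue
        used_ev.add(i)
        used_ann.add(j)
    tp = len(used_ev)
    fp = len(events) - tp
    precision = 1.0 if not events else tp / (tp + fp)
    return EvalResult(tp, fp, precision)


# ---------------------------------------------------------------------------
# Epoch feature magnitudes and threshold seeding


def _epoch_max(series: np.ndarray, t2: np.ndarray, center_s: float, halfwidth_s: float) -> float:
    sel = np.abs(t2 - center_s) <= halfwidth_s
    return float(series[sel].max()) if sel.any() else 0.0


def _prominence_series(hr: np.ndarray, wlen_s: float | None = 60.0) -> np.ndarray:
    out = np.zeros(hr.size)
    idx, prom = hr_extrema(hr, wlen_s)
    out[idx] = prom
    return out


def _seed_from_mags(mags: Sequence[float]) -> list[float]:
    mags = [m for m in mags if m > 0]
    if not mags:
        return []
    lo = min(mags)
    return [0.95 * lo, lo, float(np.median(mags))]


def threshold_candidates(
    clean: CleanSignals,
    sig_times: Sequence[float],
    grid: TailorGrid,
) -> dict[str, list[float]]:
    """Sorted candidate threshold lists per modality, seeds included.

    EDA and temperature seeds are taken per candidate window; the returned
    lists define the grid steps used both by the search and by
    parameter-recovery checks.
    """
    cands = {
        "a_edr": list(grid.a_edr_candidates),
        "dt_min": list(grid.dt_min_candidates),
        "prominence": list(grid.prominence_candidates),
    }
    if grid.seed_from_annotations and len(sig_times):
        for w in grid.t_edr_candidates:
            rise = clean.eda - trailing_min(clean.eda, w)
            mags = [_epoch_max(rise, clean.t2, ts, grid.epoch_halfwidth_s) for ts in sig_times]
            cands["a_edr"] += _seed_from_mags(mags)
        for w in grid.t_temp_candidates:
            rng = trailing_range(clean.temp, w)
            mags = [_epoch_max(rng, clean.t2, ts, grid.epoch_halfwidth_s) for ts in sig_times]
            cands["dt_min"] += _seed_from_mags(mags)
        prom = _prominence_series(clean.hr, grid.prominence_wlen_s)
        mags = [_epoch_max(prom, clean.t2, ts, grid.epoch_halfwidth_s) for ts in sig_times]
        cands["prominence"] += _seed_from_mags(mags)
    return {k: sorted(set(v)) for k, v in cands.items()}


# ---------------------------------------------------------------------------
# Stage 1: fitting from annotated sessions


def _threshold_feature(series: np.ndarray, thresh: float) -> np.ndarray:
    return np.where(series >= thresh - THRESH_TIE_TOL, series, 0.0)


def fit_from_annotations(
    clean: CleanSignals,
    sqi: SQISeries,
    annotations: AnnotationSet,
    grid: TailorGrid | None = None,
    base_params: DetectorParams | None = None,
) -> FitResult:
    """Grid-search a personal parameter set on an annotated session.

    Maximizes precision at the fixed event budget ``base_params.max_events``
    (ties broken by more true positives, then earliest grid order, so the
    result is deterministic for a given grid).
    """
    grid = grid or TailorGrid()
    base = base_params or DetectorParams()
    sig_times = annotations.significant_times
    if sig_times.size == 0:
        raise ValidationError("fit_from_annotations requires at least one significant annotation")

    cands = threshold_candidates(clean, sig_times, grid)
    rises = {w: clean.eda - trailing_min(clean.eda, w) for w in grid.t_edr_candidates}
    ranges = {w: trailing_range(clean.temp, w) for w in grid.t_temp_candidates}
    prom_series = _prominence_series(clean.hr, grid.prominence_wlen_s)

    # ties keep the first candidate seen, so enumeration order encodes the
    # preference among equally precise settings: fewer active modalities,
    # longer windows, and larger (more specific) thresholds first
    weight_combos = sorted(
        (
            wc
            for wc in itertools.product(grid.weight_candidates, repeat=3)
            if any(w > 0 for w in wc)
        ),
        key=lambda wc: (sum(1 for w in wc if w > 0), wc),
    )

    best: FitResult | None = None
    best_key = (-1.0, -1)
    for t_edr, a_thr, t_temp, dt_thr, p_thr in itertools.product(
        sorted(grid.t_edr_candidates, reverse=True),
        sorted(cands["a_edr"], reverse=True),
        sorted(grid.t_temp_candidates, reverse=True),
        sorted(cands["dt_min"], reverse=True),
        sorted(cands["prominence"], reverse=True),
    ):
        feats = FeatureSeries(
            t2=clean.t2,
            edr=_threshold_feature(rises[t_edr], a_thr),
            dtemp=_threshold_feature(ranges[t_temp], dt_thr),
            hrvar=_threshold_feature(prom_series, p_thr),
        )
        for wa, wb, wc in weight_combos:
            scores = score(feats, wa, wb, wc)
            events = select_events(
                scores, sqi.sqi_all, base.max_events, base.min_sep_s, base.clip_halfwidth_s
            )
            res = evaluate(events, annotations, grid.match_tolerance_s)
            # an empty selection is vacuously precise; rank it last so the
            # search cannot "win" by detecting nothing
            key = (res.precision if events else 0.0, res.tp)
            if best is None or key > best_key:
                best_key = key
                params = base.replace(
                    t_edr_s=t_edr,
                    a_edr_us=a_thr,
                    t_temp_s=t_temp,
                    dt_min_c=dt_thr,
                    min_peak_prominence_bpm=p_thr,
                    a=wa,
                    b=wb,
                    c=wc,
                )
                best = FitResult(params, res.precision, res.tp, res.fp)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Stage 2: feedback-driven adjustment


def _neighbors(value: float, candidates: Sequence[float]) -> list[float]:
    cs = sorted(set(candidates) | {value})
    i = cs.index(value)
    return cs[max(i - 1, 0) : i + 2]


def _count_hit(times: Sequence[float], events: Sequence[Event], tol_s: float) -> int:
    ev_times = np.array([e.time_s for e in events])
    if ev_times.size == 0:
        return 0
    return sum(1 for ts in times if np.abs(ev_times - ts).min() <= tol_s)


def iterate_feedback(
    params: DetectorParams,
    clean: CleanSignals,
    sqi: SQISeries,
    fb: Feedback,
    grid: TailorGrid | None = None,
) -> DetectorParams:
    """Adjust thresholds so false-positive moments drop out of the selection
    and reported missed moments rise into it, never giving up retained true
    positives.

    Candidate thresholds come from the feedback itself — just above each
    false positive's feature magnitude, just below each missed moment's —
    plus the immediate grid neighbours of the current values. Ties keep the
    current parameters.
    """
    grid = grid or TailorGrid()
    if not fb.items and not fb.missed_times_s:
        raise ValidationError("feedback is empty")
    tol = grid.match_tolerance_s

    rise = clean.eda - trailing_min(clean.eda, params.t_edr_s)
    rng = trailing_range(clean.temp, params.t_temp_s)
    prom = _prominence_series(clean.hr, params.prominence_wlen_s)

    def cand_list(series: np.ndarray, current: float, grid_values: Sequence[float]) -> list[float]:
        out = {current}
        for ts in fb.fp_times:
            m = _epoch_max(series, clean.t2, ts, grid.epoch_halfwidth_s)
            if m > 0:
                out.add(1.01 * m)
        for ts in fb.missed_times_s:
            m = _epoch_max(series, clean.t2, ts, grid.epoch_halfwidth_s)
            if m > 0:
                out.add(0.99 * m)
        out.update(_neighbors(current, grid_values))
        return sorted(out)

    a_cands = cand_list(rise, params.a_edr_us, grid.a_edr_candidates)
    dt_cands = cand_list(rng, params.dt_min_c, grid.dt_min_candidates)
    p_cands = cand_list(prom, params.min_peak_prominence_bpm, grid.prominence_candidates)

    def objective(p: DetectorParams) -> tuple[int, int]:
        feats = FeatureSeries(
            t2=clean.t2,
            edr=_threshold_feature(rise, p.a_edr_us),
            dtemp=_threshold_feature(rng, p.dt_min_c),
            hrvar=_threshold_feature(prom, p.min_peak_prominence_bpm),
        )
        events = select_events(
            score(feats, p.a, p.b, p.c),
            sqi.sqi_all,
            p.max_events,
            p.min_sep_s,
            p.clip_halfwidth_s,
        )
        tp_ret = _count_hit(fb.tp_times, events, tol)
        fp_ret = _count_hit(fb.fp_times, events, tol)
        missed_rec = _count_hit(fb.missed_times_s, events, tol)
        return tp_ret, tp_ret - fp_ret + missed_rec

    base_tp, base_margin = objective(params)
    best_params, best_margin = params, base_margin
    for a_thr, dt_thr, p_thr in itertools.product(a_cands, dt_cands, p_cands):
        cand = params.replace(a_edr_us=a_thr, dt_min_c=dt_thr, min_peak_prominence_bpm=p_thr)
        tp_ret, margin = objective(cand)
        if tp_ret >= base_tp and margin > best_margin:
            best_params, best_margin = cand, margin
    return best_params
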