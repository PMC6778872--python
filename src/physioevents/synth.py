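"""Synthetic 15 Hz three-channel sessions with known embedded events.

The generator emulates the signal classes a fingertip-worn autonomic sensor
produces: a slowly drifting baseline per channel with white Gaussian noise,
plus idealized salient-event morphologies —

- electrodermal reactions as a linear conductance ramp of the requested
  magnitude followed by an exponential recovery,
- temperature excursions as a monotone half-cosine rise with a slow linear
  return,
- heart-rate events as a triangular excursion whose apex prominence equals
  the requested magnitude —

and sensor artifacts (zero dropouts, spikes, frozen readings, out-of-range
excursions). Each embedded event also yields a ground-truth "significant"
annotation at its time, so detection, quality scoring, and tailoring can be
exercised end to end without any recorded data. Output is bit-reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Annotation, AnnotationSet, PhysioRecording, ValidationError

ARTIFACT_KINDS = ("zero_dropout", "spike", "flatline", "out_of_range")
_CHANNELS = ("eda", "temp", "hr")


@dataclass(frozen=True)
class SynthEvent:
    time_s: float
    modality: str
    magnitude: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.modality not in _CHANNELS:
            raise ValidationError(f"modality must be one of {_CHANNELS}")
        if self.magnitude < 0 or self.duration_s <= 0:
            raise ValidationError("event magnitude must be >= 0 and duration > 0")


@dataclass(frozen=True)
class SynthArtifact:
    time_s: float
    kind: str
    duration_s: float
    channel: str = "all"

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValidationError(f"kind must be one of {ARTIFACT_KINDS}")
        if self.channel not in _CHANNELS + ("all",):
            raise ValidationError("channel must be a channel name or 'all'")


@dataclass
class SynthConfig:
    duration_s: float = 600.0
    seed: int = 0
    fs: float = 15.0
    baseline_eda_us: float = 2.0
    baseline_temp_c: float = 33.0
    baseline_hr_bpm: float = 70.0
    noise_eda_us: float = 0.0
    noise_temp_c: float = 0.0
    noise_hr_bpm: float = 0.0
    drift_amp_eda_us: float = 0.0
    drift_amp_temp_c: float = 0.0
    drift_amp_hr_bpm: float = 0.0
    drift_period_s: float = 120.0
    #: extra sinusoidal background structure: (channel, amplitude, period_s)
    waves: list[tuple[str, float, float]] = field(default_factory=list)
    events: list[SynthEvent] = field(default_factory=list)
    artifacts: list[SynthArtifact] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.events:
            if not 0 <= e.time_s <= self.duration_s:
                raise ValidationError("event time outside session duration")
        for a in self.artifacts:
            if not 0 <= a.time_s <= self.duration_s:
                raise ValidationError("artifact time outside session duration")
        for ch, _, period in self.waves:
            if ch not in _CHANNELS:
                raise ValidationError(f"wave channel must be one of {_CHANNELS}")
            if period <= 0:
                raise ValidationError("wave period must be positive")
        # overlapping same-modality events would make the ground truth ambiguous
        by_mod: dict[str, list[SynthEvent]] = {}
        for e in self.events:
            by_mod.setdefault(e.modality, []).append(e)
        for mod, evs in by_mod.items():
            evs = sorted(evs, key=lambda e: e.time_s)
            for prev, nxt in zip(evs, evs[1:]):
                if nxt.time_s - nxt.duration_s < prev.time_s + prev.duration_s:
                    raise ValidationError(f"overlapping {mod} events")


_ARTIFACT_VALUES = {  # out-of-range levels per channel
    "eda": 35.0,
    "temp": 10.0,
    "hr": 250.0,
}
_SPIKE_OFFSETS = {"eda": 25.0, "temp": 8.0, "hr": 80.0}


def _event_waveform(t: np.ndarray, e: SynthEvent) -> np.ndarray:
    w = np.zeros_like(t)
    if e.modality == "eda":
        # linear ramp over [time - duration, time], exponential recovery after
        rise = (t >= e.time_s - e.duration_s) & (t <= e.time_s)
        w[rise] = e.magnitude * (t[rise] - (e.time_s - e.duration_s)) / e.duration_s
        rec = t > e.time_s
        w[rec] = e.magnitude * np.exp(-(t[rec] - e.time_s) / (2.0 * e.duration_s))
    elif e.modality == "temp":
        # monotone half-cosine rise, linear return of the same duration
        rise = (t >= e.time_s - e.duration_s) & (t <= e.time_s)
        phase = (t[rise] - (e.time_s - e.duration_s)) / e.duration_s
        w[rise] = e.magnitude * 0.5 * (1.0 - np.cos(np.pi * phase))
        fall = (t > e.time_s) & (t <= e.time_s + e.duration_s)
        w[fall] = e.magnitude * (1.0 - (t[fall] - e.time_s) / e.duration_s)
    else:  # hr: triangular excursion, apex at time_s
        half = e.duration_s / 2.0
        up = (t >= e.time_s - half) & (t <= e.time_s)
        w[up] = e.magnitude * (t[up] - (e.time_s - half)) / half
        down = (t > e.time_s) & (t <= e.time_s + half)
        w[down] = e.magnitude * (1.0 - (t[down] - e.time_s) / half)
    return w


def generate(cfg: SynthConfig) -> tuple[PhysioRecording, AnnotationSet]:
    """Realize a session and its ground-truth annotations from the config."""
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    channels: dict[str, np.ndarray] = {}
    baselines = {
        "eda": cfg.baseline_eda_us,
        "temp": cfg.baseline_temp_c,
        "hr": cfg.baseline_hr_bpm,
    }
    noises = {"eda": cfg.noise_eda_us, "temp": cfg.noise_temp_c, "hr": cfg.noise_hr_bpm}
    drifts = {"eda": cfg.drift_amp_eda_us, "temp": cfg.drift_amp_temp_c, "hr": cfg.drift_amp_hr_bpm}
    for ch in _CHANNELS:
        x = np.full(n, baselines[ch])
        if drifts[ch]:
            x = x + drifts[ch] * np.sin(2.0 * np.pi * t / cfg.drift_period_s)
        if noises[ch]:
            x = x + noises[ch] * rng.standard_normal(n)
        channels[ch] = x
    for ch, amp, period in cfg.waves:
        channels[ch] = channels[ch] + amp * np.sin(2.0 * np.pi * t / period)

    for e in cfg.events:
        channels[e.modality] = channels[e.modality] + _event_waveform(t, e)

    for a in cfg.artifacts:
        sel = (t >= a.time_s) & (t < a.time_s + a.duration_s)
        targets = _CHANNELS if a.channel == "all" else (a.channel,)
        for ch in targets:
            x = channels[ch]
            if a.kind == "zero_dropout":
                x[sel] = 0.0
            elif a.kind == "spike":
                x[sel] = x[sel] + _SPIKE_OFFSETS[ch]
            elif a.kind == "flatline":
                idx = np.flatnonzero(sel)
                if idx.size:
                    x[sel] = x[max(idx[0] - 1, 0)]
            else:  # out_of_range
                x[sel] = _ARTIFACT_VALUES[ch]

    rec = PhysioRecording(
        session_id=f"synth-{cfg.seed}",
        t=t,
        eda=channels["eda"],
        temp=channels["temp"],
        hr=channels["hr"],
        fs=cfg.fs,
    )
    ann = AnnotationSet(
        [Annotation(e.time_s, "significant", e.modality) for e in cfg.events]
    )
    return rec, ann


# ---------------------------------------------------------------------------
# Canned per-individual response profiles

_EVENT_TIMES = (80.0, 190.0, 300.0, 410.0, 520.0)


def _reference_config(kind: str, seed: int) -> SynthConfig:
    base = SynthConfig(
        duration_s=600.0,
        seed=seed,
        noise_eda_us=0.008,
        noise_temp_c=0.0012,
        noise_hr_bpm=1.0,
        drift_period_s=150.0,
    )
    if kind == "mary_like":
        # sharp electrodermal reactions of 0.24 µS; EDA drift steep enough to
        # trip the default 0.05 µS rise threshold, and temperature drift the
        # default trend threshold, so only a tailored set is precise
        return replace(
            base,
            drift_amp_eda_us=0.20,
            drift_amp_temp_c=0.06,
            drift_amp_hr_bpm=3.0,
            events=[SynthEvent(ts, "eda", 0.24, 8.0) for ts in _EVENT_TIMES],
        )
    if kind == "elisa_like":
        # heart-rate excursions of 30 bpm prominence over a fast oscillation
        # whose crests (~14 bpm prominence) the default 10 bpm threshold flags
        return replace(
            base,
            drift_amp_eda_us=0.06,
            drift_amp_temp_c=0.003,
            waves=[("hr", 7.0, 40.0)],
            events=[SynthEvent(ts, "hr", 30.0, 20.0) for ts in (70.0, 190.0, 310.0, 430.0, 550.0)],
        )
    if kind == "irene_like":
        # slow 0.02 °C temperature excursions over 25 s; a fast low-amplitude
        # temperature wave makes short-window trend thresholds unusable so the
        # tailored detector must adopt the 25 s window
        return replace(
            base,
            drift_amp_eda_us=0.04,
            drift_amp_hr_bpm=3.0,
            noise_temp_c=0.0008,
            waves=[("temp", 0.01, 20.0)],
            events=[SynthEvent(ts, "temp", 0.02, 25.0) for ts in (80.0, 180.0, 300.0, 420.0, 540.0)],
        )
    raise ValidationError(f"unknown reference-session kind {kind!r}")


def reference_session(kind: str, seed: int = 0) -> tuple[PhysioRecording, AnnotationSet]:
    """Session with a mono-modal response profile near the tailored thresholds.

    ``mary_like`` embeds 0.24 µS electrodermal ramps, ``elisa_like`` 30 bpm
    heart-rate excursions, and ``irene_like`` ≈0.02 °C temperature excursions
    over 25 s, each amid distractor drift in the other channels.
    """
    return generate(_reference_config(kind, seed))


#: ground-truth thresholds the reference profiles are generated from
REFERENCE_TRUTH = {
    "mary_like": ("eda", 0.24),
    "elisa_like": ("hr", 30.0),
    "irene_like": ("temp", 0.02),
}
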