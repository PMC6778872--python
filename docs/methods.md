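# Methods

## Signal model and units

A session is three synchronized channels sampled at a nominal 15 Hz:
electrodermal activity (µS), peripheral skin temperature (°C), and heart
rate (bpm), with time in seconds from session start. The sampling
frequency is inferred from the file's time axis as 1/median(Δt) rather
than assumed, so resampled inputs are handled and a deviation of more than
10% from 15 Hz raises a warning. All analysis after preprocessing runs on
a common 2 Hz axis (0.5 s steps).

## Preprocessing

1. **Artifact flagging.** A sample is flagged when it equals zero or lies
   more than three standard deviations from the mean of the preceding
   second. The two rules are combined by OR: each independently indicates
   hardware error, and their conjunction would almost never fire. The
   preceding-window statistics use the sample standard deviation
   (ddof = 1); at least two preceding samples are required, so the first
   couple of samples can only be flagged by the zero rule, and a
   zero-variance preceding window disables the deviation rule (a clean
   constant signal should not flag itself). Flagged samples are replaced
   by the median of the unflagged samples in a centred window (75 samples
   for EDA; 1 for temperature; heart rate is unspecified anywhere and uses
   the temperature setting of 1 for parsimony — with a 1-sample window the
   replacement degenerates to the nearest unflagged neighbour, which is
   also the fallback when a flagged run outruns the window). Flagged runs
   longer than the 1 s lookback partially evade the deviation rule (the
   window fills with the artifact value and its variance collapses); the
   signal-quality rules downstream exist to catch exactly this.
2. **Downsampling.** A non-overlapping 0.5 s moving average reduces each
   channel to 2 Hz. At 15 Hz a window holds 7.5 samples, which is not an
   integer: windows are therefore delimited by *time* (sample *i* belongs
   to window ⌊i/7.5⌋), alternating 7- and 8-sample windows without
   accumulating drift. The trailing partial window is dropped, so
   |output| = ⌊n/7.5⌋. Windows are aligned to the first sample; the output
   timestamp is the window start.
3. **Modality smoothing**, applied at 2 Hz following the stage order:
   - *EDA*: one-Euro filter (mincutoff 50, β 4, derivative cutoff fixed at
     the published default of 1 Hz). A 50 Hz cutoff exceeds the 1 Hz
     Nyquist of a 2 Hz series, so at these settings the stage is nearly
     transparent at steady state; it is retained for fidelity to the
     stated parameterization and becomes active at lower cutoffs.
   - *Temperature*: first-order exponential decay
     y[k] = p·y[k−1] + (1−p)·x[k] with p = 0.95 (time constant ≈ 10 s at
     2 Hz).
   - *Heart rate*: cubic smoothing spline in the csaps convention,
     minimizing p·Σ(y−x)² + (1−p)·∫(y″)² with p = 0.001. The solver is the
     Reinsch banded system on the natural-spline basis (λ = (1−p)/p),
     implemented directly because the contract requires n ≥ 4 and the
     exact p = 0 (least-squares line) and p = 1 (interpolation) limits;
     it agrees with `scipy.interpolate.make_smoothing_spline` to ~1e-12
     where both apply, which the tests assert.

Every stage maps constants to constants, so a constant recording passes
through unchanged — a property the tests rely on.

## Signal quality

Quality rules are evaluated per 0.5 s step with trailing (causal)
lookback windows; a step's score is the **minimum** over fired rules
(worst evidence dominates), 1 if none fire. EDA: any consecutive-sample
change above 3 µS within the trailing 15 s window scores 0.4; a flat
trailing 25 s window (all consecutive changes ≤ 0.001 µS) scores 0.1;
values ≤ 0.02 µS or > 30 µS score 0 and values > 20 µS score 0.65 (the
two high-range rules are tiered; the more extreme wins through the
minimum). Temperature: a flat trailing 25 s window (changes ≤ 0.0001 °C)
or a reading below 15 °C scores 0.5. During warm-up, while a rule's
window is incomplete, only the instantaneous range rules apply. The
"rate of change" rule is interpreted as the maximum consecutive-sample
change within the window, the strictest reading that stays causal. There
are no heart-rate quality rules; the session validity mask uses only the
EDA and temperature scores: after the session completes, step t is
invalid iff either channel's score falls strictly below that channel's
session mean minus one (population) standard deviation. Note that for a
series taking two values with equal frequency, μ−σ equals the lower value
exactly, so such dips sit on the strict-inequality boundary; real SQI
series are not balanced two-point distributions and the batch rule
behaves as intended.

## Feature extraction and scoring

Feature "strength" is the physical magnitude of the change when its
threshold is crossed and zero otherwise, which makes tailored weights
interpretable as unit-balancing scale factors:

- **EDR(t)** = x(t) − min of the trailing t_EDR window (default 10 s),
  kept when ≥ A_EDR (default 0.05 µS);
- **Δtemp(t)** = max − min of the trailing t_temp window (default 10 s),
  kept when ≥ the range threshold (default 0.01 °C). An optional stricter
  mode additionally requires a slope sign change inside the window (a
  vasoconstriction/vasodilation switch); the plain range test is the
  default because the method's worked examples use only T_max − T_min.
- **HR_var(t)** = topographic prominence at local heart-rate maxima and
  minima (minima via peak-finding on the negated series), kept when
  ≥ minPeakProminence (default 10 bpm). Prominence is measured within a
  locality window (default 60 s) around each extremum rather than over
  the whole session: with global prominence, the deepest point between
  any two tall event peaks acquires a prominence comparable to the peaks
  themselves, so every detected acceleration would induce a spurious
  "deceleration" between events. The global definition is available by
  setting the window to None. End samples are never extrema.

Threshold comparisons carry a 1e-9 absolute tie tolerance so that a
feature whose magnitude equals its threshold up to binary-float rounding
still fires (e.g. 35.8367 − 35.8267 < 0.01 in IEEE arithmetic by 2e-15).

The combined score is S = a·EDR + b·Δtemp + c·HR_var with non-negative
weights defaulting to 1. Weights are not capped at 1: tailored scale
factors naturally exceed 1 when balancing µS-scale features against
bpm-scale ones. Selection is greedy: repeatedly take the highest-score
quality-valid step (ties broken by earlier time) at least min_sep_s
(default 20 s) from every already-selected event, up to N events (default
5, up to 10 in practice). The 20 s separation guarantees the ±10 s clip
windows of selected events never overlap; clips are truncated at session
edges. Greedy selection matches the operational "take the highest-scoring
events" procedure and is optimal whenever candidate peaks are separated,
which the tests verify against exhaustive subset enumeration.

## Tailoring

Stage 1 (`fit_from_annotations`) operationalizes "accuracy" as precision
at the session's fixed event budget N: recall enters only through the
missed-moment channel of stage 2, mirroring how feedback was gathered.
Feature magnitudes are measured in ±5 s epochs around each annotated
significant moment; candidate thresholds are the grid's values plus seeds
derived from the observed magnitudes (0.95·min, min, median — per
candidate window for the windowed features). The search is a
deterministic grid walk; ties keep the first candidate seen, and the
enumeration order encodes the preference among equally precise settings:
fewer active modalities, longer windows, larger (more specific)
thresholds. An empty event selection is vacuously precise and is ranked
below any non-empty one so the search cannot win by detecting nothing.
Tailored thresholds live in the *filtered* signal domain: smoothing
attenuates raw event magnitudes (e.g. a 0.02 °C excursion over 25 s
expresses as ≈ 0.019 °C after the exponential-decay stage), and the
recovered thresholds track the expressed, not the injected, magnitude.

Stage 2 (`iterate_feedback`) searches the product of small per-modality
candidate lists: the current threshold, values just above each false
positive's epoch magnitude (×1.01), just below each missed moment's
(×0.99), and the current value's immediate grid neighbours. A candidate
is accepted only if it retains every currently retained true positive and
strictly improves the margin (retained TPs − retained FPs + recovered
missed moments); ties keep the current parameters, so all-TP feedback is
a fixed point.

`evaluate` matches events to significant annotations nearest-pair-first
within a ±10 s tolerance (the clip half-width); each annotation matches
at most one event; precision is TP/(TP+FP), defined as 1 for an empty
event list.

## Synthetic sessions

The generator emulates the signal classes of a fingertip ANS sensor, not
their physiology: per channel a constant baseline, optional slow
sinusoidal drift and extra sinusoidal background waves, and white
Gaussian noise; events with idealized morphologies chosen to be exactly
scorable by the feature definitions (linear EDA ramp with exponential
recovery; monotone half-cosine temperature rise with linear return;
triangular heart-rate excursion whose apex prominence equals the
requested magnitude); artifacts injected verbatim (zero dropouts, spikes,
frozen readings, out-of-range excursions). Everything is reproducible
bit-for-bit from the seed.

Three reference profiles embed five mono-modal events of fixed magnitude
in a 600 s session amid distractor structure strong enough that the
default thresholds produce false positives, so tailoring is actually
exercised: `mary_like` (0.24 µS EDA ramps over 8 s; EDA drift steep
enough to trip the 0.05 µS default), `elisa_like` (30 bpm triangular
heart-rate excursions over a 7 bpm, 40 s-period oscillation whose crests
the 10 bpm default flags), `irene_like` (0.02 °C temperature excursions
over 25 s over a fast low-amplitude wave that makes 10 s-window trend
thresholds unusable, forcing the 25 s window). Event spacing (≥ 100 s)
keeps clip windows and separation constraints inactive at the defaults.

What passing tests on these sessions do **not** show: performance on real
recordings with respiratory sinus arrhythmia, motion-coupled artifacts
correlated across channels, non-stationary baselines, or ambiguous
human-labelled ground truth. The synthetic precision figures characterize
the pipeline's mechanics, not clinical performance.

## Problem sizes and numerical choices

Tests and the acceptance script use 600 s sessions (9 000 raw samples,
1 200 analysis steps) and parameter sweeps of 10–20 points — large enough
for every windowed rule to leave warm-up and for 5 events plus
distractors, while keeping the whole suite in seconds. Tailoring fits use
an event budget of N = 7 (the mid-range of the budgets used in practice,
5–10) with 5 embedded events, so an imprecise parameter set has room to
admit false positives and precision is informative. Degenerate inputs:
empty series are rejected with validation errors; windows shorter than
the data produce warm-up behaviour as described; even median windows are
rounded up to odd; ties in selection and matching always resolve to the
earlier time.

## Known limitations

- The batch pipeline mirrors a real-time-capable design (causal windows,
  trailing rules) but does not implement streaming execution.
- Valence (positive vs negative significance) is not classified; the
  score is a magnitude.
- The one-Euro stage at the published settings is effectively transparent
  at 2 Hz (cutoff far above Nyquist); whether it was originally applied
  before downsampling is unresolved, and both behaviours are reachable
  through the configuration.
- Long artifact plateaus can partially evade the three-standard-deviation
  flag rule (variance collapse) and leak residual excursions past repair;
  the quality rules catch the out-of-range and frozen cases but a
  plateau inside the physiological range survives.
- Grid-search tailoring finds the best candidate in a finite set; it does
  not optimize continuously, by design (determinism, and fidelity to the
  discrete manual iteration it automates).
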