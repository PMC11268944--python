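# Methods

This note documents the models, algorithms, defaults and design choices
behind `sdmkit`, and what the synthetic data used in its tests does and
does not represent.

## Data model and naming

A reading holds the complete record of one test session. Timestamps are
64-bit float seconds relative to the start of the reading: vendor epochs
and timezones are resolved at ingestion time, never inside the model.
Levels are the unit of processing; their ids are the ordered modality
values joined by `_` (a level with no modalities is called `main`).

Measure ids are generated from `(task, modalities, abbreviation,
aggregation)` with `-` as the field separator and `_` joining modality
values. `-` is therefore forbidden inside any part; `_` is allowed
(needed for multi-word modality values such as `symbol_to_digit`), which
means the mapping is injective only when modality values contain neither
separator — the practical naming discipline used by all built-in tests.

Flags use a fixed two-by-two taxonomy: domain `technical` (device or
recording problem) or `behavioral` (the subject did not perform the test
as instructed), and severity `deviation` (annotate, keep trusting) or
`invalidation` (keep the value, distrust it). Flags never remove
measures; filtering on `flag_count`/`flag_ids` is the analyst's call
downstream. An invalidation flag attached to an input propagates along
the processing graph to every derived dataset and measure.

## Pipeline engine

Pipelines are ordered lists of declared steps (`transform`, `extract`,
`flag`). Execution is declaration order, applied per level
independently; the provenance requirements drive three non-obvious
semantics:

- *Skip, don't raise*: a step whose declared inputs are missing on a
  level is recorded `skipped_missing_input`. Unsupervised recordings are
  routinely incomplete; missing data is a status, not an exception.
- *Stop flags are level-local*: a flag raised with `stopped_processing`
  aborts the remaining steps on that level only (`aborted_by_flag`).
  Levels are independent sub-task attempts; one corrupted attempt should
  not discard the session.
- *Frozen parameters*: step params are deep-copied at declaration, so
  the trace records the configuration that actually ran.

Cyclic input/output declarations are rejected before any step executes.
The trace is a `networkx` DiGraph with containment edges
(reading→level→raw dataset/context) and data-flow edges (input→step,
step→output); exports order nodes lexicographically so two identical
runs serialize identically.

## Signal processing defaults

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| sampling irregularity limit | 0.10 | std(Δt)/mean(Δt) | flags clock jitter an order above typical phone IMU jitter |
| max-gap limit | 1.5 | nominal periods | one dropped sample (gap = 2 periods) already trips it |
| orientation minimum | 0.5 g | — | gravity must dominate the expected axis |
| step band | 0.5–5 | Hz | locomotor band; cadences 30–300 steps/min |
| step prominence | 0.3 | m/s² | well below the ~1 m/s² vertical oscillation of walking |
| step separation | 0.25 | s | caps detection at 240 steps/min |
| turn rate threshold | 15 | °/s | separates turning from heading wander |
| turn minimum angle | 160 | ° | accepts U-turns, rejects corrections |
| too-short fraction | 0.8 | of protocol | < 80 % of the protocol invalidates duration-dependent measures |

All are overridable from a YAML config (CLI `--config`).

Numerical choices worth recording:

- **Zero-phase filtering** is a forward–backward Butterworth cascade,
  symmetrized by averaging with the filter of the time-reversed signal.
  The symmetrization makes the operation exactly invariant under time
  reversal (including edge transients), a property the test suite
  asserts at 1e-9.
- **Gravity** is the per-axis median of the 3-axis signal — robust to
  activity bursts, cheaper and more testable than a low-pass split.
- **Step detection** operates on the signed projection of
  gravity-removed acceleration onto the gravity axis, not on the
  Euclidean norm: the norm rectifies the vertical oscillation, which
  doubles the peak count of a sinusoidal vertical component. One impact
  peak per step survives in the signed projection.
- **Turn integration** uses the trapezoidal rule over each
  above-threshold run extended one sample into the surrounding
  below-threshold signal. The extension integrates the entry/exit ramps;
  without it a constant-rate turn loses half a sample of area at each
  boundary (a 2 s, 90°/s turn at 100 Hz would integrate to 179.1°
  instead of 180°).
- **Sway ellipse area** is π·χ²₀.₉₅,₂·√(λ₁λ₂), χ²₀.₉₅,₂ = 5.991, with
  λᵢ the eigenvalues of the demeaned (AP, ML) covariance. Eigenvalues
  are clipped at zero before the square root to absorb roundoff on
  degenerate (constant) input.
- **DTW** is the full unconstrained dynamic program with Euclidean local
  cost, path-averaged; both polylines are arc-length resampled first
  (default 100 points, hard cap 2000), which bounds the O(n²) cost and
  makes `sim` and `dtw_sim` commensurable.
- **Degenerate inputs**: fewer than 3 timestamps (sampling stats), < 5 s
  (step detection), < 10 s (sway), empty response logs and
  single-point drawing traces raise `InsufficientDataError` at the
  function level; inside pipelines the wrapping step converts this into
  a technical invalidation flag so the run continues.

## Test registry

The default build registers 16 evaluation codes: `sixmwt`, `utt`, `sbt`
(mobility, belt-worn device, gravity expected on +z), `draw`, `pinch`,
`cps`, `tap`, `typing`, `grip`, `sts` (handheld device), and six
questionnaires (`msis29`, `alsfrs_r`, `pdq39`, `mood`, `fatigue`,
`qol`). Tapping, typing, grip and sit-to-stand share one event-statistics
engine (count, rate, inter-event interval mean/CV) — their inputs are
one timestamp per repetition. Handedness and other modalities always
come from level metadata, never inferred from the signal.

Questionnaire scoring is declarative (YAML per instrument): items, range,
subscales, and one of two transforms — raw `sum`, or `scaled_0_100` =
100·(Σ − n·min)/((max − min)·n). MSIS-29 (29 items, 1–5; physical 1–20,
psychological 21–29), ALSFRS-R (12 items, 0–4, raw total) and PDQ-39
(39 items, 0–4, eight dimensions, summary index = mean of dimensions)
follow their published scoring; `mood`, `fatigue` and `qol` are generic
forms demonstrating that new instruments are data, not code. Both
transforms are monotone non-decreasing in every answer, which the suite
checks property-based.

## Synthetic data: what it emulates, what it does not

The generators produce canonical-format readings with a serialized
ground truth (true cadence, sway σ, turn angles, accuracy, answers,
seed, parameters):

- `gen_walk` — single vertical harmonic (A = 1 m/s², default cadence 108
  steps/min, 360 s, 100 Hz) plus white noise (σ = 0.05 m/s²) on all
  axes, gravity on +z. Not a biomechanical gait model: no stride
  asymmetry, no harmonics, no drift. Passing cadence-recovery tests
  shows the detection chain is correct, not that it is robust to
  pathological gait.
- `gen_sway` — iid Gaussian AP/ML acceleration (σ = 0.05 m/s², 60 s,
  100 Hz). Real sway is autocorrelated; the iid model is chosen because
  the 95 % ellipse area then has the closed form π·5.991·σ_AP·σ_ML
  against which the estimate is checked.
- `gen_turns` — piecewise-constant yaw rate; exact integral known.
- `gen_drawing` — reference shape (square, circle, spiral, lemniscate)
  resampled along arc length plus Gaussian jitter; a full session is the
  16-level protocol (4 shapes × 2 hands × 2 attempts).
- `gen_cps` — exactly round(p·n) correct trials, Gaussian reaction
  times clipped at 0.1 s.
- Corruption operators (`drop_samples`, `flip_orientation`, `truncate`,
  `shuffle_timestamps`) exercise each flag path end to end.

White noise, perfect clocks (until corrupted) and exact protocol
adherence are deliberate simplifications: the suite demonstrates
correctness of the measure definitions and of the
flagging/tracing machinery, not clinical validity of any measure.

## Problem sizes

The test-suite and acceptance runs use 60 s walks at 100 Hz (6 000
samples), 60 s sway recordings, and 10-seed sweeps per condition —
compact enough to iterate on while still giving the estimators realistic
sample counts per recording.

## Known limitations

- Walked distance is not estimated (needs a step-length model with
  anthropometrics); cadence and step-timing measures are reported
  instead.
- No sensor fusion: orientation checks use the raw gravity direction
  only; magnetometer and quaternion streams are out of scope.
- Vendor formats (proprietary JSON dialects, HDF5 exports) are not
  parsed; the canonical JSON dialect is the single ingestion format, and
  adapters are expected to target it.
- Flag thresholds are sensible defaults, not clinically validated
  cut-offs; any deployment should re-derive them from its own data.
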