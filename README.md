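# sdmkit

Traceable extraction of **sensor-derived measures (SDMs)** from structured
smartphone/wearable tests.

Clinical studies of neurodegenerative disease increasingly use structured
tests run on a phone or wearable — a six-minute walk with the device worn
on a belt, shapes drawn on the screen with either hand, a symbol–digit
substitution task, patient-reported questionnaires. Turning the raw
recordings into scalar outcome measures (cadence, sway ellipse area,
drawing accuracy, reaction time, questionnaire scores) requires more than
signal processing: measures need standard names that link back to what
produced them, a complete provenance trace, and systematic flagging of
the technical and behavioral problems that unsupervised recordings are
full of. `sdmkit` provides all of that for 16 structured tests (10 active
tests and 6 questionnaires) behind one data model, one pipeline engine
and one canonical JSON format, plus a synthetic-recording generator so
every pipeline is testable with known ground truth.

## Data model

A **reading** is one subject's one session of one test. Its sub-task
attempts are **levels**, keyed by **modalities** (e.g. `shape=square,
hand=right, attempt=first`); levels hold columnar timestamped
**datasets**, analysis windows (**epochs**), extracted **measures** and
quality **flags**. Measure ids are generated, never hand-written:

```
{task}-{modality values joined by _}-{abbreviation}[-{aggregation}]
e.g.  draw-square_right_first-sim-mean,  sixmwt-cadence
```

Flags follow `{task}-{domain}-{severity}-{name}` with domain ∈
{technical, behavioral} and severity ∈ {deviation, invalidation}. Flags
annotate — they never delete data — and an invalidation flag propagates
to every measure derived from the flagged input. Every processing run
emits a **data trace**: a DAG connecting raw datasets, processing steps
(with their frozen parameters), derived datasets, epochs and measures.

## Core algorithms

- **Walk (sixmwt)** — steps are local maxima of the zero-phase band-passed
  (0.5–5 Hz) vertical acceleration with prominence ≥ 0.3 m/s² and
  separation ≥ 0.25 s; cadence = 60·count/duration.
- **U-turn (utt)** — turns are intervals with |yaw rate| ≥ 15°/s whose
  trapezoidal integral reaches ≥ 160°; each becomes an epoch with signed
  angle, duration and peak rate.
- **Balance (sbt)** — postural sway: RMS AP/ML acceleration and the 95 %
  confidence ellipse area π·χ²₀.₉₅,₂·√(λ₁λ₂) of the (AP, ML) covariance
  eigenvalues, plus resultant jerk RMS.
- **Drawing (draw)** — trace and reference are arc-length resampled to a
  common grid; `sim` is the mean index-paired Euclidean distance,
  `dtw_sim` the DTW path-averaged distance (always ≤ `sim`).
- **Processing speed (cps)** — accuracy, reaction-time mean/median over
  correct trials, and RT drift (last third − first third).
- **Questionnaires** — MSIS-29, ALSFRS-R, PDQ-39 plus generic mood,
  fatigue and QoL forms, scored from declarative YAML configs.

## Worked example

```sh
sdmkit simulate sixmwt --seed 1 --out walk.json --truth truth.json
sdmkit process walk.json --out measures.csv --trace trace.json
```

`measures.csv` (abridged — the generated walk has cadence 108 steps/min):

```
subject_id,session_id,evaluation_code,level_id,measure_id,measure_name,value,unit,flag_count,flag_ids
subj001,sixmwt_001,sixmwt,main,sixmwt-cadence,cadence,108.00000000009823,steps/min,0,
subj001,sixmwt_001,sixmwt,main,sixmwt-step_time_cv,step time coefficient of variation,0.009432921551963902,,0,
subj001,sixmwt_001,sixmwt,main,sixmwt-steps,step count,648,,0,
```

The cadence row reads back the generator's ground truth (108 steps/min)
to within a fraction of a step per minute; `flag_count` is 0 because the
recording is clean. Corrupt it and the measures stay, annotated:

```sh
sdmkit simulate sixmwt --seed 1 --corrupt truncate --frac 0.1 --out short.json
sdmkit process short.json --out short.csv
# → same rows, flag_ids = sixmwt-behavioral-invalidation-too_short
```

`sdmkit list-tests` prints the 16 registered tests;
`sdmkit validate reading.json` schema-checks a document (the schema is
published at `src/sdmkit/schema.json`).

In Python:

```python
from sdmkit import default_registry, process
from sdmkit.synthetic import gen_walk

reading, truth = gen_walk(cadence=108, seed=1)
reading, trace = process(reading, default_registry().steps_for("sixmwt"))
print(reading.levels[0].measures["sixmwt-cadence"].value)  # 108.00000000009823
```

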