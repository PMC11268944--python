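"""Registry of structured tests and the pipelines that score them.

The default build registers 16 evaluation codes: 10 active tests
(cps, draw, pinch, tap, typing, grip, sixmwt, utt, sbt, sts) and 6
questionnaires (msis29, alsfrs_r, pdq39, mood, fatigue, qol).  Each
entry maps an evaluation code to a pipeline factory plus documentation
of the measures it can emit (id, name, unit), from which the registry
listing and the CLI docs are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import ConfigurationError, UnknownTestError
from .mobility import sbt_steps, sixmwt_steps, utt_steps
from .processing import ProcessingStep
from .questionnaires import load_instrument, questionnaire_steps
from .upperlimb import cps_steps, draw_steps, event_test_steps, pinch_steps

StepFactory = Callable[..., list[ProcessingStep]]


@dataclass(frozen=True)
class MeasureDoc:
    id: str
    name: str
    unit: str = ""


@dataclass(frozen=True)
class RegistryEntry:
    code: str
    category: str  # "test" | "questionnaire"
    factory: StepFactory
    measures: tuple[MeasureDoc, ...]

    def describe(self) -> dict:
        return {
            "code": self.code,
            "category": self.category,
            "n_measures": len(self.measures),
            "measures": [
                {"id": m.id, "name": m.name, "unit": m.unit}
                for m in self.measures
            ],
        }


class TestRegistry:
    """Evaluation-code → pipeline mapping with self-documentation."""

    def __init__(self):
        self._entries: dict[str, RegistryEntry] = {}

    def register(
        self,
        code: str,
        category: str,
        factory: StepFactory,
        measures: Sequence[MeasureDoc],
        thresholds: Thresholds = DEFAULT_THRESHOLDS,
    ) -> None:
        if code in self._entries:
            raise ConfigurationError(f"evaluation code {code!r} already registered")
        if category not in {"test", "questionnaire"}:
            raise ConfigurationError(f"bad category {category!r}")
        steps = factory(thresholds)
        if not any(s.kind == "extract" for s in steps):
            raise ConfigurationError(
                f"pipeline for {code!r} declares no extract step"
            )
        self._entries[code] = RegistryEntry(
            code, category, factory, tuple(measures)
        )

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def codes(self) -> list[str]:
        return sorted(self._entries)

    def entry(self, code: str) -> RegistryEntry:
        if code not in self._entries:
            raise UnknownTestError(
                f"unknown evaluation code {code!r}; registered: "
                f"{', '.join(self.codes()) or '(none)'}"
            )
        return self._entries[code]

    def steps_for(
        self, code: str, thresholds: Thresholds = DEFAULT_THRESHOLDS
    ) -> list[ProcessingStep]:
        return self.entry(code).factory(thresholds)

    def listing(self) -> list[dict]:
        return [self._entries[c].describe() for c in self.codes()]


def _questionnaire_docs(instrument: str) -> list[MeasureDoc]:
    config = load_instrument(instrument)
    docs = [
        MeasureDoc(f"{instrument}-{s.name}", f"{instrument} {s.name} score")
        for s in config.subscales
    ]
    if config.summary:
        docs.append(
            MeasureDoc(
                f"{instrument}-{config.summary_name}",
                f"{instrument} summary index",
            )
        )
    return docs


def _event_docs(task: str) -> list[MeasureDoc]:
    return [
        MeasureDoc(f"{task}-events", "event count"),
        MeasureDoc(f"{task}-rate", "event rate", "1/s"),
        MeasureDoc(f"{task}-iei-mean", "mean inter-event interval", "s"),
        MeasureDoc(f"{task}-iei_cv", "inter-event interval CV"),
    ]


def default_registry(
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> TestRegistry:
    """The default build: 16 structured tests, of which 6 questionnaires."""
    reg = TestRegistry()
    reg.register(
        "sixmwt", "test", sixmwt_steps,
        [
            MeasureDoc("sixmwt-steps", "step count"),
            MeasureDoc("sixmwt-cadence", "cadence", "steps/min"),
            MeasureDoc("sixmwt-step_time_cv", "step time CV"),
            MeasureDoc("sixmwt-cadence-min", "per-minute cadence min", "steps/min"),
            MeasureDoc("sixmwt-cadence-max", "per-minute cadence max", "steps/min"),
            MeasureDoc("sixmwt-cadence-mean", "per-minute cadence mean", "steps/min"),
        ],
        thresholds,
    )
    reg.register(
        "utt", "test", utt_steps,
        [
            MeasureDoc("utt-turns", "turn count"),
            MeasureDoc("utt-turn_angle-mean", "mean absolute turn angle", "rad"),
            MeasureDoc("utt-turn_duration-mean", "mean turn duration", "s"),
            MeasureDoc("utt-turn_peak_rate-mean", "mean peak turn rate", "rad/s"),
        ],
        thresholds,
    )
    reg.register(
        "sbt", "test", sbt_steps,
        [
            MeasureDoc("sbt-rms_ap", "RMS AP acceleration", "m/s^2"),
            MeasureDoc("sbt-rms_ml", "RMS ML acceleration", "m/s^2"),
            MeasureDoc("sbt-ellipse_area", "95% sway ellipse area", "(m/s^2)^2"),
            MeasureDoc("sbt-jerk_rms", "resultant jerk RMS", "m/s^3"),
        ],
        thresholds,
    )
    reg.register(
        "draw", "test", draw_steps,
        [
            MeasureDoc("draw-{shape}_{hand}_{attempt}-sim",
                       "mean distance to reference", "px"),
            MeasureDoc("draw-{shape}_{hand}_{attempt}-dtw_sim",
                       "DTW distance to reference", "px"),
            MeasureDoc("draw-{shape}_{hand}_{attempt}-duration",
                       "drawing duration", "s"),
        ],
        thresholds,
    )
    reg.register(
        "pinch", "test", pinch_steps,
        [
            MeasureDoc("pinch-attempts", "pinch attempts"),
            MeasureDoc("pinch-successes", "successful pinches"),
            MeasureDoc("pinch-success_rate", "pinch success rate"),
            MeasureDoc("pinch-inter_pinch_interval-mean",
                       "mean inter-pinch interval", "s"),
        ],
        thresholds,
    )
    reg.register(
        "cps", "test", cps_steps,
        [
            MeasureDoc("cps-correct", "correct responses"),
            MeasureDoc("cps-total", "total responses"),
            MeasureDoc("cps-accuracy", "response accuracy"),
            MeasureDoc("cps-rt-mean", "mean reaction time", "s"),
            MeasureDoc("cps-rt-median", "median reaction time", "s"),
            MeasureDoc("cps-rt_drift", "reaction-time drift", "s"),
        ],
        thresholds,
    )
    for task in ("tap", "typing", "grip", "sts"):
        reg.register(
            task, "test", event_test_steps(task), _event_docs(task), thresholds
        )
    for instrument in ("msis29", "alsfrs_r", "pdq39", "mood", "fatigue", "qol"):
        reg.register(
            instrument, "questionnaire", questionnaire_steps(instrument),
            _questionnaire_docs(instrument), thresholds,
        )
    return reg
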