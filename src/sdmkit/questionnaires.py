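"""Patient-reported outcome (questionnaire) scoring.

Scoring rules are data, not code: each instrument ships as a YAML config
(``instruments/*.yaml``) declaring its items, per-item range, subscales
and summary rule.  Two transforms cover the supported instruments:

* ``sum`` — raw sum of the subscale items;
* ``scaled_0_100`` — 100 * (sum - n * min) / ((max - min) * n), i.e. the
  subscale rescaled so the floor maps to 0 and the ceiling to 100.

Bundled instruments: MSIS-29 (29 items, 1–5; physical items 1–20,
psychological 21–29, both scaled 0–100), ALSFRS-R (12 items, 0–4, raw
total 0–48), PDQ-39 (39 items, 0–4; eight dimensions scaled 0–100 and a
summary index = mean of the dimension scores), plus generic mood,
fatigue and quality-of-life forms scored with the same engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import yaml

from .model import (
    Level,
    MeasureValue,
    Reading,
    ValueDefinition,
)
from .processing import ProcessingStep

TRANSFORMS = {"sum", "scaled_0_100"}


@dataclass(frozen=True)
class Subscale:
    name: str
    items: tuple[int, ...]  # 1-based item indices
    transform: str

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass(frozen=True)
class QuestionnaireConfig:
    """Declarative scoring configuration for one instrument."""

    instrument: str
    n_items: int
    item_min: float
    item_max: float
    subscales: tuple[Subscale, ...]
    #: "mean_of_subscales" adds a summary index averaging all subscale
    #: scores (PDQ-39 style); None emits subscales only
    summary: Optional[str] = None
    summary_name: str = "summary_index"

    def __post_init__(self):
        for sub in self.subscales:
            bad = [i for i in sub.items if not 1 <= i <= self.n_items]
            if bad:
                raise ValueError(
                    f"{self.instrument}/{sub.name}: item indices {bad} out of "
                    f"range 1..{self.n_items}"
                )


def score_questionnaire(
    config: QuestionnaireConfig, answers: Sequence[float]
) -> dict[str, float]:
    """Score one instrument; returns {subscale name: score}.

    Answers must cover every item and lie within the declared range.
    Every transform is monotone non-decreasing in every answer.
    """
    if len(answers) != config.n_items:
        raise ValueError(
            f"{config.instrument}: expected {config.n_items} answers, "
            f"got {len(answers)}"
        )
    for idx, a in enumerate(answers, start=1):
        if not config.item_min <= a <= config.item_max:
            raise ValueError(
                f"{config.instrument}: answer {a!r} to item {idx} outside "
                f"[{config.item_min}, {config.item_max}]"
            )
    scores: dict[str, float] = {}
    for sub in config.subscales:
        vals = [answers[i - 1] for i in sub.items]
        total = float(sum(vals))
        n = len(vals)
        if sub.transform == "sum":
            scores[sub.name] = total
        else:  # scaled_0_100
            span = (config.item_max - config.item_min) * n
            scores[sub.name] = 100.0 * (total - config.item_min * n) / span
    if config.summary == "mean_of_subscales":
        scores[config.summary_name] = sum(
            scores[s.name] for s in config.subscales
        ) / len(config.subscales)
    return scores


def load_instrument(instrument: str) -> QuestionnaireConfig:
    """Load a bundled instrument config by id (e.g. "msis29")."""
    ref = resources.files("sdmkit").joinpath(f"instruments/{instrument}.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return QuestionnaireConfig(
        instrument=doc["instrument"],
        n_items=int(doc["n_items"]),
        item_min=float(doc["item_min"]),
        item_max=float(doc["item_max"]),
        subscales=tuple(
            Subscale(s["name"], tuple(s["items"]), s["transform"])
            for s in doc["subscales"]
        ),
        summary=doc.get("summary"),
        summary_name=doc.get("summary_name", "summary_index"),
    )


def _questionnaire_extract_factory(config: QuestionnaireConfig):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets["answers"]
        order = ds["item"]
        by_item = dict(zip((int(i) for i in order), ds["answer"]))
        answers = [float(by_item[i]) for i in sorted(by_item)]
        scores = score_questionnaire(config, answers)
        return [
            MeasureValue(
                ValueDefinition(
                    f"{config.instrument}-{name}",
                    f"{config.instrument} {name} score",
                    "",
                ),
                value,
            )
            for name, value in scores.items()
        ]

    return func


def questionnaire_steps(instrument: str):
    """Pipeline factory scoring one instrument from an 'answers' dataset
    (columns ts, item, answer)."""

    def factory(thresholds=None) -> list[ProcessingStep]:
        config = load_instrument(instrument)
        return [
            ProcessingStep(
                "score", "extract", _questionnaire_extract_factory(config),
                input_ids=["answers"],
                output_ids=[f"{instrument}-{s.name}" for s in config.subscales],
                params={"instrument": instrument},
            ),
        ]

    return factory
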