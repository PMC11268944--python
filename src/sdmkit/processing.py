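"""Declarative processing-step pipeline with a full data trace.

A pipeline is an ordered list of :class:`ProcessingStep`.  Steps declare
their inputs (dataset/measure ids within a level, or ``context:<key>``
entries) and outputs, so the runner can

* check the declarations are acyclic before executing anything,
* skip a step whose inputs are absent on a level (incomplete data never
  raises),
* stop processing a level after a ``stopped_processing`` flag, and
* record every entity and step in a data trace DAG connecting raw
  datasets, derived datasets, epochs and measures.

Execution order is declaration order, applied per level independently.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import networkx as nx

from .errors import ConfigurationError
from .model import (
    Flag,
    FlagTarget,
    Level,
    LevelEpoch,
    MeasureValue,
    RawDataSet,
    Reading,
    attach_flag,
)

STATUS_COMPLETED = "completed"
STATUS_SKIPPED = "skipped_missing_input"
STATUS_ABORTED = "aborted_by_flag"

StepFunc = Callable[[Level, Reading, dict], Sequence[Any]]
LevelPredicate = Callable[[Level], bool]


def modality_predicate(**dimensions: str) -> LevelPredicate:
    """Predicate matching levels whose modalities include every given
    dimension=value pair (e.g. ``modality_predicate(hand="left")``)."""

    def predicate(level: Level) -> bool:
        return all(
            level.modality_value(dim) == val for dim, val in dimensions.items()
        )

    return predicate


@dataclass
class ProcessingStep:
    """One declared pipeline step.

    ``kind`` is ``transform`` (datasets in, derived dataset out),
    ``extract`` (datasets/measures in, measures and epochs out) or
    ``flag`` (quality check emitting zero or more flags).  ``params`` is
    deep-copied at construction so the trace reflects the configuration
    at run time even if the caller later mutates its dict.
    """

    step_id: str
    kind: str
    func: StepFunc
    input_ids: list[str] = field(default_factory=list)
    output_ids: list[str] = field(default_factory=list)
    level_filter: Optional[LevelPredicate] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in {"transform", "extract", "flag"}:
            raise ConfigurationError(f"unknown step kind {self.kind!r}")
        self.params = copy.deepcopy(self.params)

    def matches(self, level: Level) -> bool:
        return self.level_filter is None or self.level_filter(level)


class DataTrace:
    """DAG connecting readings, levels, datasets, epochs, measures, steps.

    Node ids are stable strings like ``dataset:left/acc`` or
    ``step:left/detect_steps``.  Edges carry a ``relation`` attribute:
    ``contains`` for structural containment, ``input``/``output`` for
    step data flow.
    """

    def __init__(self):
        self.graph = nx.DiGraph()

    # -- node helpers -------------------------------------------------
    @staticmethod
    def node_id(kind: str, level_id: Optional[str] = None, item: str = "") -> str:
        if kind == "reading":
            return "reading"
        if kind == "level":
            return f"level:{level_id}"
        return f"{kind}:{level_id}/{item}"

    def add_entity(self, kind: str, level_id=None, item="", **attrs) -> str:
        nid = self.node_id(kind, level_id, item)
        self.graph.add_node(nid, kind=kind, **attrs)
        return nid

    def add_edge(self, src: str, dst: str, relation: str) -> None:
        self.graph.add_edge(src, dst, relation=relation)

    # -- queries ------------------------------------------------------
    def step_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "step"
        )

    def measure_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "measure"
        )

    def raw_dataset_nodes(self) -> list[str]:
        return sorted(
            n
            for n, d in self.graph.nodes(data=True)
            if d["kind"] == "dataset" and not d.get("derived", False)
        )

    def context_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "context"
        )

    def status(self, step_node: str) -> str:
        return self.graph.nodes[step_node]["status"]

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def measure_sources(self, measure_node: str) -> set[str]:
        """Raw-dataset and context ancestors of a measure node."""
        ancestors = nx.ancestors(self.graph, measure_node)
        roots = set(self.raw_dataset_nodes()) | set(self.context_nodes())
        return ancestors & roots

    # -- export -------------------------------------------------------
    def export(self) -> dict:
        """Adjacency structure with deterministic (lexicographic) order."""
        nodes = [
            {"id": n, **{k: v for k, v in sorted(d.items())}}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        edges = [
            {"source": u, "target": v, "relation": d["relation"]}
            for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: e[:2])
        ]
        return {"nodes": nodes, "edges": edges}

    def to_dot(self) -> str:
        shapes = {
            "reading": "folder",
            "level": "tab",
            "dataset": "cylinder",
            "context": "note",
            "epoch": "component",
            "measure": "ellipse",
            "step": "box",
        }
        lines = ["digraph data_trace {", "  rankdir=LR;"]
        for n, d in sorted(self.graph.nodes(data=True)):
            label = n.replace('"', "'")
            extra = ""
            if d["kind"] == "step":
                extra = f"\\n[{d.get('status', '')}]"
            lines.append(
                f'  "{n}" [shape={shapes[d["kind"]]}, label="{label}{extra}"];'
            )
        for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: e[:2]):
            style = "dashed" if d["relation"] == "contains" else "solid"
            lines.append(f'  "{u}" -> "{v}" [style={style}];')
        lines.append("}")
        return "\n".join(lines)


def export_trace(trace: DataTrace) -> dict:
    """JSON-ready node/edge lists in deterministic order."""
    return trace.export()


def filter_levels(reading: Reading, predicate: LevelPredicate) -> list[Level]:
    """Levels matching ``predicate``, in reading order; may be empty."""
    return [lv for lv in reading.levels if predicate(lv)]


def _check_acyclic_declarations(steps: Sequence[ProcessingStep]) -> None:
    g = nx.DiGraph()
    for s in steps:
        g.add_node(s.step_id)
    for s1 in steps:
        for s2 in steps:
            if s1 is s2:
                continue
            if set(s1.output_ids) & set(s2.input_ids):
                g.add_edge(s1.step_id, s2.step_id)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    raise ConfigurationError(
        f"cyclic step declarations: {' -> '.join(u for u, _ in cycle)}"
    )


def _init_trace(reading: Reading) -> DataTrace:
    trace = DataTrace()
    rnode = trace.add_entity("reading")
    for lv in reading.levels:
        lnode = trace.add_entity("level", lv.id)
        trace.add_edge(rnode, lnode, "contains")
        for ds_id in sorted(lv.datasets):
            dnode = trace.add_entity("dataset", lv.id, ds_id, derived=False)
            trace.add_edge(lnode, dnode, "contains")
        for key in sorted(lv.context):
            cnode = trace.add_entity("context", lv.id, key)
            trace.add_edge(lnode, cnode, "contains")
    return trace


def _input_available(level: Level, input_id: str) -> bool:
    if input_id.startswith("context:"):
        return input_id.split(":", 1)[1] in level.context
    return input_id in level.datasets or input_id in level.measures


def _invalidation_flags(reading: Reading, level: Level, input_ids) -> list[Flag]:
    """Invalidation flags attached to any of the step's inputs (or the
    level itself); measures extracted from them inherit the reference."""
    hits: list[Flag] = []
    for f in reading.flags:
        if f.severity != "invalidation":
            continue
        for t in f.targets:
            if t.level_id != level.id:
                continue
            if t.kind == "level" or (
                t.kind == "dataset" and t.item_id in input_ids
            ) or (t.kind == "measure" and t.item_id in input_ids):
                if f not in hits:
                    hits.append(f)
    return hits


def process(
    reading: Reading, steps: Sequence[ProcessingStep]
) -> tuple[Reading, DataTrace]:
    """Run a pipeline over a reading; return it augmented plus its trace.

    Steps run in declaration order on every level matching their filter.
    A step whose declared inputs are absent on a level is recorded as
    ``skipped_missing_input`` and does not raise.  A flag raised with
    ``stopped_processing=True`` aborts the remaining steps on that level
    only (``aborted_by_flag``).  Raw data are never mutated; transforms
    add new datasets, extracts add measures/epochs, flags annotate.
    """
    _check_acyclic_declarations(steps)
    trace = _init_trace(reading)
    for level in reading.levels:
        lnode = trace.node_id("level", level.id)
        aborted = False
        for step in steps:
            if not step.matches(level):
                continue
            snode = trace.add_entity(
                "step", level.id, step.step_id,
                step_kind=step.kind, params=copy.deepcopy(step.params),
                status=STATUS_COMPLETED,
            )
            trace.add_edge(lnode, snode, "contains")
            for input_id in step.input_ids:
                if input_id.startswith("context:"):
                    inode = trace.node_id(
                        "context", level.id, input_id.split(":", 1)[1]
                    )
                elif input_id in level.measures:
                    inode = trace.node_id("measure", level.id, input_id)
                else:
                    inode = trace.node_id("dataset", level.id, input_id)
                if inode in trace.graph:
                    trace.add_edge(inode, snode, "input")
            if aborted:
                trace.graph.nodes[snode]["status"] = STATUS_ABORTED
                continue
            if not all(_input_available(level, i) for i in step.input_ids):
                trace.graph.nodes[snode]["status"] = STATUS_SKIPPED
                continue

            outputs = step.func(level, reading, step.params) or []
            # invalidation flags on inputs propagate to everything produced
            inherited = _invalidation_flags(reading, level, set(step.input_ids))
            for out in outputs:
                if isinstance(out, RawDataSet):
                    level.add_dataset(out)
                    dnode = trace.add_entity(
                        "dataset", level.id, out.id, derived=True
                    )
                    trace.add_edge(snode, dnode, "output")
                    for f in inherited:
                        target = FlagTarget("dataset", level.id, out.id)
                        if target not in f.targets:
                            f.targets.append(target)
                        attach_flag(reading, f)
                elif isinstance(out, MeasureValue):
                    level.measures.add(out)
                    mnode = trace.add_entity("measure", level.id, out.id)
                    trace.add_edge(snode, mnode, "output")
                    for f in inherited:
                        target = FlagTarget("measure", level.id, out.id)
                        if target not in f.targets:
                            f.targets.append(target)
                        attach_flag(reading, f)
                elif isinstance(out, LevelEpoch):
                    level.epochs.append(out)
                    enode = trace.add_entity(
                        "epoch", level.id, str(len(level.epochs) - 1)
                    )
                    trace.add_edge(snode, enode, "output")
                elif isinstance(out, Flag):
                    if not out.targets:
                        out.targets.append(FlagTarget("level", level.id))
                    attach_flag(reading, out)
                    if out.stopped_processing:
                        aborted = True
                else:  # pragma: no cover - defensive
                    raise TypeError(
                        f"step {step.step_id!r} produced {type(out).__name__}"
                    )
    return reading, trace
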