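"""Pipeline semantics: filtering, skipping, aborting, tracing."""

import pytest

from sdmkit.errors import ConfigurationError
from sdmkit.model import Flag, MeasureValue, Modality, ValueDefinition
from sdmkit.processing import (
    ProcessingStep,
    export_trace,
    filter_levels,
    modality_predicate,
    process,
)

from conftest import make_dataset, make_reading


def extract_step(step_id="extract", input_ids=("data",), measure_id="tap-x"):
    def func(level, reading, params):
        return [MeasureValue(ValueDefinition(measure_id, measure_id), 1.0)]

    return ProcessingStep(step_id, "extract", func,
                          input_ids=list(input_ids), output_ids=[measure_id])


def transform_step(step_id="transform", input_id="data", output_id="derived"):
    def func(level, reading, params):
        ds = level.datasets[input_id]
        return [make_dataset(output_id, ds.timestamps.tolist(),
                             (ds["v"] * 2).tolist())]

    return ProcessingStep(step_id, "transform", func,
                          input_ids=[input_id], output_ids=[output_id])


def two_hand_reading():
    return make_reading(
        n_levels=2,
        modalities=[[Modality("hand", "right")], [Modality("hand", "left")]],
        datasets=[[make_dataset()], [make_dataset()]],
    )


class TestProcess:
    def test_level_filter_executes_on_matching_levels_only(self):
        r = two_hand_reading()
        step = extract_step()
        step.level_filter = modality_predicate(hand="right")
        r, trace = process(r, [step])
        assert "tap-x" in r.get_level("right").measures
        assert "tap-x" not in r.get_level("left").measures
        assert trace.step_nodes() == ["step:right/extract"]

    def test_missing_input_skips_without_raising(self):
        r = make_reading()
        step = extract_step(input_ids=["absent"])
        r, trace = process(r, [step])
        assert len(r.levels[0].measures) == 0
        assert trace.status("step:level0/extract") == "skipped_missing_input"

    def test_trace_path_raw_transform_derived_extract_measure(self):
        r = make_reading()
        steps = [transform_step(),
                 extract_step(input_ids=["derived"], measure_id="tap-y")]
        r, trace = process(r, steps)
        import networkx as nx

        path = nx.shortest_path(
            trace.graph, "dataset:level0/data", "measure:level0/tap-y"
        )
        assert path == [
            "dataset:level0/data", "step:level0/transform",
            "dataset:level0/derived", "step:level0/extract",
            "measure:level0/tap-y",
        ]

    def test_cyclic_declarations_rejected_before_execution(self):
        executed = []

        def func(level, reading, params):
            executed.append(1)
            return []

        s1 = ProcessingStep("a", "transform", func, input_ids=["x"],
                            output_ids=["y"])
        s2 = ProcessingStep("b", "transform", func, input_ids=["y"],
                            output_ids=["x"])
        with pytest.raises(ConfigurationError, match="cyclic"):
            process(make_reading(), [s1, s2])
        assert not executed

    def test_stop_flag_aborts_flagged_level_only(self):
        r = two_hand_reading()

        def flag_func(level, reading, params):
            if level.id == "right":
                return [Flag("tap-technical-invalidation-dead", "broken",
                             stopped_processing=True)]
            return []

        steps = [
            ProcessingStep("check", "flag", flag_func, input_ids=["data"]),
            extract_step(),
        ]
        r, trace = process(r, steps)
        assert trace.status("step:right/extract") == "aborted_by_flag"
        assert trace.status("step:left/extract") == "completed"
        assert "tap-x" in r.get_level("left").measures
        assert "tap-x" not in r.get_level("right").measures

    def test_invalidation_flag_propagates_to_downstream_measures(self):
        r = make_reading()

        def flag_func(level, reading, params):
            from sdmkit.model import FlagTarget

            return [Flag("tap-behavioral-invalidation-bad", "r",
                         targets=[FlagTarget("dataset", level.id, "data")])]

        steps = [
            ProcessingStep("check", "flag", flag_func, input_ids=["data"]),
            transform_step(),
            extract_step(input_ids=["derived"], measure_id="tap-y"),
        ]
        r, _ = process(r, steps)
        m = r.levels[0].measures["tap-y"]
        assert "tap-behavioral-invalidation-bad" in m.flag_ids

    def test_determinism_identical_runs(self):
        steps = [transform_step(), extract_step(input_ids=["derived"])]
        r1, t1 = process(make_reading(), steps)
        r2, t2 = process(make_reading(), steps)
        assert r1.levels[0].measures.ids() == r2.levels[0].measures.ids()
        assert export_trace(t1) == export_trace(t2)

    def test_raw_data_never_mutated(self):
        r = make_reading()
        before = r.levels[0].datasets["data"].content_hash()
        process(r, [transform_step(), extract_step(input_ids=["derived"])])
        assert r.levels[0].datasets["data"].content_hash() == before

    def test_deleting_any_raw_dataset_never_raises(self, registry):
        """Skip-safety: removing the raw dataset converts dependent steps
        to skipped, with no exception."""
        from sdmkit.synthetic import generate

        for code in registry.codes():
            r, _ = generate(code, seed=0)
            for level in r.levels:
                level.datasets.clear()
            r, trace = process(r, registry.steps_for(code))
            statuses = {trace.status(s) for s in trace.step_nodes()}
            assert statuses <= {"skipped_missing_input"}


class TestFilterLevels:
    def test_hand_filter_on_full_drawing_session(self):
        from sdmkit.synthetic import gen_drawing

        r, _ = gen_drawing(shape=None, seed=0)
        assert len(r.levels) == 16
        left = filter_levels(r, modality_predicate(hand="left"))
        assert len(left) == 8

    def test_trivial_predicates(self):
        r = two_hand_reading()
        assert filter_levels(r, lambda lv: True) == r.levels
        assert filter_levels(r, lambda lv: False) == []


class TestExportTrace:
    def test_empty_pipeline_entities_only(self):
        r = make_reading()
        _, trace = process(r, [])
        exported = export_trace(trace)
        kinds = {n["kind"] for n in exported["nodes"]}
        assert "step" not in kinds
        assert {"reading", "level", "dataset"} <= kinds

    def test_single_extract_step_degrees(self):
        r = make_reading()
        _, trace = process(r, [extract_step()])
        snode = "step:level0/extract"
        in_edges = [e for e in trace.graph.in_edges(snode, data=True)
                    if e[2]["relation"] == "input"]
        out_edges = list(trace.graph.out_edges(snode))
        assert len(in_edges) == 1  # one declared input
        assert len(out_edges) == 1  # one measure produced

    def test_any_completed_run_is_acyclic(self, registry):
        from sdmkit.synthetic import generate

        for code in ("sixmwt", "draw", "msis29"):
            r, _ = generate(code, seed=3)
            _, trace = process(r, registry.steps_for(code))
            assert trace.is_acyclic()

    def test_export_deterministic_order_and_dot(self):
        r = make_reading()
        _, trace = process(r, [extract_step()])
        exported = export_trace(trace)
        ids = [n["id"] for n in exported["nodes"]]
        assert ids == sorted(ids)
        dot = trace.to_dot()
        assert dot.startswith("digraph") and "step:level0/extract" in dot
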