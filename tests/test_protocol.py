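import json
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import fishtrack
from fishtrack import synthfish
from fishtrack.estimators import VigorConfig, fish_velocity, grating_velocity, vigor
from fishtrack.protocol import (
    ExperimentRecord,
    ParamTree,
    ProtocolSpec,
    SimulatedClock,
    Stimulus,
    combine,
    conditional,
    load_record,
    run_protocol,
    save_record,
)


def pause_flash_protocol():
    return ProtocolSpec(
        name="pause_flash",
        stimuli=(
            Stimulus("pause", 9.0, params={"luminance": 0.0}),
            Stimulus("flash", 1.0, params={"luminance": 1.0}),
        ),
    )


class TestRunProtocol:
    def test_pause_then_flash_single_transition_at_9s(self):
        record = run_protocol(pause_flash_protocol(), SimulatedClock(Fraction(1, 60)))
        starts = record.stimulus_log[record.stimulus_log.event == "start"]
        assert list(starts.stimulus) == ["pause", "flash"]
        assert starts.t.tolist() == [0.0, 9.0]   # exact, no jitter
        end = record.stimulus_log[record.stimulus_log.event == "protocol_end"]
        assert end.t.tolist() == [10.0]

    def test_record_duration_equals_sum_of_durations(self):
        spec = ProtocolSpec("p", (Stimulus("a", 1.25), Stimulus("b", 2.5),
                                  Stimulus("c", 0.25)))
        record = run_protocol(spec, SimulatedClock(Fraction(1, 100)))
        assert record.metadata["run"]["total_duration"] == 4.0
        assert record.stimulus_log.t.iloc[-1] == 4.0

    def test_start_fires_once_per_stimulus(self):
        calls = []
        spec = ProtocolSpec("p", (
            Stimulus("a", 0.5, on_start=lambda s, c: calls.append(("a", c.t))),
            Stimulus("b", 0.5, on_start=lambda s, c: calls.append(("b", c.t))),
        ))
        run_protocol(spec, SimulatedClock(Fraction(1, 20)))
        assert calls == [("a", 0.0), ("b", 0.5)]

    def test_update_runs_every_tick_incoming_only(self):
        ticks = {"a": 0, "b": 0}

        def count(stim, ctx):
            ticks[stim.name] += 1

        spec = ProtocolSpec("p", (
            Stimulus("a", 0.5, on_update=count),
            Stimulus("b", 0.25, on_update=count),
        ))
        run_protocol(spec, SimulatedClock(Fraction(1, 20)))
        # 0.5 s at 20 Hz = ticks 0..9 for a; 0.25 s = ticks 10..14 for b
        assert ticks == {"a": 10, "b": 5}

    def test_hook_exception_aborts_with_partial_record(self):
        def bomb(t, stim, ctx):
            if t >= 0.2:
                raise RuntimeError("boom")

        record = run_protocol(
            ProtocolSpec("p", (Stimulus("a", 1.0),)),
            SimulatedClock(Fraction(1, 10)), update_hook=bomb,
        )
        assert record.aborted
        assert record.metadata["run"]["aborted"] is True
        assert len(record.stimulus_log) > 0

    def test_two_runs_byte_identical(self, tmp_path):
        logs = []
        for run_dir in ("a", "b"):
            record = run_protocol(pause_flash_protocol(),
                                  SimulatedClock(Fraction(1, 60)))
            files = save_record(record, tmp_path / run_dir / "rec", format="csv")
            logs.append(b"".join(sorted(p.read_bytes() for p in files)))
        assert logs[0] == logs[1]

    def test_dynamic_grating_matches_estimator_law(self):
        # closed-loop grating driven by a pre-recorded vigor trace must log
        # velocities equal to the estimator-module law, sample for sample
        fs = 60.0
        cfg = VigorConfig(window=0.05, vigor_scale=30.0, swim_threshold=0.05)
        _, curv = synthfish.generate_bout_train([0.3, 1.2], 20.0, 0.8, 0.25, fs, 2.0)
        vig = vigor(curv, fs, cfg)

        def stream(t):
            return {"vigor": float(vig[min(int(round(t * fs)), len(vig) - 1)])}

        def update(stim, ctx):
            v_fish = fish_velocity(ctx.estimator["vigor"], cfg)
            stim.params["velocity"] = grating_velocity(10.0, v_fish, 1.0)

        grating = Stimulus("grating", 2.0, params={"velocity": 10.0},
                           dynamic=True, on_update=update)
        record = run_protocol(ProtocolSpec("cl", (grating,)),
                              SimulatedClock(Fraction(1, 60)),
                              estimator_stream=stream)
        updates = record.stimulus_log[record.stimulus_log.event == "update"]
        expected = [
            grating_velocity(10.0, fish_velocity(stream(t)["vigor"], cfg), 1.0)
            for t in updates.t
        ]
        assert np.allclose(updates.param_velocity.to_numpy(), expected)

    def test_protocol_requires_stimuli(self):
        with pytest.raises(ValueError):
            ProtocolSpec("empty", ())


class TestCombine:
    def test_singleton_identity(self):
        s = Stimulus("a", 1.0, params={"k": 1})
        both = [run_protocol(ProtocolSpec("p", (stim,)), SimulatedClock(Fraction(1, 10)))
                for stim in (s, combine([Stimulus("a", 1.0, params={"k": 1})]))]
        a, b = (r.stimulus_log for r in both)
        assert list(a.t) == list(b.t)
        assert list(a.event) == list(b.event)

    def test_two_constant_stimuli_both_logged(self):
        comp = combine([
            Stimulus("s1", 0.5, params={"p": 1}),
            Stimulus("s2", 0.5, params={"q": 2}),
        ])
        record = run_protocol(ProtocolSpec("p", (comp,)),
                              SimulatedClock(Fraction(1, 10)))
        start = record.stimulus_log[record.stimulus_log.event == "start"].iloc[0]
        assert start["param_s1.p"] == 1
        assert start["param_s2.q"] == 2

    def test_nested_combine_flattens(self):
        def mk():
            return [Stimulus("a", 1.0, params={"x": 1}),
                    Stimulus("b", 1.0, params={"y": 2}),
                    Stimulus("c", 1.0, params={"z": 3})]

        a, b, c = mk()
        nested = combine([combine([a, b]), c])
        a2, b2, c2 = mk()
        flat = combine([a2, b2, c2])
        r1 = run_protocol(ProtocolSpec("p", (nested,)), SimulatedClock(Fraction(1, 5)))
        r2 = run_protocol(ProtocolSpec("p", (flat,)), SimulatedClock(Fraction(1, 5)))
        pd.testing.assert_frame_equal(r1.stimulus_log, r2.stimulus_log)

    def test_empty_combine_raises(self):
        with pytest.raises(ValueError):
            combine([])

    def test_mismatched_durations_raise(self):
        with pytest.raises(ValueError):
            combine([Stimulus("a", 1.0), Stimulus("b", 2.0)])


class TestConditional:
    def test_always_false_matches_else_branch(self):
        log_if, log_else = [], []
        cond = conditional(
            Stimulus("yes", 1.0, on_update=lambda s, c: log_if.append(c.t)),
            Stimulus("no", 1.0, on_update=lambda s, c: log_else.append(c.t)),
            predicate=lambda est: False,
        )
        run_protocol(ProtocolSpec("p", (cond,)), SimulatedClock(Fraction(1, 10)),
                     estimator_stream=lambda t: {"swimming": False})
        assert log_if == []
        assert len(log_else) == 10

    def test_branch_switches_follow_bout_windows(self):
        fs = 60.0
        cfg = VigorConfig(window=0.05, swim_threshold=0.05)
        starts = [0.4, 1.4]
        _, curv = synthfish.generate_bout_train(starts, 20.0, 0.8, 0.3, fs, 2.2)
        vig = vigor(curv, fs, cfg)

        def stream(t):
            i = min(int(round(t * fs)), len(vig) - 1)
            return {"vigor": float(vig[i])}

        cond = conditional(
            Stimulus("swim", 2.2), Stimulus("rest", 2.2),
            predicate=lambda est: est["vigor"] >= cfg.swim_threshold,
        )
        record = run_protocol(ProtocolSpec("p", (cond,)),
                              SimulatedClock(Fraction(1, 60)),
                              estimator_stream=stream)
        updates = record.stimulus_log[record.stimulus_log.event == "update"]
        swim_ticks = updates[updates.param_branch == "swim"].t.to_numpy()
        truth = np.zeros(len(vig), dtype=bool)
        t_axis = np.arange(len(vig)) / fs
        for s in starts:
            truth |= (t_axis >= s) & (t_axis < s + 0.3 + cfg.window)
        got = np.zeros(len(vig), dtype=bool)
        got[np.round(swim_ticks * fs).astype(int)] = True
        # agreement within one tick at each boundary
        assert (got != truth).sum() <= 2 * 2 * len(starts)

    def test_alternating_predicate_logged_every_tick(self):
        flips = {"n": 0}

        def pred(est):
            flips["n"] += 1
            return flips["n"] % 2 == 0

        cond = conditional(Stimulus("a", 0.5), Stimulus("b", 0.5), pred)
        record = run_protocol(ProtocolSpec("p", (cond,)),
                              SimulatedClock(Fraction(1, 20)),
                              estimator_stream=lambda t: {})
        updates = record.stimulus_log[record.stimulus_log.event == "update"]
        assert list(updates.param_branch) == ["b", "a"] * 5

    def test_missing_estimator_stream_aborts(self):
        cond = conditional(Stimulus("a", 0.5), Stimulus("b", 0.5), lambda e: True)
        record = run_protocol(ProtocolSpec("p", (cond,)),
                              SimulatedClock(Fraction(1, 10)))
        assert record.aborted


class TestParamTree:
    def test_set_get_nested(self):
        tree = ParamTree()
        tree.set("a/b/c", 3)
        assert tree.get("a/b/c") == 3
        assert tree.contains("a/b")

    def test_access_recorded(self):
        tree = ParamTree({"x": {"y": 1}})
        tree.get("x/y")
        tree.get("z", default=5)
        assert tree.accessed == {"x/y", "z"}

    def test_default_registers_value(self):
        tree = ParamTree()
        assert tree.get("p/q", default=7) == 7
        assert tree.to_dict()["p"]["q"] == 7

    def test_missing_without_default_raises(self):
        with pytest.raises(KeyError):
            ParamTree().get("nope")


class TestSaveLoad:
    def make_record(self, rng):
        df = pd.DataFrame({
            "t": np.arange(1000) / 300.0,
            "theta_00": rng.normal(size=1000),
            "theta_01": rng.normal(size=1000),
            "valid": np.ones(1000, dtype=bool),
        })
        record = run_protocol(pause_flash_protocol(), SimulatedClock(Fraction(1, 60)))
        record.tracking_log = df
        return record

    def test_hdf5_round_trip_bit_identical(self, tmp_path, rng):
        record = self.make_record(rng)
        save_record(record, tmp_path / "rec", format="hdf5")
        back = load_record(tmp_path / "rec", format="hdf5")
        for col in record.tracking_log.columns:
            a = record.tracking_log[col].to_numpy()
            b = back.tracking_log[col].to_numpy()
            if a.dtype.kind == "f":
                assert np.array_equal(a, b)   # bit-exact
            else:
                assert list(a) == list(b)

    def test_csv_round_trip_within_tolerance(self, tmp_path, rng):
        record = self.make_record(rng)
        save_record(record, tmp_path / "rec", format="csv")
        back = load_record(tmp_path / "rec", format="csv")
        a = record.tracking_log.theta_00.to_numpy()
        b = back.tracking_log.theta_00.to_numpy()
        assert np.abs(a - b).max() < 1e-12

    def test_empty_tracking_record_writes_metadata_and_stim_log(self, tmp_path):
        record = run_protocol(pause_flash_protocol(), SimulatedClock(Fraction(1, 60)))
        files = save_record(record, tmp_path / "rec", format="csv")
        names = sorted(p.name for p in files)
        assert names == ["rec.metadata.json", "rec.stimulus_log.csv"]

    def test_version_string_in_metadata(self, tmp_path):
        record = run_protocol(pause_flash_protocol(), SimulatedClock(Fraction(1, 60)))
        save_record(record, tmp_path / "rec", format="hdf5")
        meta = json.loads((tmp_path / "rec.metadata.json").read_text())
        assert meta["software"]["version"] == fishtrack.__version__

    def test_every_accessed_parameter_saved(self, tmp_path):
        # audit: each parameter read during the run must appear in the tree
        tree = ParamTree({"stim": {"luminance": 0.3}, "loop": {"gain": 1.5}})

        def update(stim, ctx):
            stim.params["l"] = ctx.tree.get("stim/luminance")
            stim.params["g"] = ctx.tree.get("loop/gain")
            ctx.tree.get("loop/offset", default=0.0)

        spec = ProtocolSpec("p", (Stimulus("s", 0.5, dynamic=True,
                                           on_update=update),))
        record = run_protocol(spec, SimulatedClock(Fraction(1, 10)), tree=tree)
        save_record(record, tmp_path / "rec", format="hdf5")
        meta = json.loads((tmp_path / "rec.metadata.json").read_text())

        def present(d, path):
            node = d
            for p in path.split("/"):
                if not isinstance(node, dict) or p not in node:
                    return False
                node = node[p]
            return True

        for path in tree.accessed:
            assert present(meta, path), path

    def test_bad_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            save_record(ExperimentRecord(), tmp_path / "rec", format="feather")
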