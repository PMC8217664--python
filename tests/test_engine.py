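"""Rendering, scheduling, logging and resume behaviour of the engine."""

import random

import pytest

from conftest import run_interrupted, tree_snapshot
from flowcall import MacroBindings, PortLink, WorkflowSpec, engine, fixtures, link_steps
from flowcall.engine import RunLogs
from flowcall.errors import StaleStateError, UnboundInputError, UnboundMacroError


class TestRender:
    def test_linked_input_becomes_upstream_output_path(self, qc_bwa_spec, tmp_path):
        bindings = MacroBindings({"THREADS": "4", "R1": "/data/r1.fq"})
        steps = {s.name: s for s in engine.render(qc_bwa_spec, bindings, tmp_path / "run")}
        qc_out = str(tmp_path / "run" / "qc" / "clean1")
        assert steps["bwa"].command == f"bwa mem {qc_out} > " + str(
            tmp_path / "run" / "bwa" / "bam"
        )
        assert steps["qc"].command == f"fastp -i /data/r1.fq -o {qc_out} -w 4"
        for s in steps.values():
            assert "#" not in s.command and "<" not in s.command and "[" not in s.command

    def test_identity_render_without_macros_or_links(self, tmp_path):
        spec = WorkflowSpec()
        spec.add_step("noop", "true")
        (step,) = engine.render(spec, MacroBindings(), tmp_path)
        assert step.command == "true"

    def test_unbound_macro_names_the_macro(self, qc_bwa_spec, tmp_path):
        with pytest.raises(UnboundMacroError, match="THREADS"):
            engine.render(qc_bwa_spec, MacroBindings({"R1": "x"}), tmp_path)

    def test_unbound_input_names_the_port(self, qc_bwa_spec, tmp_path):
        with pytest.raises(UnboundInputError, match="r1"):
            engine.render(qc_bwa_spec, MacroBindings({"THREADS": "4"}), tmp_path)

    def test_macro_default_used_when_unbound(self, tmp_path):
        spec = WorkflowSpec()
        spec.add_step("s", "echo #TAG#")
        spec.declare_macro("TAG", "fallback")
        (step,) = engine.render(spec, MacroBindings(), tmp_path)
        assert step.command == "echo fallback"

    def test_escaped_hash_renders_literally(self, tmp_path):
        spec = WorkflowSpec()
        spec.add_step("s", "echo '##1'")
        (step,) = engine.render(spec, MacroBindings(), tmp_path)
        assert step.command == "echo '#1'"


class TestExecute:
    def test_linear_chain_runs_in_order(self, tmp_path):
        spec, bindings, oracle = fixtures.make_workflow_fixture(
            3, edge_probability=1.0, seed=0, step_kind="timestamping"
        )
        state = engine.run(spec, bindings, tmp_path / "run", 2)
        assert state.all_succeeded
        ts = fixtures.read_timestamps(tmp_path / "run", oracle.step_names)
        for u, v in oracle.edges:
            assert ts[u][1] <= ts[v][0]

    def test_failure_gates_downstream_only(self, tmp_path):
        # a -> b -> d, c independent; a fails: b,d never start, c succeeds
        spec = WorkflowSpec()
        spec.add_step("a", "echo x > [out] && exit 7")
        spec.add_step("b", "cat <in_a> > [out]")
        spec.add_step("c", "echo ok > [out]")
        spec.add_step("d", "cat <in_b> > /dev/null")
        link_steps(spec, PortLink("a", "out", "b", "in_a"))
        link_steps(spec, PortLink("b", "out", "d", "in_b"))
        state = engine.run(spec, MacroBindings(), tmp_path / "r", 2)
        assert state.statuses == {
            "a": "failed", "b": "pending", "c": "succeeded", "d": "pending",
        }
        commands = RunLogs(tmp_path / "r").command_log.read_text().splitlines()
        assert len(commands) == 2  # only a and c were ever launched

    def test_exit_status_zero_is_success(self, tmp_path):
        spec = WorkflowSpec()
        spec.add_step("good", "true")
        spec.add_step("bad", "exit 5")
        state = engine.run(spec, MacroBindings(), tmp_path / "r", 1)
        assert state.statuses["good"] == "succeeded"
        assert state.statuses["bad"] == "failed"
        assert "exit status 5" in state.failure_reasons["bad"]

    def test_logs_have_commands_ok_and_streams(self, tmp_path):
        spec = WorkflowSpec()
        spec.add_step("hello", "echo HELLO")
        spec.add_step("oops", "echo SAD >&2 && exit 1")
        state = engine.run(spec, MacroBindings(), tmp_path / "r", 1)
        logs = RunLogs(tmp_path / "r")
        commands = logs.command_log.read_text().strip().splitlines()
        assert commands == ["echo HELLO", "echo SAD >&2 && exit 1"]
        assert logs.read_ok() == ["hello"]
        out = logs.out_file.read_text()
        assert "==== step: hello ====" in out and "HELLO" in out
        err = logs.err_file.read_text()
        assert "==== step: oops ====" in err and "SAD" in err

    def test_failed_run_ok_log_counts_only_successes(self, tmp_path):
        # failure at step 2 of 3: ok-log holds exactly the one success
        spec = WorkflowSpec()
        spec.add_step("s1", "echo 1 > [out]")
        spec.add_step("s2", "cat <in_s1> > [out] && exit 9")
        spec.add_step("s3", "cat <in_s2> > /dev/null")
        link_steps(spec, PortLink("s1", "out", "s2", "in_s1"))
        link_steps(spec, PortLink("s2", "out", "s3", "in_s2"))
        state = engine.run(spec, MacroBindings(), tmp_path / "r", 1)
        assert RunLogs(tmp_path / "r").read_ok() == ["s1"]
        assert state.statuses["s2"] == "failed"
        assert state.statuses["s3"] == "pending"

    def test_serial_launch_order_is_deterministic(self, tmp_path):
        spec, bindings, _ = fixtures.make_workflow_fixture(8, 0.35, seed=5)
        engine.run(spec, bindings, tmp_path / "r1", 1)
        engine.run(spec, bindings, tmp_path / "r2", 1)
        assert tree_snapshot(tmp_path / "r1") == tree_snapshot(tmp_path / "r2")


class TestResume:
    def test_resume_runs_only_remaining_steps(self, tmp_path):
        spec, bindings, oracle = fixtures.make_diamond_fixture(sleep_seconds=0)
        rd = tmp_path / "r"
        state = run_interrupted(spec, bindings, rd, stop_after=2, max_parallel=1)
        assert state.interrupted and len(state.ok_entries) == 2
        before = RunLogs(rd).command_log.read_text().splitlines()
        state2 = engine.resume(spec, bindings, rd, 1)
        assert state2.all_succeeded
        after = RunLogs(rd).command_log.read_text().splitlines()
        assert len(after) == 4  # each step executed exactly once overall
        assert after[: len(before)] == before

    def test_resume_of_complete_run_spawns_nothing(self, tmp_path):
        spec, bindings, _ = fixtures.make_chain_fixture(4)
        rd = tmp_path / "r"
        engine.run(spec, bindings, rd, 1)
        n_before = len(RunLogs(rd).command_log.read_text().splitlines())
        state = engine.resume(spec, bindings, rd, 1)
        assert state.all_succeeded
        assert len(RunLogs(rd).command_log.read_text().splitlines()) == n_before

    def test_unknown_ok_entry_is_stale(self, tmp_path):
        spec, bindings, _ = fixtures.make_chain_fixture(3)
        rd = tmp_path / "r"
        engine.run(spec, bindings, rd, 1)
        with open(RunLogs(rd).ok_log, "a") as fh:
            fh.write("zz\n")
        with pytest.raises(StaleStateError, match="zz"):
            engine.resume(spec, bindings, rd, 1)

    def test_fingerprint_mismatch_refuses(self, tmp_path):
        spec, bindings, _ = fixtures.make_chain_fixture(3)
        rd = tmp_path / "r"
        engine.run(spec, bindings, rd, 1)
        other = MacroBindings({"EXTRA": "1"})
        with pytest.raises(StaleStateError, match="fingerprint"):
            engine.resume(spec, other, rd, 1)

    def test_fresh_directory_refuses_resume(self, tmp_path):
        spec, bindings, _ = fixtures.make_chain_fixture(3)
        with pytest.raises(StaleStateError):
            engine.resume(spec, bindings, tmp_path / "never_ran", 1)


class TestSchedulingProperty:
    def test_random_dags_respect_dependencies(self, tmp_path):
        # smaller version of the full soundness sweep in the acceptance suite
        rng = random.Random(123)
        for case in range(10):
            n = rng.randint(2, 10)
            spec, bindings, oracle = fixtures.make_workflow_fixture(
                n, edge_probability=0.4, seed=1000 + case, step_kind="timestamping"
            )
            rd = tmp_path / f"dag{case}"
            state = engine.run(spec, bindings, rd, 4)
            assert state.all_succeeded
            ts = fixtures.read_timestamps(rd, oracle.step_names)
            for u, v in oracle.edges:
                assert ts[u][1] <= ts[v][0], (u, v)

    def test_injected_failure_matches_oracle(self, tmp_path):
        spec, bindings, oracle = fixtures.make_workflow_fixture(
            6, edge_probability=0.5, seed=77, fail_at=1
        )
        state = engine.run(spec, bindings, tmp_path / "r", 2)
        expected = oracle.expected_outcomes()
        for name, outcome in expected.items():
            if outcome == "succeeded":
                assert state.statuses[name] == "succeeded"
            elif outcome == "failed":
                assert state.statuses[name] == "failed"
            else:
                assert state.statuses[name] == "pending"
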