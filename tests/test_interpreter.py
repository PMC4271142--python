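"""Language execution semantics: control flow, functions, sys, task
laziness, wait barriers, par threads, overrides, and failure handling."""

import io
import os

import pytest

from pipescript import EngineOptions, run_script
from pipescript.testkit import make_file_tree


def run_capture(source, run_dir, **options):
    out = io.StringIO()
    defaults = dict(run_dir=run_dir, write_report=False, dispatch_tick=0.003)
    defaults.update(options)
    status, engine = run_script(source, options=EngineOptions(**defaults),
                                origin=os.path.join(run_dir, "script.bds"),
                                stdout=out)
    return status, engine, out.getvalue()


class TestBasics:
    def test_empty_program_exits_ok(self, run_dir):
        status, _, _ = run_capture("", run_dir)
        assert status.code == 0 and status.reason == "ok"

    def test_control_flow_and_functions(self, run_dir):
        src = """\
int fib(int n) {
    if( n < 2 ) {
        return n
    }
    return fib(n - 1) + fib(n - 2)
}
total := 0
for( int i = 0 ; i < 10 ; i++ ) {
    if( i % 2 == 0 ) {
        continue
    }
    total += i
}
println "total=" + total
println "fib=" + fib(10)
xs := ["a", "b", "c"]
for( x in xs ) {
    print x
}
println ""
n := 7
while( n > 0 ) {
    n = n - 2
    if( n < 0 ) {
        break
    }
}
println "n=" + n
println "div=" + (7 / 2) + " mod=" + (7 % 2) + " real=" + (1 + 2.0)
"""
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0
        assert out.splitlines() == [
            "total=25", "fib=55", "abc", "n=-1", "div=3 mod=1 real=3.0"]

    def test_string_indexing_and_builtins(self, run_dir):
        src = """\
xs := ["zero", "one", "two"]
println xs[1]
println toStr(toInt("42") + 1)
println toInt(3.9)
println toReal(2) / 4
"""
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0
        assert out.splitlines() == ["one", "43", "3", "0.5"]

    def test_index_out_of_range_is_runtime_error_with_checkpoint(self, run_dir):
        status, engine, _ = run_capture('xs := ["a"]\nprintln xs[5]\n', run_dir)
        assert status.code == 1 and status.reason == "runtime-error"
        assert engine.last_checkpoint and os.path.exists(engine.last_checkpoint)


class TestSys:
    def test_sys_echoes_stdout_and_continues(self, run_dir):
        status, _, out = run_capture("sys echo hello\nprintln \"after\"\n",
                                     run_dir)
        assert status.code == 0
        assert "hello" in out and "after" in out

    def test_sys_interpolates_variables(self, run_dir):
        src = 'in := "a.txt"\nsys echo $in\n'
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0
        assert "a.txt" in out

    def test_failing_sys_aborts_with_checkpoint(self, run_dir):
        status, engine, _ = run_capture("sys false\nprintln \"unreached\"\n",
                                        run_dir)
        assert status.code == 1
        assert engine.last_checkpoint is not None


class TestTasks:
    def test_program_blocks_until_tasks_finish_without_explicit_wait(
            self, run_dir):
        src = 'task { sleep 0.3; echo done > implicit.txt }\n'
        status, engine, _ = run_capture(src, run_dir)
        assert status.code == 0
        assert open(os.path.join(run_dir, "implicit.txt")).read() == "done\n"
        assert all(r.terminal for r in engine.scheduler.records.values())

    def test_up_to_date_task_is_skipped_without_spawning(self, run_dir):
        make_file_tree({"in.txt": {"size": 3, "mtime_offset": 0},
                        "out.txt": {"size": 3, "mtime_offset": 100}}, run_dir)
        src = 'task( "out.txt" <- "in.txt" ) { echo never > out.txt }\n'
        status, engine, _ = run_capture(src, run_dir)
        assert status.code == 0
        rec = engine.scheduler.records["task.1"]
        assert rec.state == "SKIPPED" and rec.pid is None
        assert engine.events.count_transitions("RUNNING") == 0

    def test_unconditional_task_always_runs(self, run_dir):
        status, engine, _ = run_capture("task { true }\n", run_dir)
        assert status.code == 0
        assert engine.scheduler.records["task.1"].state == "DONE"

    def test_oversized_task_terminates_program_before_running(self, run_dir):
        src = 'task( cpus := 2 ) { echo no > never.txt }\n'
        status, engine, _ = run_capture(src, run_dir, total_cpus=1)
        assert status.code == 1
        assert engine.events.count_transitions("RUNNING") == 0
        assert not os.path.exists(os.path.join(run_dir, "never.txt"))

    def test_failed_task_reports_reason_and_checkpoints(self, run_dir):
        src = 'tid := task { exit 3 }\nwait\nprintln "unreached"\n'
        status, engine, out = run_capture(src, run_dir)
        assert status.code == 1 and status.reason == "task-failed"
        assert "task.1" in out and "unreached" not in out
        assert engine.last_checkpoint is not None

    def test_dependency_operator_as_expression(self, run_dir):
        make_file_tree({"in.txt": {"size": 3, "mtime_offset": 100},
                        "out.txt": {"size": 3, "mtime_offset": 0}}, run_dir)
        src = """\
if( "out.txt" <- "in.txt" ) {
    println "stale"
}
"""
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0 and "stale" in out


class TestWait:
    def test_wait_is_a_barrier(self, run_dir):
        src = """\
task { sleep 0.3; echo a > a.txt }
task { sleep 0.3; echo b > b.txt }
wait
sys cat a.txt b.txt > both.txt
"""
        status, engine, _ = run_capture(src, run_dir)
        assert status.code == 0
        assert open(os.path.join(run_dir, "both.txt")).read() == "a\nb\n"

    def test_wait_on_specific_id_leaves_others_running(self, run_dir):
        src = """\
t1 := task { sleep 0.1; echo one > one.txt }
t2 := task { sleep 0.6; echo two > two.txt }
wait [t1]
exists := "one done"
println exists
"""
        status, engine, out = run_capture(src, run_dir)
        assert status.code == 0
        assert "one done" in out
        # t2 joined only by the implicit final wait
        assert engine.scheduler.records["task.2"].state == "DONE"

    def test_one_failure_waits_for_the_rest_then_stops(self, run_dir):
        src = """\
task { exit 1 }
task { sleep 0.4; echo ok > survivor.txt }
wait
println "unreached"
"""
        status, engine, out = run_capture(src, run_dir)
        assert status.code == 1
        assert "unreached" not in out
        # the healthy task was allowed to finish before the stop
        assert engine.scheduler.records["task.2"].state == "DONE"
        assert os.path.exists(os.path.join(run_dir, "survivor.txt"))


class TestPar:
    def test_par_blocks_run_concurrently_and_join_implicitly(self, run_dir):
        src = """\
par {
    task { sleep 0.3; echo a > pa.txt }
}
par {
    task { sleep 0.3; echo b > pb.txt }
}
"""
        status, engine, _ = run_capture(src, run_dir, total_cpus=4)
        assert status.code == 0
        assert os.path.exists(os.path.join(run_dir, "pa.txt"))
        assert os.path.exists(os.path.join(run_dir, "pb.txt"))
        assert engine.events.max_concurrent("RUNNING", id_prefix="task.") == 2

    def test_par_function_call_joinable_by_id(self, run_dir):
        src = """\
void work(int n) {
    task { echo $n > par_out.txt }
}
pid := par work(5)
wait [pid]
sys cat par_out.txt
"""
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0
        assert "5" in out

    def test_par_scope_is_a_snapshot(self, run_dir):
        src = """\
x := 1
par {
    x = 99
}
wait
println "x=" + x
"""
        status, _, out = run_capture(src, run_dir)
        assert status.code == 0
        assert "x=1" in out

    def test_par_failure_surfaces_at_final_wait(self, run_dir):
        src = "par {\n    task { exit 1 }\n}\n"
        status, engine, _ = run_capture(src, run_dir)
        assert status.code == 1 and status.reason == "task-failed"


class TestOverrides:
    def test_override_replaces_initializer(self, run_dir):
        src = 'in := "input.file"\nprintln in\n'
        out = io.StringIO()
        from pipescript import parse, check_program, Engine
        typed = check_program(parse(src))
        engine = Engine(typed, options=EngineOptions(run_dir=run_dir,
                                                     write_report=False),
                        overrides={"in": "another.file"}, stdout=out)
        status = engine.run()
        assert status.code == 0
        assert out.getvalue() == "another.file\n"

    def test_override_round_trip_matches_edited_script(self, run_dir):
        edited = 'n := 5\nprintln n * 2\n'
        status1, _, out1 = run_capture(edited, run_dir)
        out = io.StringIO()
        from pipescript import parse, check_program, Engine
        typed = check_program(parse('n := 0\nprintln n * 2\n'))
        engine = Engine(typed, options=EngineOptions(run_dir=run_dir,
                                                     write_report=False),
                        overrides={"n": 5}, stdout=out)
        assert engine.run().code == 0
        assert out.getvalue() == out1


class TestDeterminism:
    def test_scheduled_command_sequence_is_stable_across_runs(self, tmp_path):
        src = """\
for( int i = 0 ; i < 5 ; i++ ) {
    task { echo $i }
}
wait
"""
        seqs = []
        for run_name in ("a", "b"):
            d = str(tmp_path / run_name)
            os.makedirs(d)
            _, engine, _ = run_capture(src, d)
            seqs.append([(r.spec.id, tuple(r.spec.command))
                         for r in sorted(engine.scheduler.records.values(),
                                         key=lambda r: r.spec.id)])
        assert seqs[0] == seqs[1]
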