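"""Absolute serialization: canonical encoding, recovery-mode resume,
variable restoration, stale-source detection, and inspection."""

import os

import pytest

from pipescript import (EngineOptions, StaleSourceError, inspect_checkpoint,
                        resume, run_script)
from pipescript.checkpoint import load_document, save_document
from pipescript.testkit import gen_flaky_chain, make_file_tree


def run(source, run_dir, **options):
    defaults = dict(run_dir=run_dir, write_report=False, dispatch_tick=0.003)
    defaults.update(options)
    return run_script(source, options=EngineOptions(**defaults),
                      origin=os.path.join(run_dir, "script.bds"))


def read_events(run_dir):
    events = []
    with open(os.path.join(run_dir, "events.log")) as fh:
        for line in fh:
            t, unit, old, new = line.rstrip("\n").split("\t")
            events.append((float(t), unit, old, new))
    return events


def ran_ids(run_dir):
    return {unit for _, unit, _, new in read_events(run_dir)
            if new == "RUNNING"}


LOOP_SRC = """\
total := 0
for( int i = 0 ; i < 10 ; i++ ) {
    total += i
    sys echo $i >> trace.txt
    if( i == 5 ) {
        checkpoint "mid.chp"
    }
}
sys echo total=$total >> trace.txt
"""


class TestExplicitCheckpoint:
    def test_mid_loop_checkpoint_resumes_at_successor_iteration(self, tmp_path):
        first = str(tmp_path / "first")
        os.makedirs(first)
        status, engine = run(LOOP_SRC, first)
        assert status.code == 0
        trace = open(os.path.join(first, "trace.txt")).read().splitlines()
        assert trace == [str(i) for i in range(10)] + ["total=45"]

        # resume in a fresh directory: iterations 0..5 must not repeat,
        # and the restored variables continue accumulating correctly
        second = str(tmp_path / "second")
        os.makedirs(second)
        status2 = resume(os.path.join(first, "mid.chp"),
                         options=EngineOptions(run_dir=second,
                                               write_report=False))
        assert status2.code == 0
        trace2 = open(os.path.join(second, "trace.txt")).read().splitlines()
        assert trace2 == ["6", "7", "8", "9", "total=45"]

    def test_unnamed_checkpoint_gets_auto_name_in_run_dir(self, run_dir):
        status, engine = run("x := 1\ncheckpoint\n", run_dir)
        assert status.code == 0
        assert engine.last_checkpoint.endswith("explicit-statement.chp")
        assert os.path.exists(engine.last_checkpoint)


class TestResumeSemantics:
    def test_failed_stage_rerun_done_stages_untouched(self, tmp_path):
        d = str(tmp_path)
        make_file_tree({"src.txt": {"size": 4, "mtime_offset": 0}}, d)
        src = gen_flaky_chain(3, {2: 1}, retry=0)
        status, engine = run(src, d)
        assert status.code == 1
        assert engine.scheduler.records["task.1"].state == "DONE"
        assert engine.scheduler.records["task.2"].state == "FAILED"
        first_events = len(read_events(d))

        status2 = resume(engine.last_checkpoint,
                         options=EngineOptions(run_dir=d, write_report=False))
        assert status2.code == 0
        resumed = {u for _, u, _, new in read_events(d)[first_events:]
                   if new == "RUNNING"}
        assert "task.1" not in resumed  # DONE task never re-executed
        assert {"task.2", "task.3"} <= resumed
        final = open(os.path.join(d, "chain_3.txt")).read()
        assert final == "xxxxstage1\nstage2\nstage3\n"
        # stage 2's command really ran exactly twice (fail + success)
        assert open(os.path.join(d, "cnt_2.txt")).read().strip() == "2"

    def test_double_resume_schedules_zero_tasks(self, tmp_path):
        d = str(tmp_path)
        src = 'task { echo hi > out.txt }\nwait\ncheckpoint "done.chp"\n'
        status, engine = run(src, d)
        assert status.code == 0
        n_events = len(read_events(d))
        status2 = resume(os.path.join(d, "done.chp"),
                         options=EngineOptions(run_dir=d, write_report=False))
        assert status2.code == 0
        new_events = read_events(d)[n_events:]
        assert not any(new == "RUNNING" for _, _, _, new in new_events)

    def test_resume_with_edited_script_is_rejected(self, tmp_path):
        d = str(tmp_path)
        script = tmp_path / "script.bds"
        script.write_text("task { exit 1 }\nwait\n")
        status, engine = run(script.read_text(), d)
        assert status.code == 1
        script.write_text("task { exit 0 }\nwait\n")  # the "bug fix"
        with pytest.raises(StaleSourceError):
            resume(engine.last_checkpoint,
                   options=EngineOptions(run_dir=d, write_report=False),
                   script_override=str(script))

    def test_wait_failure_checkpoint_records_reasons(self, run_dir):
        status, engine = run("task { exit 9 }\nwait\n", run_dir)
        assert status.code == 1
        data = load_document(engine.last_checkpoint)
        assert data["reason"] == "wait-failure"
        task = data["tasks"][0]
        assert task["state"] == "FAILED"
        assert "exit code 9" in task["failure_reason"]

    def test_scope_round_trip_preserves_types_and_values(self, run_dir):
        src = ('n := 5\nfiles := ["a.txt", "b.txt"]\nratio := 2.5\n'
               'flag := true\ncheckpoint "vars.chp"\n')
        status, engine = run(src, run_dir)
        assert status.code == 0
        data = load_document(os.path.join(run_dir, "vars.chp"))
        g = data["scopes"][0]
        assert g["n"] == {"type": "int", "value": 5}
        assert g["files"] == {"type": "string[]", "value": ["a.txt", "b.txt"]}
        assert g["ratio"] == {"type": "real", "value": 2.5}
        assert g["flag"] == {"type": "bool", "value": True}


class TestEncoding:
    def test_load_save_is_byte_identity(self, run_dir):
        status, engine = run('x := 1\ncheckpoint "c.chp"\n', run_dir)
        path = os.path.join(run_dir, "c.chp")
        before = open(path, "rb").read()
        save_document(load_document(path), path)
        assert open(path, "rb").read() == before

    def test_serialization_is_fast_for_large_task_tables(self, run_dir):
        import time
        src = """\
for( int i = 0 ; i < 1000 ; i++ ) {
    task( "o" + i + ".txt" <- "missing_in.txt", taskName := "t" + i ) { true }
}
"""
        # dry-run: build a 1000-entry task table without launching anything
        status, engine = run(src, run_dir, dry_run=True)
        assert status.code == 0
        from pipescript.interpreter import ThreadCtx
        t0 = time.monotonic()
        engine._checkpoint(ThreadCtx("main"), "explicit-statement",
                           path=os.path.join(run_dir, "big.chp"))
        assert time.monotonic() - t0 < 1.0
        assert len(load_document(os.path.join(run_dir, "big.chp"))["tasks"]) == 1000


class TestInspect:
    def test_inspect_lists_variables_and_tasks_read_only(self, run_dir):
        src = 'greeting := "hello"\ntask { exit 2 }\nwait\n'
        status, engine = run(src, run_dir)
        assert status.code == 1
        path = engine.last_checkpoint
        before = open(path, "rb").read()
        dump = inspect_checkpoint(path)
        assert "greeting" in dump and "hello" in dump
        assert "task.1" in dump and "FAILED" in dump
        assert "stderr" in dump  # failed task points at its stderr log
        assert open(path, "rb").read() == before
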