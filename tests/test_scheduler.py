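"""Scheduler lifecycle: resource accounting, FIFO dispatch, retry+1,
stale-output cleanup, DAG ordering, and interrupt kills."""

import os
import time

import pytest

from pipescript import ResourceError, Scheduler, TaskSpec
from pipescript.events import EventLog
from pipescript.runner import proc_group_members
from pipescript.testkit import flaky_command


def make_scheduler(tmp_path, **kw):
    events = EventLog(os.path.join(str(tmp_path), "events.log"))
    defaults = dict(run_dir=str(tmp_path), total_cpus=4, tick=0.003, grace=0.5)
    defaults.update(kw)
    sched = Scheduler(events, **defaults)
    sched.start()
    return sched, events


def spec(task_id, command, **kw):
    if isinstance(command, str):
        command = [command]
    return TaskSpec(id=task_id, command=command, **kw)


class TestSubmission:
    def test_oversized_request_rejected_outright(self, tmp_path):
        sched, _ = make_scheduler(tmp_path, total_cpus=1)
        with pytest.raises(ResourceError, match="lack of resources"):
            sched.submit(spec("task.1", "true", cpus=2))
        sched.shutdown()

    def test_fitting_request_scheduled(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=64)
        sched.submit(spec("task.1", "true", cpus=2))
        assert sched.wait_all(timeout=10)
        sched.shutdown()
        assert events.count_transitions("SCHEDULED") == 1

    def test_mock_cluster_accepts_any_size(self, tmp_path):
        sched, _ = make_scheduler(tmp_path, executor="mock-cluster")
        sched.submit(spec("task.1", "true", cpus=4096))
        assert sched.wait_all(timeout=10)
        sched.shutdown()


class TestDispatch:
    def test_peak_concurrency_is_pool_over_cpus(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=8)
        for i in range(12):
            sched.submit(spec(f"task.{i}", "sleep 0.25", cpus=2))
        assert sched.wait_all(timeout=30)
        sched.shutdown()
        assert events.max_concurrent("RUNNING") == 4

    def test_undersubscribed_pool_runs_everything_at_once(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=4)
        for i in range(3):
            sched.submit(spec(f"task.{i}", "sleep 0.3", cpus=1))
        assert sched.wait_all(timeout=30)
        sched.shutdown()
        assert events.max_concurrent("RUNNING") == 3

    def test_cpu_conservation_from_event_log(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=4)
        cpus = {}
        for i in range(10):
            c = 1 + (i % 2)
            cpus[f"task.{i}"] = c
            sched.submit(spec(f"task.{i}", "sleep 0.05", cpus=c))
        assert sched.wait_all(timeout=30)
        sched.shutdown()
        in_use = 0
        for _, tid, old, new in events.snapshot():
            if new == "RUNNING":
                in_use += cpus[tid]
            elif old == "RUNNING":
                in_use -= cpus[tid]
            assert 0 <= in_use <= 4

    def test_successor_waits_for_predecessors(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=4)
        sched.submit(spec("task.1", "sleep 0.2", cpus=1))
        sched.submit(spec("task.2", "true", cpus=1), after=["task.1"])
        assert sched.wait_all(timeout=30)
        sched.shutdown()
        starts = {tid: t for t, tid, _, new in events.snapshot()
                  if new == "RUNNING"}
        ends = {tid: t for t, tid, old, new in events.snapshot()
                if old == "RUNNING" and new == "DONE"}
        assert starts["task.2"] >= ends["task.1"]

    def test_failed_predecessor_fails_dependent_without_running_it(self, tmp_path):
        sched, events = make_scheduler(tmp_path, total_cpus=4)
        sched.submit(spec("task.1", "false"))
        sched.submit(spec("task.2", "true"), after=["task.1"])
        sched.wait_all(timeout=30)
        sched.shutdown()
        assert sched.records["task.2"].state == "FAILED"
        assert events.count_transitions("RUNNING", id_prefix="task.2") == 0


class TestRetry:
    def test_always_failing_task_gets_exactly_retry_plus_one_attempts(self, tmp_path):
        sched, _ = make_scheduler(tmp_path)
        sched.submit(spec("task.1", "exit 1", retry=2))
        sched.wait_all(timeout=30)
        sched.shutdown()
        rec = sched.records["task.1"]
        assert rec.state == "FAILED"
        assert rec.attempts == 3

    def test_flaky_task_succeeds_within_budget(self, tmp_path):
        counter = os.path.join(str(tmp_path), "cnt")
        line = flaky_command(1, counter).replace("\\$", "$")
        sched, _ = make_scheduler(tmp_path)
        sched.submit(spec("task.1", line, retry=1))
        sched.wait_all(timeout=30)
        sched.shutdown()
        rec = sched.records["task.1"]
        assert rec.state == "DONE"
        assert rec.attempts == 2
        with open(counter) as fh:
            assert fh.read().strip() == "2"

    def test_failed_task_outputs_are_cleaned_up(self, tmp_path):
        out = os.path.join(str(tmp_path), "half.txt")
        sched, _ = make_scheduler(tmp_path)
        sched.submit(spec("task.1", f"echo partial > {out}; exit 1",
                          outs=[out], retry=1))
        sched.wait_all(timeout=30)
        sched.shutdown()
        assert sched.records["task.1"].state == "FAILED"
        assert not os.path.exists(out)


class TestKillAll:
    def test_interrupt_leaves_no_descendant_processes(self, tmp_path):
        sched, _ = make_scheduler(tmp_path, total_cpus=16)
        for i in range(10):
            sched.submit(spec(f"task.{i}", "sleep 30", cpus=1))
        deadline = time.monotonic() + 10
        while time.monotonic() < deadline:
            with sched.lock:
                if sum(r.state == "RUNNING" for r in sched.records.values()) >= 10:
                    break
            time.sleep(0.01)
        pgids = [r.handle.pgid for r in sched.records.values()
                 if r.handle is not None]
        sched.kill_all()
        sched.shutdown()
        for pgid in pgids:
            assert proc_group_members(pgid) == []
        states = {r.state for r in sched.records.values()}
        assert states <= {"KILLED"}

    def test_kill_all_with_only_done_tasks_is_a_noop(self, tmp_path):
        sched, _ = make_scheduler(tmp_path)
        sched.submit(spec("task.1", "true"))
        sched.wait_all(timeout=30)
        sched.kill_all()
        sched.shutdown()
        assert sched.records["task.1"].state == "DONE"

    def test_grandchild_processes_die_with_the_group(self, tmp_path):
        sched, _ = make_scheduler(tmp_path)
        sched.submit(spec("task.1", "(sleep 30 &); sleep 30"))
        deadline = time.monotonic() + 10
        while time.monotonic() < deadline:
            with sched.lock:
                rec = sched.records["task.1"]
                if rec.state == "RUNNING":
                    break
            time.sleep(0.01)
        time.sleep(0.2)  # give the subshell time to fork the grandchild
        pgid = rec.handle.pgid
        assert len(proc_group_members(pgid)) >= 2
        sched.kill_all()
        sched.shutdown()
        assert proc_group_members(pgid) == []
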