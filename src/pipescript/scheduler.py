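"""Resource-aware task scheduler.

A strict-FIFO dispatch loop drives tasks through their lifecycle
(CREATED -> SCHEDULED -> RUNNING -> terminal) against a CPU/memory
resource pool.  The head of the queue blocks until it fits (no
backfilling), which makes scheduling deterministic: on a saturated pool a
stream of identical tasks runs one wave at a time, and peak concurrency on
an n-CPU pool with c-CPU tasks is floor(n/c).

Two executors share the submit/poll/kill contract:

* ``local`` — validates each request against the pool totals (a task that
  can never fit is rejected outright, terminating the program) and debits
  or credits the pool as tasks start and finish;
* ``mock-cluster`` — accepts every submission immediately and without
  resource accounting, emulating a cluster whose resource manager decides
  how to run things; it can simulate queue latency and a seeded induced
  failure rate for robustness testing.

Failure handling implements the retry+1 rule: a task is attempted up to
``retry + 1`` times and only marked FAILED after its last attempt; every
failed attempt deletes the task's declared outputs so a rerun can never
consume half-written files.
"""

from __future__ import annotations

import os
import random
import shutil
import threading
import time
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from . import runner
from .errors import ResourceError

TERMINAL_STATES = {"DONE", "FAILED", "KILLED", "TIMEOUT", "SKIPPED"}


@dataclass
class TaskSpec:
    id: str
    command: list  # interpolated command lines
    name: Optional[str] = None
    ins: list = field(default_factory=list)
    outs: list = field(default_factory=list)
    cpus: int = 1
    mem: int = 0  # bytes; 0 = unaccounted
    timeout: float = 0  # seconds; 0 = none
    retry: int = 0


@dataclass
class TaskRecord:
    spec: TaskSpec
    state: str = "CREATED"
    attempts: int = 0
    pid: Optional[int] = None
    exit_code: Optional[int] = None
    t_sched: Optional[float] = None
    t_start: Optional[float] = None
    t_end: Optional[float] = None
    stdout_path: Optional[str] = None
    stderr_path: Optional[str] = None
    exit_path: Optional[str] = None
    after: list = field(default_factory=list)  # predecessor task ids
    owner: str = "main"  # spawning interpreter thread
    failure_reason: Optional[str] = None
    ready_time: float = 0.0  # mock-cluster queue latency
    handle: object = None

    @property
    def terminal(self) -> bool:
        return self.state in TERMINAL_STATES


class ResourcePool:
    """CPU/memory budget; 0 <= in_use <= total at every instant."""

    def __init__(self, total_cpus: int, total_mem: int = 0):
        self.total_cpus = total_cpus
        self.total_mem = total_mem
        self.in_use_cpus = 0
        self.in_use_mem = 0

    def fits_total(self, cpus, mem) -> bool:
        if cpus > self.total_cpus:
            return False
        if self.total_mem and mem > self.total_mem:
            return False
        return True

    def fits_now(self, cpus, mem) -> bool:
        if self.in_use_cpus + cpus > self.total_cpus:
            return False
        if self.total_mem and self.in_use_mem + mem > self.total_mem:
            return False
        return True

    def acquire(self, cpus, mem):
        self.in_use_cpus += cpus
        self.in_use_mem += mem
        assert self.in_use_cpus <= self.total_cpus

    def release(self, cpus, mem):
        self.in_use_cpus -= cpus
        self.in_use_mem -= mem
        assert self.in_use_cpus >= 0 and self.in_use_mem >= 0


class Scheduler:
    def __init__(self, events, run_dir: str, executor: str = "local",
                 total_cpus: Optional[int] = None, total_mem: int = 0,
                 fail_rate: float = 0.0, queue_delay: float = 0.0,
                 seed: int = 0, grace: float = 5.0, tick: float = 0.005,
                 work_dir: Optional[str] = None):
        if executor not in ("local", "mock-cluster"):
            raise ValueError(f"unknown executor {executor!r}")
        self.events = events
        self.run_dir = run_dir
        self.work_dir = work_dir or run_dir
        self.executor = executor
        self.pool = ResourcePool(total_cpus or os.cpu_count() or 1, total_mem)
        self.fail_rate = fail_rate
        self.queue_delay = queue_delay
        self.rng = random.Random(seed)
        self.grace = grace
        self.tick = tick
        self.records: dict[str, TaskRecord] = {}
        self.queue: deque[str] = deque()
        self.lock = threading.RLock()
        self.cond = threading.Condition(self.lock)
        self._stop = False
        self._killing = False
        self._thread = None
        self._supervisors: list[threading.Thread] = []

    # ------------------------------------------------------------ lifecycle

    def start(self):
        self._thread = threading.Thread(target=self._dispatch_loop,
                                        name="dispatcher", daemon=True)
        self._thread.start()

    def shutdown(self):
        with self.lock:
            self._stop = True
            self.cond.notify_all()
        if self._thread is not None:
            self._thread.join(timeout=10)
        for t in list(self._supervisors):
            t.join(timeout=10)

    def _set_state(self, record: TaskRecord, new: str):
        old = record.state
        record.state = new
        self.events.record(record.spec.id, old, new)
        self.cond.notify_all()

    # ------------------------------------------------------------ submit

    def submit(self, spec: TaskSpec, after=None, owner="main") -> str:
        """Enqueue a task; local executor rejects requests that can never
        be satisfied ("lack of resources")."""
        if self.executor == "local" and not self.pool.fits_total(spec.cpus, spec.mem):
            raise ResourceError(
                f"task {spec.id} ({spec.name or 'unnamed'}) requires "
                f"{spec.cpus} CPUs / {spec.mem} B mem; execution will fail "
                f"owing to lack of resources (pool: {self.pool.total_cpus} CPUs)")
        record = TaskRecord(spec=spec, after=list(after or []), owner=owner)
        with self.lock:
            self.records[spec.id] = record
            self.events.record(spec.id, "-", "CREATED")
            record.t_sched = time.time()
            record.ready_time = time.monotonic() + self.queue_delay
            self._set_state(record, "SCHEDULED")
            self.queue.append(spec.id)
        return spec.id

    def record_skipped(self, spec: TaskSpec, owner="main") -> str:
        """A lazily up-to-date task: recorded, never executed."""
        record = TaskRecord(spec=spec, owner=owner)
        with self.lock:
            self.records[spec.id] = record
            self.events.record(spec.id, "-", "CREATED")
            self._set_state(record, "SKIPPED")
        return spec.id

    def restore_record(self, record: TaskRecord):
        """Adopt a terminal record from a checkpoint without executing it."""
        with self.lock:
            self.records[record.spec.id] = record

    # ------------------------------------------------------------ dispatch

    def _dispatch_loop(self):
        while True:
            with self.lock:
                if self._stop:
                    return
                self._dispatch_ready()
            time.sleep(self.tick)

    def _dispatch_ready(self):
        """Start every startable task at the head of the FIFO queue.

        Strict FIFO: the head blocks on resources (no backfilling), but a
        head whose predecessors are still pending parks at the back so
        independent work behind it is not starved.
        """
        scanned = 0
        while self.queue and scanned < len(self.queue) and not self._killing:
            task_id = self.queue[0]
            record = self.records[task_id]
            unmet = [a for a in record.after
                     if not self.records[a].terminal
                     or self.records[a].state not in ("DONE", "SKIPPED")]
            failed_pred = [a for a in record.after
                           if self.records[a].state in ("FAILED", "KILLED", "TIMEOUT")]
            if failed_pred:
                self.queue.popleft()
                record.failure_reason = f"predecessor failed: {failed_pred[0]}"
                self._cleanup_outputs(record.spec)
                self._set_state(record, "FAILED")
                continue
            if unmet:
                # predecessors pending: rotate so later tasks can be examined
                self.queue.rotate(-1)
                scanned += 1
                continue
            if self.executor == "mock-cluster":
                if time.monotonic() < record.ready_time:
                    self.queue.rotate(-1)
                    scanned += 1
                    continue
                self.queue.popleft()
                self._start_task(record)
                scanned = 0
                continue
            if not self.pool.fits_now(record.spec.cpus, record.spec.mem):
                return  # head-of-line blocking on resources
            self.queue.popleft()
            self.pool.acquire(record.spec.cpus, record.spec.mem)
            self._start_task(record)
            scanned = 0

    def _start_task(self, record: TaskRecord):
        spec = record.spec
        record.attempts += 1
        record.t_start = time.time()
        if self.executor == "mock-cluster" and self.rng.random() < self.fail_rate:
            # induced failure: the "node" died before the command could run
            self._set_state(record, "RUNNING")
            thread = threading.Thread(
                target=self._simulate_failure, args=(record,), daemon=True)
            self._supervisors.append(thread)
            thread.start()
            return
        script = runner.write_script(spec, self.run_dir)
        record.stdout_path = os.path.join(self.run_dir, f"{spec.id}.stdout")
        record.stderr_path = os.path.join(self.run_dir, f"{spec.id}.stderr")
        record.exit_path = os.path.join(self.run_dir, f"{spec.id}.exitCode")
        handle = runner.launch(script, record.stdout_path, record.stderr_path,
                               record.exit_path, timeout=spec.timeout,
                               cwd=self.work_dir, task_id=spec.id)
        record.pid = handle.pid
        record.handle = handle
        self._set_state(record, "RUNNING")
        thread = threading.Thread(target=self._supervise, args=(record, handle),
                                  daemon=True)
        self._supervisors.append(thread)
        thread.start()

    def _simulate_failure(self, record: TaskRecord):
        time.sleep(0.01)
        with self.lock:
            self._on_terminal(record, runner.Outcome("exit", exit_code=1))

    def _supervise(self, record: TaskRecord, handle):
        outcome = runner.supervise(handle, grace=self.grace)
        with self.lock:
            self._on_terminal(record, outcome)

    def _on_terminal(self, record: TaskRecord, outcome):
        """Retry+1 semantics with stale-output cleanup (lock held)."""
        spec = record.spec
        if self.executor == "local":
            self.pool.release(spec.cpus, spec.mem)
        record.exit_code = outcome.exit_code
        record.t_end = time.time()
        record.handle = None
        if outcome.ok:
            self._set_state(record, "DONE")
            return
        self._cleanup_outputs(spec)
        if outcome.kind == "killed" or self._killing:
            record.failure_reason = "killed"
            self._set_state(record, "KILLED")
            return
        if outcome.kind == "timeout":
            record.failure_reason = f"timeout after {spec.timeout} s"
        else:
            record.failure_reason = f"exit code {outcome.exit_code}"
        if record.attempts < spec.retry + 1:
            record.ready_time = time.monotonic() + self.queue_delay
            self._set_state(record, "SCHEDULED")
            self.queue.append(spec.id)
            return
        self._set_state(record, "TIMEOUT" if outcome.kind == "timeout" else "FAILED")

    def _cleanup_outputs(self, spec: TaskSpec):
        for out in spec.outs:
            path = out if os.path.isabs(out) else os.path.join(self.work_dir, out)
            try:
                if os.path.isdir(path) and not os.path.islink(path):
                    shutil.rmtree(path, ignore_errors=True)
                elif os.path.lexists(path):
                    os.remove(path)
            except OSError:
                pass

    # ------------------------------------------------------------ waiting

    def wait_for(self, ids, timeout=None) -> bool:
        """Block until the named tasks are terminal; True iff all DONE/SKIPPED."""
        deadline = time.monotonic() + timeout if timeout else None
        with self.cond:
            while True:
                pending = [i for i in ids if not self.records[i].terminal]
                if not pending:
                    return all(self.records[i].state in ("DONE", "SKIPPED")
                               for i in ids)
                if deadline is not None and time.monotonic() > deadline:
                    return False
                self.cond.wait(timeout=0.05)

    def wait_all(self, timeout=None) -> bool:
        deadline = time.monotonic() + timeout if timeout else None
        with self.cond:
            while True:
                pending = [r for r in self.records.values() if not r.terminal]
                if not pending:
                    return all(r.state in ("DONE", "SKIPPED")
                               for r in self.records.values())
                if deadline is not None and time.monotonic() > deadline:
                    return False
                self.cond.wait(timeout=0.05)

    def failed_records(self):
        with self.lock:
            return [r for r in self.records.values()
                    if r.state in ("FAILED", "KILLED", "TIMEOUT")]

    # ------------------------------------------------------------ interrupt

    def kill_all(self):
        """Dequeue everything scheduled; kill every running process group;
        clean outputs of non-DONE tasks.  Best-effort and idempotent."""
        with self.lock:
            self._killing = True
            while self.queue:
                task_id = self.queue.popleft()
                record = self.records[task_id]
                if record.state == "SCHEDULED":
                    record.failure_reason = "killed before start"
                    self._cleanup_outputs(record.spec)
                    self._set_state(record, "KILLED")
            running = [r for r in self.records.values()
                       if r.state == "RUNNING" and r.handle is not None]
        for record in running:
            runner.request_kill(record.handle, grace=min(self.grace, 1.0))
        self.wait_all(timeout=30)
        with self.lock:
            for record in self.records.values():
                if record.state != "DONE":
                    self._cleanup_outputs(record.spec)
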