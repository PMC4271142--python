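"""Per-task process supervision.

Each task runs as a shell script in its *own process group* (POSIX
session), with stdout/stderr redirected to per-task log files and the
numeric exit status written to an exit-status file once supervision ends.
Timeouts and interrupts signal the whole group (TERM, grace period, then
KILL), so grandchildren cannot survive.  A timeout writes the literal
sentinel ``timeout`` to the exit file so downstream code can tell it apart
from any real exit code.

Per-task artifacts in the run directory, by stable name:
``<id>.sh``, ``<id>.stdout``, ``<id>.stderr``, ``<id>.exitCode``.
"""

from __future__ import annotations

import os
import signal
import subprocess
import time
from dataclasses import dataclass, field
from typing import Optional

from .errors import SpawnError

TIMEOUT_SENTINEL = "timeout"

_SCRIPT_PROLOGUE = "#!/bin/sh\nset -e\n"


@dataclass
class Outcome:
    kind: str  # 'exit' | 'timeout' | 'killed'
    exit_code: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.kind == "exit" and self.exit_code == 0


@dataclass
class RunHandle:
    task_id: str
    pid: int
    pgid: int
    script_path: str
    stdout_path: str
    stderr_path: str
    exit_path: str
    deadline: Optional[float]  # absolute monotonic time, None = no timeout
    popen: subprocess.Popen = field(repr=False, default=None)
    kill_requested: bool = False


def write_script(spec, directory: str) -> str:
    """Materialize the task's command lines as an executable shell script.

    Content is deterministic for identical specs: a strict-mode prologue
    followed by the command lines in declared order.
    """
    path = os.path.join(directory, f"{spec.id}.sh")
    lines = spec.command if isinstance(spec.command, list) else [spec.command]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_SCRIPT_PROLOGUE)
        for line in lines:
            fh.write(line + "\n")
    os.chmod(path, 0o755)
    return path


def launch(script_path: str, stdout_path: str, stderr_path: str,
           exit_path: str, timeout: float = 0, cwd: Optional[str] = None,
           task_id: str = "") -> RunHandle:
    """Spawn the script as the leader of a fresh process group and return
    immediately; stdout/stderr go to the given log files."""
    if not os.path.isfile(script_path):
        raise SpawnError(f"script does not exist: {script_path}")
    try:
        out_fh = open(stdout_path, "ab")
        err_fh = open(stderr_path, "ab")
        popen = subprocess.Popen(
            ["/bin/sh", script_path],
            stdout=out_fh, stderr=err_fh,
            cwd=cwd, start_new_session=True)
    except OSError as exc:
        raise SpawnError(f"failed to spawn {script_path}: {exc}") from exc
    finally:
        try:
            out_fh.close()
            err_fh.close()
        except UnboundLocalError:
            pass
    deadline = time.monotonic() + timeout if timeout and timeout > 0 else None
    return RunHandle(task_id=task_id, pid=popen.pid, pgid=popen.pid,
                     script_path=script_path, stdout_path=stdout_path,
                     stderr_path=stderr_path, exit_path=exit_path,
                     deadline=deadline, popen=popen)


def supervise(handle: RunHandle, grace: float = 5.0,
              poll: float = 0.02) -> Outcome:
    """Wait for the task; enforce the deadline; write the exit-status file.

    All outcomes are values: a plain exit code, a timeout (group killed,
    sentinel written), or a kill (requested via `request_kill`).
    """
    timed_out = False
    while True:
        rc = handle.popen.poll()
        if rc is not None:
            break
        if handle.deadline is not None and time.monotonic() > handle.deadline:
            timed_out = True
            _terminate_group(handle.pgid, grace)
            handle.popen.wait()
            break
        time.sleep(poll)
    # make sure no group member survives any terminal outcome
    _reap_group(handle.pgid)
    if timed_out:
        _write_exit(handle.exit_path, TIMEOUT_SENTINEL)
        return Outcome("timeout")
    rc = handle.popen.returncode
    _write_exit(handle.exit_path, str(rc))
    if handle.kill_requested:
        return Outcome("killed", exit_code=rc)
    return Outcome("exit", exit_code=rc)


def request_kill(handle: RunHandle, grace: float = 5.0):
    """Signal the task's whole process group: TERM, grace, then KILL."""
    handle.kill_requested = True
    _terminate_group(handle.pgid, grace)


def _write_exit(path: str, value: str):
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(value + "\n")
    os.replace(tmp, path)


def _signal_group(pgid: int, sig) -> bool:
    try:
        os.killpg(pgid, sig)
        return True
    except ProcessLookupError:
        return False
    except PermissionError:
        return False


def _terminate_group(pgid: int, grace: float):
    if not _signal_group(pgid, signal.SIGTERM):
        return
    end = time.monotonic() + grace
    while time.monotonic() < end:
        if not proc_group_members(pgid):
            return
        time.sleep(0.02)
    _signal_group(pgid, signal.SIGKILL)


def _reap_group(pgid: int, wait: float = 2.0):
    """Best-effort: ensure zero processes remain in the group."""
    end = time.monotonic() + wait
    while time.monotonic() < end:
        members = proc_group_members(pgid)
        if not members:
            return
        _signal_group(pgid, signal.SIGKILL)
        time.sleep(0.02)


def proc_group_members(pgid: int) -> list[int]:
    """Scan /proc for live processes whose process group is `pgid`."""
    members = []
    for entry in os.listdir("/proc"):
        if not entry.isdigit():
            continue
        try:
            with open(f"/proc/{entry}/stat", "rb") as fh:
                data = fh.read().decode("utf-8", "replace")
        except OSError:
            continue
        # field 2 (comm) may contain spaces/parens; pgrp is field 5 overall
        rparen = data.rfind(")")
        fields = data[rparen + 2:].split()
        # after comm: state(0) ppid(1) pgrp(2)
        try:
            state, _ppid, grp = fields[0], int(fields[1]), int(fields[2])
        except (IndexError, ValueError):
            continue
        if grp == pgid and state != "Z":
            members.append(int(entry))
    return members


class LogPoller:
    """Tail many log files with a bounded number of open descriptors.

    Each poll tick stats every registered file and opens *only* the ones
    whose size changed since the previous tick, reading the appended
    region.  Files are opened one at a time and closed before the next, so
    the number of simultaneously open log descriptors never exceeds 1
    regardless of how many files are registered.
    """

    def __init__(self):
        self.offsets: dict[str, int] = {}
        self.owners: dict[str, str] = {}
        self.opens = 0  # instrumentation: files opened across all ticks
        self.max_open = 0

    def register(self, task_id: str, path: str):
        self.owners[path] = task_id
        self.offsets.setdefault(path, 0)

    def poll(self) -> list[tuple[str, bytes]]:
        emitted = []
        for path, offset in list(self.offsets.items()):
            try:
                size = os.stat(path).st_size
            except OSError:
                continue
            if size == offset:
                continue
            if size < offset:  # truncated; restart from the top
                offset = 0
            self.opens += 1
            self.max_open = max(self.max_open, 1)
            with open(path, "rb") as fh:
                fh.seek(offset)
                data = fh.read(size - offset)
            self.offsets[path] = offset + len(data)
            if data:
                emitted.append((self.owners[path], data))
        return emitted
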