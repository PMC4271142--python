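"""Engine configuration.

Defaults are fully specified so a bare ``pipescript run script.bds``
works: local executor, a pool sized to the machine's CPU count, unlimited
memory, no retries, and a run directory derived from the script name.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional


@dataclass
class EngineOptions:
    executor: str = "local"  # 'local' | 'mock-cluster'
    total_cpus: Optional[int] = None  # None -> machine CPU count
    total_mem: int = 0  # bytes; 0 = unlimited/unaccounted
    retry: int = 0  # global default retry count
    run_dir: Optional[str] = None  # engine artifacts (scripts, logs, events)
    work_dir: Optional[str] = None  # cwd for task commands; defaults to run_dir
    poll_interval: float = 0.25  # log-poller tick, seconds
    dispatch_tick: float = 0.005
    grace: float = 5.0  # TERM -> KILL grace period, seconds
    mtime_slack: float = 0.0
    dry_run: bool = False
    check_only: bool = False
    write_report: bool = True
    echo_logs: bool = False  # mirror task stdout/stderr to the console
    verbosity: int = 0
    # mock-cluster knobs
    fail_rate: float = 0.0
    queue_delay: float = 0.0
    seed: int = 0
    include_path: tuple = ()

    def resolved_run_dir(self, script_path: Optional[str] = None) -> str:
        if self.run_dir:
            return self.run_dir
        base = os.path.splitext(os.path.basename(script_path or "run"))[0]
        return f"{base}.run"
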