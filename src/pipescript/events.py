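"""Append-only event log of task lifecycle transitions.

One line per transition: ``<monotonic-ish timestamp>\t<id>\t<old>\t<new>``.
Tests and the report module consume it; the scheduler's conservation and
concurrency properties are asserted by replaying it.
"""

from __future__ import annotations

import os
import threading
import time


class EventLog:
    def __init__(self, path=None):
        self.path = path
        self.events = []  # (timestamp, unit_id, old_state, new_state)
        self._lock = threading.Lock()
        self._fh = None
        if path is not None:
            os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
            self._fh = open(path, "a", encoding="utf-8")

    def record(self, unit_id, old, new):
        t = time.time()
        with self._lock:
            self.events.append((t, unit_id, old, new))
            if self._fh is not None:
                self._fh.write(f"{t:.6f}\t{unit_id}\t{old}\t{new}\n")
                self._fh.flush()

    def close(self):
        with self._lock:
            if self._fh is not None:
                self._fh.close()
                self._fh = None

    def snapshot(self):
        with self._lock:
            return list(self.events)

    def max_concurrent(self, state="RUNNING", id_prefix=None):
        """Peak number of units simultaneously in `state` (event replay)."""
        current = set()
        peak = 0
        for _, unit_id, old, new in self.snapshot():
            if id_prefix is not None and not unit_id.startswith(id_prefix):
                continue
            if new == state:
                current.add(unit_id)
                peak = max(peak, len(current))
            elif old == state:
                current.discard(unit_id)
        return peak

    def count_transitions(self, new_state, id_prefix=None, distinct=False):
        seen = set()
        count = 0
        for _, unit_id, _, new in self.snapshot():
            if new != new_state:
                continue
            if id_prefix is not None and not unit_id.startswith(id_prefix):
                continue
            if distinct:
                seen.add(unit_id)
            else:
                count += 1
        return len(seen) if distinct else count
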