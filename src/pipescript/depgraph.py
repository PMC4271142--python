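"""Lazy-processing dependency graph.

Implements the four-clause out-of-date rule behind the dependency operator
(an output triggers regeneration when it does not exist, has zero length,
is an empty directory, or is older than any input), the inferred
producer/consumer DAG over declared task files, and deferred `dep`/`goal`
resolution that tolerates deleted intermediate files: if the final targets
are newer than the transitive *source* inputs, nothing runs at all.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import CycleError, DuplicateProducerError, UnproducibleTargetError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- stamps

@dataclass(frozen=True)
class FileStamp:
    path: str
    exists: bool
    size: int = 0
    mtime: float = 0.0
    is_dir: bool = False
    dir_empty: bool = False


def stamp(path: str) -> FileStamp:
    """Snapshot filesystem metadata; never raises for missing paths.

    A directory's effective mtime is the max over its immediate entries, so
    directories behave as first-class dependencies.
    """
    try:
        st = os.stat(path)
    except OSError:
        return FileStamp(path, exists=False)
    if os.path.isdir(path):
        try:
            entries = os.listdir(path)
        except OSError:
            entries = []
        mtime = st.st_mtime
        for entry in entries:
            try:
                mtime = max(mtime, os.stat(os.path.join(path, entry)).st_mtime)
            except OSError:
                pass
        return FileStamp(path, exists=True, size=st.st_size, mtime=mtime,
                         is_dir=True, dir_empty=not entries)
    return FileStamp(path, exists=True, size=st.st_size, mtime=st.st_mtime)


def _out_bad(s: FileStamp) -> bool:
    """Clauses independent of inputs: missing, zero length, empty directory."""
    if not s.exists:
        return True
    if s.is_dir:
        return s.dir_empty
    return s.size == 0


def needs_update(outs, ins, base_dir: Optional[str] = None,
                 mtime_slack: float = 0.0) -> bool:
    """The dependency operator: true iff any output must be regenerated.

    True iff any out is missing / zero-length / an empty directory, or
    min(out mtimes) < max(in mtimes) (strict, minus `mtime_slack` for
    coarse filesystem clocks).  A missing input triggers an update with a
    warning, since an upstream step may regenerate it.  With no inputs only
    the output-only clauses apply.
    """
    outs = [_resolve(p, base_dir) for p in _as_list(outs)]
    ins = [_resolve(p, base_dir) for p in _as_list(ins)]
    out_stamps = [stamp(p) for p in outs]
    if any(_out_bad(s) for s in out_stamps):
        return True
    if not ins:
        return False
    in_stamps = [stamp(p) for p in ins]
    for s in in_stamps:
        if not s.exists:
            log.warning("dependency input %s does not exist", s.path)
            return True
    min_out = min(s.mtime for s in out_stamps)
    max_in = max(s.mtime for s in in_stamps)
    return min_out < max_in - mtime_slack


def _as_list(value):
    if value is None:
        return []
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


def _resolve(path, base_dir):
    if base_dir and not os.path.isabs(path):
        return os.path.join(base_dir, path)
    return path


# ---------------------------------------------------------------- graph

@dataclass
class DepNode:
    node_id: str
    kind: str  # 'task' | 'dep'
    spec: object  # TaskSpec (opaque here)
    outs: list
    ins: list
    state: str = "deferred"  # deferred | planned | submitted | done | failed


class DependencyGraph:
    """Producer/consumer DAG inferred from declared ins/outs.

    Nodes are task/dep declarations; an edge P -> C exists when C consumes
    a path that P produces.  Each path has at most one producer.
    """

    def __init__(self, base_dir: Optional[str] = None):
        self.base_dir = base_dir
        self.nodes: dict[str, DepNode] = {}
        self.file_index: dict[str, str] = {}  # resolved path -> producer node id
        self.graph = nx.DiGraph()

    def resolve(self, path: str) -> str:
        return _resolve(path, self.base_dir)

    def producer_of(self, path: str) -> Optional[DepNode]:
        nid = self.file_index.get(self.resolve(path))
        return self.nodes[nid] if nid is not None else None

    def register(self, node: DepNode) -> None:
        for out in node.outs:
            key = self.resolve(out)
            if key in self.file_index:
                raise DuplicateProducerError(
                    f"{out!r} is already produced by {self.file_index[key]}")
        self.nodes[node.node_id] = node
        self.graph.add_node(node.node_id)
        for out in node.outs:
            self.file_index[self.resolve(out)] = node.node_id
        for inp in node.ins:
            producer = self.file_index.get(self.resolve(inp))
            if producer is not None and producer != node.node_id:
                self.graph.add_edge(producer, node.node_id)
        # a newly produced path may feed nodes registered earlier
        for other in self.nodes.values():
            if other.node_id == node.node_id:
                continue
            for inp in other.ins:
                if self.file_index.get(self.resolve(inp)) == node.node_id:
                    self.graph.add_edge(node.node_id, other.node_id)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            # undo the registration to keep the graph consistent
            self.graph.remove_node(node.node_id)
            del self.nodes[node.node_id]
            for out in node.outs:
                del self.file_index[self.resolve(out)]
            raise CycleError(f"dependency cycle: {cycle}")

    def predecessors(self, node_id: str):
        return list(self.graph.predecessors(node_id))

    # ------------------------------------------------------------ goals

    def effective_time(self, path: str, _seen=frozenset()) -> float:
        """Mtime of `path` if it is present and usable; otherwise look
        through the deleted/empty intermediate to its producer's inputs.
        Sources that are missing contribute nothing (with a warning)."""
        key = self.resolve(path)
        if key in _seen:
            return float("-inf")
        s = stamp(key)
        if s.exists and not _out_bad(s):
            return s.mtime
        producer = self.producer_of(path)
        if producer is None:
            if not s.exists:
                log.warning("source input %s does not exist and has no producer",
                            path)
            return float("-inf")
        times = [self.effective_time(p, _seen | {key}) for p in producer.ins]
        return max(times) if times else float("-inf")

    def _consistent(self, dnode: DepNode) -> bool:
        """Every *existing, usable* output of `dnode` is at least as new as
        the effective time of every input; missing outputs do not count
        against consistency (deleted intermediates are tolerated)."""
        in_time = max((self.effective_time(p) for p in dnode.ins),
                      default=float("-inf"))
        for out in dnode.outs:
            s = stamp(self.resolve(out))
            if s.exists and not _out_bad(s) and s.mtime < in_time:
                return False
        return True

    def _ancestors_of(self, targets) -> list[str]:
        """Producer node ids reachable backwards from the targets, in
        topological order."""
        seen = set()
        stack = []
        for t in _as_list(targets):
            producer = self.producer_of(t)
            if producer is not None:
                stack.append(producer.node_id)
        while stack:
            nid = stack.pop()
            if nid in seen:
                continue
            seen.add(nid)
            stack.extend(self.graph.predecessors(nid))
        return [nid for nid in nx.topological_sort(self.graph) if nid in seen]

    def resolve_goal(self, targets) -> list[DepNode]:
        """Minimal topologically ordered plan bringing `targets` up to date.

        A producer enters the plan iff (a) a demanded output (a target, or
        an input a planned consumer must read) is missing or unusable,
        (b) one of its existing outputs is older than the effective time
        of its inputs, or (c) the producer of one of its inputs is itself
        planned (a rebuilt input invalidates everything downstream).  When
        the targets are consistent with the transitive source inputs the
        plan is empty, even if intermediate files have been deleted.
        """
        targets = _as_list(targets)
        for t in targets:
            if self.producer_of(t) is None and not stamp(self.resolve(t)).exists:
                raise UnproducibleTargetError(
                    f"target {t!r} does not exist and no task produces it")
        order = self._ancestors_of(targets)
        demand = {self.resolve(t) for t in targets}
        planned: set[str] = set()
        changed = True
        while changed:
            changed = False
            for nid in order:
                if nid in planned:
                    continue
                dnode = self.nodes[nid]
                demanded_missing = any(
                    self.resolve(out) in demand and
                    _out_bad(stamp(self.resolve(out)))
                    for out in dnode.outs)
                cascade = any(
                    (p := self.producer_of(inp)) is not None
                    and p.node_id in planned
                    for inp in dnode.ins)
                if demanded_missing or cascade or not self._consistent(dnode):
                    planned.add(nid)
                    changed = True
                    for inp in dnode.ins:
                        if self.producer_of(inp) is not None and \
                                _out_bad(stamp(self.resolve(inp))):
                            demand.add(self.resolve(inp))
        return [self.nodes[nid] for nid in order if nid in planned]
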