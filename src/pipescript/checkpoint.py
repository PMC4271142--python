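"""Checkpoint files: absolute serialization of the engine state.

A checkpoint is a canonical JSON document (sorted keys, fixed separators,
so ``load`` followed by ``save`` is byte-identical) containing everything
needed to resume with no access to the original script: the embedded
source bundle and its hash, the program counter and scope chain of the
main thread, the task table, deferred dependency nodes, par-thread
snapshots, and the id counters.  Resume re-parses the embedded source
(node ids are deterministic), re-submits every non-terminal task, and
traverses the tree in recovery mode up to the recorded program counter.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

from . import typesys as T
from .config import EngineOptions
from .depgraph import DepNode
from .errors import (CorruptCheckpointError, StaleSourceError,
                     VersionMismatchError)
from .parser import parse
from .scheduler import TaskSpec, TaskRecord
from .typecheck import check_program

FORMAT_VERSION = 1

_TERMINAL_KEEP = {"DONE", "SKIPPED"}


# ---------------------------------------------------------------- canonical io

def save_document(data: dict, path: str) -> None:
    """Atomic canonical write (temp file + rename)."""
    text = json.dumps(data, sort_keys=True, indent=1, ensure_ascii=False,
                      allow_nan=False)
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write(text + "\n")
    os.replace(tmp, path)


def load_document(path: str) -> dict:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except (OSError, ValueError) as exc:
        raise CorruptCheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if not isinstance(data, dict) or "format_version" not in data:
        raise CorruptCheckpointError(f"{path} is not a checkpoint file")
    if data["format_version"] != FORMAT_VERSION:
        raise VersionMismatchError(
            f"checkpoint format {data['format_version']} != {FORMAT_VERSION}")
    return data


# ---------------------------------------------------------------- encoding

def _encode_scope(scope) -> dict:
    out = {}
    for name, (tag, value) in scope.bindings.items():
        out[name] = {"type": str(tag), "value": value}
    return out


def _decode_binding(entry):
    tag = T.parse_tag(entry["type"])
    value = entry["value"]
    if tag == T.REAL and isinstance(value, int):
        value = float(value)
    return tag, value


def _encode_spec(spec: TaskSpec) -> dict:
    return {"id": spec.id, "name": spec.name, "command": spec.command,
            "ins": spec.ins, "outs": spec.outs, "cpus": spec.cpus,
            "mem": spec.mem, "timeout": spec.timeout, "retry": spec.retry}


def _decode_spec(data) -> TaskSpec:
    return TaskSpec(id=data["id"], name=data["name"], command=data["command"],
                    ins=data["ins"], outs=data["outs"], cpus=data["cpus"],
                    mem=data["mem"], timeout=data["timeout"], retry=data["retry"])


# ---------------------------------------------------------------- serialize

def serialize_state(engine, ctx, path: str, reason: str, pc: int,
                    reexec: bool, capture_scope) -> str:
    """Write the full engine state; called only at statement boundaries."""
    chain = []
    scope = capture_scope
    while scope is not None:
        chain.append(scope)
        scope = scope.parent
    chain.reverse()  # global first

    tasks = []
    with engine.scheduler.lock:
        records = sorted(engine.scheduler.records.values(),
                         key=lambda r: _seq(r.spec.id))
        for rec in records:
            tasks.append({
                "spec": _encode_spec(rec.spec),
                "state": rec.state,
                "attempts": rec.attempts,
                "exit_code": rec.exit_code,
                "failure_reason": rec.failure_reason,
                "owner": rec.owner,
                "after": rec.after,
                "stdout_path": rec.stdout_path,
                "stderr_path": rec.stderr_path,
                "exit_path": rec.exit_path,
            })

    dep_nodes = []
    for node_id, dnode in engine.dep_nodes.items():
        dep_nodes.append({"id": node_id, "kind": dnode.kind, "state": dnode.state,
                          "outs": dnode.outs, "ins": dnode.ins,
                          "spec": _encode_spec(dnode.spec)})

    par = {}
    for par_id, rec in engine.par_records.items():
        entry = {"status": rec["status"], "node": rec["node"],
                 "error": rec.get("error")}
        if rec["status"] != "done":
            entry["scope"] = _encode_scope(rec["scope"])
        par[par_id] = entry

    data = {
        "format_version": FORMAT_VERSION,
        "reason": reason,
        "main_origin": engine.tree.order[0],
        "sources": engine.tree.sources,
        "order": engine.tree.order,
        "source_hash": engine.tree.source_hash,
        "pc": pc,
        "reexec": reexec,
        "scopes": [_encode_scope(s) for s in chain],
        "counters": {"task": engine.task_seq, "dep": engine.dep_seq,
                     "par": engine.par_seq},
        "tasks": tasks,
        "dep_nodes": dep_nodes,
        "par": par,
    }
    save_document(data, path)
    return path


def _seq(unit_id: str) -> int:
    try:
        return int(unit_id.rsplit(".", 1)[1])
    except (IndexError, ValueError):
        return 0


# ---------------------------------------------------------------- restore

def restore_into_engine(engine, ctx, data: dict) -> None:
    """Reconstruct scopes, task table, dep graph and counters; put the main
    thread in recovery mode aimed at the recorded program counter."""
    from .interpreter import Scope

    engine.task_seq = data["counters"]["task"]
    engine.dep_seq = data["counters"]["dep"]
    engine.par_seq = data["counters"]["par"]

    # par threads that did not finish re-run their whole block; their old
    # task records (and graph registrations) are dropped so the re-run can
    # declare the same outputs again
    rerun_pars = {par_id for par_id, entry in data["par"].items()
                  if entry["status"] != "done"}
    owners = {t["spec"]["id"]: t["owner"] for t in data["tasks"]}

    # dependency graph (producers must be known before tasks resubmit)
    for entry in data["dep_nodes"]:
        if owners.get(entry["id"]) in rerun_pars:
            continue
        dnode = DepNode(node_id=entry["id"], kind=entry["kind"],
                        spec=_decode_spec(entry["spec"]),
                        outs=entry["outs"], ins=entry["ins"],
                        state=entry["state"])
        if dnode.kind == "dep" and dnode.state in ("planned", "submitted"):
            # will be re-planned/resubmitted below via the task table
            dnode.state = "deferred"
        engine.graph.register(dnode)
        engine.dep_nodes[dnode.node_id] = dnode

    known = {t["spec"]["id"] for t in data["tasks"]
             if t["owner"] not in rerun_pars}
    for entry in data["tasks"]:
        if entry["owner"] in rerun_pars:
            continue
        spec = _decode_spec(entry["spec"])
        owner = entry["owner"]
        if entry["state"] in _TERMINAL_KEEP:
            record = TaskRecord(spec=spec, state=entry["state"],
                                attempts=entry["attempts"],
                                exit_code=entry["exit_code"],
                                failure_reason=entry["failure_reason"],
                                owner=entry["owner"],
                                after=entry["after"],
                                stdout_path=entry["stdout_path"],
                                stderr_path=entry["stderr_path"],
                                exit_path=entry["exit_path"])
            engine.scheduler.restore_record(record)
            engine.events.record(spec.id, "-", f"RESTORED:{entry['state']}")
        else:
            # pending/failed work is re-executed with a fresh retry budget
            after = [a for a in entry["after"] if a in known]
            engine.scheduler.submit(spec, after=after, owner=owner)
            dnode = engine.dep_nodes.get(spec.id)
            if dnode is not None:
                dnode.state = "submitted"
        if entry["owner"] == "main":
            ctx.spawned.append(spec.id)

    # scope chain: global bindings merge into the live global scope, inner
    # scopes are handed to the recovery traversal in nesting order
    scopes = data["scopes"]
    if scopes:
        for name, entry in scopes[0].items():
            tag, value = _decode_binding(entry)
            engine.global_scope.declare(name, tag, value)
    chain = []
    for encoded in scopes[1:]:
        scope = Scope()
        for name, entry in encoded.items():
            tag, value = _decode_binding(entry)
            scope.declare(name, tag, value)
        chain.append(scope)
    ctx.restore_chain = chain
    ctx.mode = "recover"
    ctx.recover_target = data["pc"]
    ctx.reexec = data["reexec"]

    # par threads: completed ones are remembered, unfinished ones re-run
    # their block from the start with their snapshot scope
    for par_id, entry in data["par"].items():
        if entry["status"] == "done":
            engine.par_records[par_id] = {"status": "done", "node": entry["node"],
                                          "scope": None, "error": entry.get("error")}
            ctx.spawned.append(par_id)
        else:
            snapshot = Scope()
            for name, benc in entry.get("scope", {}).items():
                tag, value = _decode_binding(benc)
                snapshot.declare(name, tag, value)
            node = engine.tree.node(entry["node"])
            engine._spawn_par(par_id, node, snapshot, ctx)


# ---------------------------------------------------------------- resume

def _bundle_resolver(sources: dict):
    def resolve(name: str, from_file: str):
        candidates = []
        if from_file:
            candidates.append(os.path.normpath(
                os.path.join(os.path.dirname(from_file), name)))
        candidates.append(name)
        for cand in candidates:
            if cand in sources:
                return cand, sources[cand]
        # fall back to basename matching (checkpoint may travel machines)
        for origin in sources:
            if os.path.basename(origin) == os.path.basename(name):
                return origin, sources[origin]
        return None

    return resolve


def resume(path: str, options: Optional[EngineOptions] = None,
           script_override: Optional[str] = None, stdout=None):
    """Re-execute a checkpointed program from where it stopped.

    Uses the source text embedded in the checkpoint; `script_override`
    only *validates* that an on-disk script still matches (a checkpoint is
    not valid against modified source).
    """
    from .interpreter import Engine

    data = load_document(path)
    if script_override is not None:
        with open(script_override, "r", encoding="utf-8") as fh:
            text = fh.read()
        digest = hashlib.sha256()
        digest.update(text.encode("utf-8"))
        for origin in data["order"][1:]:
            digest.update(data["sources"][origin].encode("utf-8"))
        if digest.hexdigest() != data["source_hash"]:
            raise StaleSourceError(
                "checkpoint is no longer valid with respect to the new "
                f"source code in {script_override}")
    main_origin = data["main_origin"]
    tree = parse(data["sources"][main_origin], origin=main_origin,
                 resolver=_bundle_resolver(data["sources"]))
    typed = check_program(tree)
    engine = Engine(typed, options=options, restore=data,
                    script_path=main_origin, stdout=stdout)
    return engine.run()


# ---------------------------------------------------------------- inspect

def inspect(path: str) -> str:
    """Human-readable, read-only dump of a checkpoint: variables per
    scope, the program counter, and the task table with failure reasons."""
    data = load_document(path)
    lines = []
    lines.append(f"checkpoint: {path}")
    lines.append(f"  reason: {data['reason']}")
    lines.append(f"  script: {data['main_origin']}")
    lines.append(f"  source hash: {data['source_hash']}")
    pc_where = ""
    if data["pc"] >= 0:
        try:
            tree = parse(data["sources"][data["main_origin"]],
                         origin=data["main_origin"],
                         resolver=_bundle_resolver(data["sources"]))
            pc_where = f" at {tree.node(data['pc']).pos}"
        except Exception:  # a dump must never fail on a parse hiccup
            pc_where = ""
    lines.append(f"  program counter: node {data['pc']}{pc_where}"
                 + (" (re-execute)" if data["reexec"] else " (resume after)"))
    for depth, scope in enumerate(data["scopes"]):
        label = "globals" if depth == 0 else f"scope[{depth}]"
        lines.append(f"  {label}:")
        for name in sorted(scope):
            entry = scope[name]
            lines.append(f"    {entry['type']} {name} = {entry['value']!r}")
    lines.append("  tasks:")
    for task in data["tasks"]:
        spec = task["spec"]
        extra = ""
        if task["failure_reason"]:
            extra = f" reason={task['failure_reason']!r} stderr={task['stderr_path']}"
        lines.append(f"    {spec['id']} [{task['state']}] attempts={task['attempts']}"
                     f" exit={task['exit_code']}{extra}")
    for par_id, entry in sorted(data["par"].items()):
        lines.append(f"  par {par_id}: {entry['status']}")
    return "\n".join(lines) + "\n"
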