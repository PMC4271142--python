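"""Tree-walking interpreter and engine orchestration.

Executes the typed tree: expression evaluation, control flow, functions,
task/par spawning, wait barriers, and checkpoint cooperation.  The
interpreter runs in one of two traversal modes:

* **run** — normal execution;
* **recover** — used on resume: statements are skipped (no side effects)
  while descending only into the subtree containing the serialized program
  counter; on reaching it the engine switches to run mode, so execution
  continues exactly where the checkpointed run stopped.  Scopes along the
  descent are not rebuilt by re-executing declarations but restored from
  the checkpoint.

An implicit global wait at the end of the main thread means the program
never exits while tasks or par-threads are still live; any failure there
(or at an explicit wait) writes a checkpoint, reports the failed tasks,
and exits nonzero.
"""

from __future__ import annotations

import logging
import os
import subprocess
import sys as _sys
import threading
import time
from dataclasses import dataclass, field
from typing import Optional

from . import ast_nodes as A
from . import typesys as T
from .config import EngineOptions
from .depgraph import DependencyGraph, DepNode, needs_update
from .errors import (PipeScriptError, ResourceError, RuntimeFault, SysFailure,
                     UnknownIdError)
from .events import EventLog
from .runner import LogPoller
from .scheduler import Scheduler, TaskSpec
from .typecheck import TIME_CONSTANTS, TypedTree

log = logging.getLogger(__name__)

#: hidden binding carrying a for-in loop's iteration index across checkpoints
_ITER_KEY = "$idx"

#: recover-target sentinel meaning "the implicit wait at program end"
PC_PROGRAM_END = -1


@dataclass
class ExitStatus:
    code: int
    reason: str  # ok | task-failed | type-error | runtime-error | interrupted

    def __post_init__(self):
        assert (self.code == 0) == (self.reason == "ok")


class Scope:
    """Lexical scope: innermost-first lookup, global scope at the root."""

    __slots__ = ("bindings", "parent")

    def __init__(self, parent=None):
        self.bindings: dict[str, list] = {}  # name -> [TypeTag, value]
        self.parent = parent

    def declare(self, name, tag, value):
        self.bindings[name] = [tag, value]

    def find(self, name):
        scope = self
        while scope is not None:
            if name in scope.bindings:
                return scope.bindings[name]
            scope = scope.parent
        return None

    def get(self, name):
        entry = self.find(name)
        if entry is None:
            raise KeyError(name)
        return entry[1]

    def set(self, name, value):
        entry = self.find(name)
        if entry is None:
            raise KeyError(name)
        entry[1] = value

    def flatten(self) -> "Scope":
        """Snapshot of every visible binding in a single parentless scope;
        container values are copied (par threads must not share lists)."""
        snap = Scope()
        chain = []
        scope = self
        while scope is not None:
            chain.append(scope)
            scope = scope.parent
        for scope in reversed(chain):  # outer first so inner shadows win
            for name, (tag, value) in scope.bindings.items():
                snap.bindings[name] = [tag, list(value) if isinstance(value, list)
                                       else value]
        return snap


# ------------------------------------------------------------ control flow

class _Break(Exception):
    pass


class _Continue(Exception):
    pass


class _Return(Exception):
    def __init__(self, value):
        self.value = value


class _Exit(Exception):
    def __init__(self, code):
        self.code = code


class WaitFailure(Exception):
    """Raised at a wait barrier when a joined unit failed."""

    def __init__(self, failed_ids):
        self.failed_ids = failed_ids
        super().__init__(f"failed units: {', '.join(failed_ids)}")


class ThreadCtx:
    """Per interpreter-thread execution state."""

    def __init__(self, thread_id: str, mode: str = "run",
                 recover_target: int = -2, reexec: bool = False):
        self.id = thread_id
        self.spawned: list[str] = []  # task/par ids created by this thread
        self.mode = mode
        self.recover_target = recover_target
        self.reexec = reexec
        self.restore_chain: list[Scope] = []
        self.restore_idx = 0
        self.stmt_stack: list[tuple] = []  # (stmt, scope, fn_depth)
        self.fault_stack = None  # stack snapshot at the moment of a fault
        self.fn_depth = 0

    def next_restored_scope(self, parent: Scope) -> Scope:
        if self.restore_idx < len(self.restore_chain):
            scope = self.restore_chain[self.restore_idx]
            self.restore_idx += 1
            scope.parent = parent
            return scope
        return Scope(parent)


# ------------------------------------------------------------ value rendering

def display(value) -> str:
    """Render a value the way print and string concatenation see it."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, list):
        return "[" + ", ".join(display(v) for v in value) + "]"
    return str(value)


def interp_value(value) -> str:
    """Render a value for command-line interpolation (lists space-joined)."""
    if isinstance(value, list):
        return " ".join(display(v) for v in value)
    return display(value)


# ------------------------------------------------------------ engine

class Engine:
    def __init__(self, typed: TypedTree, options: Optional[EngineOptions] = None,
                 overrides: Optional[dict] = None, restore: Optional[dict] = None,
                 script_path: Optional[str] = None, stdout=None):
        self.typed = typed
        self.tree = typed.tree
        self.options = options or EngineOptions()
        self.overrides = dict(overrides or {})
        self.restore = restore
        self.script_path = script_path or self.tree.order[0]
        self.stdout = stdout if stdout is not None else _sys.stdout

        self.run_dir = os.path.abspath(self.options.resolved_run_dir(self.script_path))
        os.makedirs(self.run_dir, exist_ok=True)
        self.work_dir = os.path.abspath(self.options.work_dir or self.run_dir)
        os.makedirs(self.work_dir, exist_ok=True)

        self.events = EventLog(os.path.join(self.run_dir, "events.log"))
        self.scheduler = Scheduler(
            self.events, self.run_dir,
            executor=self.options.executor,
            total_cpus=self.options.total_cpus,
            total_mem=self.options.total_mem,
            fail_rate=self.options.fail_rate,
            queue_delay=self.options.queue_delay,
            seed=self.options.seed,
            grace=self.options.grace,
            tick=self.options.dispatch_tick,
            work_dir=self.work_dir)
        self.graph = DependencyGraph(base_dir=self.work_dir)
        self.dep_nodes: dict[str, DepNode] = {}  # declaration order preserved
        self.global_scope = Scope()
        for name, value in TIME_CONSTANTS.items():
            self.global_scope.declare(name, T.INT, value)
        self.task_seq = 0
        self.dep_seq = 0
        self.par_seq = 0
        self.par_records: dict[str, dict] = {}
        self.par_threads: dict[str, threading.Thread] = {}
        self.par_ctxs: dict[str, ThreadCtx] = {}
        self._seq_lock = threading.Lock()
        self.last_checkpoint: Optional[str] = None
        self._poller_stop = threading.Event()
        self._poller_thread = None

    # -------------------------------------------------------- public API

    def run(self) -> ExitStatus:
        ctx = ThreadCtx("main")
        if self.restore is not None:
            self._apply_restore(ctx)
        self.scheduler.start()
        if self.options.echo_logs:
            self._start_poller()
        status = None
        try:
            try:
                if not (ctx.mode == "recover" and
                        ctx.recover_target == PC_PROGRAM_END):
                    self.exec_stmts(self.tree.root.stmts, self.global_scope, ctx)
                else:
                    ctx.mode = "run"
                status = self._finalize(ctx, explicit_code=None)
            except _Exit as e:
                status = self._finalize(ctx, explicit_code=e.code)
            except WaitFailure as e:
                self._join_everything()
                self._checkpoint(ctx, "wait-failure")
                self._report_failures()
                status = ExitStatus(1, "task-failed")
            except (RuntimeFault, ResourceError, PipeScriptError) as e:
                self._emit(f"! error: {e}\n")
                self.scheduler.kill_all()
                self._checkpoint(ctx, "runtime-error")
                status = ExitStatus(1, "runtime-error")
            except KeyboardInterrupt:
                self._emit("! interrupted\n")
                self.scheduler.kill_all()
                self._checkpoint(ctx, "interrupt")
                status = ExitStatus(130, "interrupted")
        finally:
            self._stop_poller()
            self.scheduler.shutdown()
            if self.options.write_report:
                from .report import write_report
                try:
                    write_report(self)
                except OSError as exc:  # non-fatal
                    log.warning("could not write report: %s", exc)
            self.events.close()
        return status

    def _finalize(self, ctx, explicit_code) -> ExitStatus:
        """The implicit global wait at the end of the main thread."""
        self._join_everything()
        failed = self.scheduler.failed_records()
        failed_pars = [pid for pid, rec in self.par_records.items()
                       if rec.get("status") == "failed"]
        if failed or failed_pars:
            ctx.stmt_stack = []  # resume target: program end
            ctx.fault_stack = None
            self._checkpoint(ctx, "wait-failure")
            self._report_failures()
            return ExitStatus(1, "task-failed")
        if explicit_code is not None and explicit_code != 0:
            return ExitStatus(explicit_code, "runtime-error")
        return ExitStatus(0, "ok")

    def _join_everything(self):
        for thread in list(self.par_threads.values()):
            thread.join()
        self.scheduler.wait_all()

    def _report_failures(self):
        for record in self.scheduler.failed_records():
            self._emit(
                f"! task {record.spec.id} ({record.spec.name or 'unnamed'}) "
                f"{record.state}: {record.failure_reason or ''} "
                f"[attempts={record.attempts}, stderr={record.stderr_path}]\n")
        for pid, rec in self.par_records.items():
            if rec.get("status") == "failed":
                self._emit(f"! par thread {pid} failed: {rec.get('error', '')}\n")

    def _emit(self, text: str):
        self.stdout.write(text)
        try:
            self.stdout.flush()
        except (AttributeError, OSError):
            pass

    # -------------------------------------------------------- log echo

    def _start_poller(self):
        poller = LogPoller()
        registered = set()

        def loop():
            while True:
                stopping = self._poller_stop.is_set()
                with self.scheduler.lock:
                    for rec in self.scheduler.records.values():
                        for path in (rec.stdout_path, rec.stderr_path):
                            if path and path not in registered:
                                poller.register(rec.spec.id, path)
                                registered.add(path)
                for task_id, data in poller.poll():
                    text = data.decode("utf-8", "replace")
                    for line in text.splitlines():
                        self._emit(f"[{task_id}] {line}\n")
                if stopping:  # one final sweep after the engine finished
                    return
                self._poller_stop.wait(self.options.poll_interval)

        self._poller_thread = threading.Thread(target=loop, daemon=True)
        self._poller_thread.start()

    def _stop_poller(self):
        self._poller_stop.set()
        if self._poller_thread is not None:
            self._poller_thread.join(timeout=5)

    # -------------------------------------------------------- statements

    def exec_stmts(self, stmts, scope, ctx):
        for stmt in stmts:
            self.exec_stmt(stmt, scope, ctx)

    def exec_stmt(self, stmt, scope, ctx):
        if ctx.mode == "recover":
            if stmt.nid == ctx.recover_target:
                ctx.mode = "run"
                if not ctx.reexec:
                    return
            elif not stmt.contains(ctx.recover_target):
                return
            else:
                return self._recover_into(stmt, scope, ctx)
        ctx.stmt_stack.append((stmt, scope, ctx.fn_depth))
        try:
            self._dispatch(stmt, scope, ctx)
        except (WaitFailure, PipeScriptError, KeyboardInterrupt):
            # snapshot the stack before unwinding so the checkpoint's
            # program counter points at the faulting statement
            if ctx.fault_stack is None:
                ctx.fault_stack = list(ctx.stmt_stack)
            raise
        finally:
            ctx.stmt_stack.pop()

    def _recover_into(self, stmt, scope, ctx):
        """Descend, without side effects, into the compound statement that
        contains the recovery target."""
        if isinstance(stmt, A.Block):
            inner = ctx.next_restored_scope(scope)
            self.exec_stmts(stmt.stmts, inner, ctx)
            return
        if isinstance(stmt, A.If):
            for branch in (stmt.then, stmt.els):
                if branch is not None and branch.contains(ctx.recover_target):
                    self.exec_stmt(branch, scope, ctx)
                    return
            return
        if isinstance(stmt, A.While):
            ctx.stmt_stack.append((stmt, scope, ctx.fn_depth))
            try:
                try:
                    self.exec_stmt(stmt.body, scope, ctx)  # recovered iteration
                except _Break:
                    return
                except _Continue:
                    pass
                if ctx.mode != "run":
                    return
                self._run_while(stmt, scope, ctx)
            finally:
                ctx.stmt_stack.pop()
            return
        if isinstance(stmt, A.ForC):
            ctx.stmt_stack.append((stmt, scope, ctx.fn_depth))
            try:
                for_scope = ctx.next_restored_scope(scope)
                try:
                    self.exec_stmt(stmt.body, for_scope, ctx)
                except _Break:
                    return
                except _Continue:
                    pass
                if ctx.mode != "run":
                    return
                if stmt.update is not None:
                    self._dispatch(stmt.update, for_scope, ctx)
                self._run_forc_loop(stmt, for_scope, ctx)
            finally:
                ctx.stmt_stack.pop()
            return
        if isinstance(stmt, A.ForIn):
            ctx.stmt_stack.append((stmt, scope, ctx.fn_depth))
            try:
                for_scope = ctx.next_restored_scope(scope)
                try:
                    self.exec_stmt(stmt.body, for_scope, ctx)
                except _Break:
                    return
                except _Continue:
                    pass
                if ctx.mode != "run":
                    return
                items = self._as_iter(self.eval(stmt.iterable, for_scope, ctx))
                idx = for_scope.get(_ITER_KEY) + 1
                self._run_forin_loop(stmt, for_scope, ctx, items, idx)
            finally:
                ctx.stmt_stack.pop()
            return
        # leaf statements cannot contain another statement's pc; a target
        # inside an expression subtree means "re-execute this statement"
        ctx.mode = "run"
        self.exec_stmt(stmt, scope, ctx)

    def _dispatch(self, stmt, scope, ctx):
        method = self._DISPATCH.get(type(stmt))
        if method is None:
            raise RuntimeFault(f"cannot execute {stmt.kind}", stmt.pos)
        method(self, stmt, scope, ctx)

    def _exec_decl(self, stmt: A.VarDecl, scope, ctx):
        if scope is self.global_scope and ctx.fn_depth == 0 \
                and stmt.name in self.overrides:
            tag = self._decl_tag(stmt)
            scope.declare(stmt.name, tag, self.overrides[stmt.name])
            return
        tag = self._decl_tag(stmt)
        if stmt.init is not None:
            value = self.eval(stmt.init, scope, ctx)
        else:
            value = T.default_value(tag)
        value = self._coerce(tag, value)
        scope.declare(stmt.name, tag, value)

    def _decl_tag(self, stmt: A.VarDecl) -> T.TypeTag:
        if stmt.declared is not None:
            return stmt.declared
        return self.typed.types[stmt.init.nid]

    @staticmethod
    def _coerce(tag, value):
        if tag == T.REAL and isinstance(value, int) and not isinstance(value, bool):
            return float(value)
        return value

    def _exec_assign(self, stmt: A.Assign, scope, ctx):
        value = self.eval(stmt.value, scope, ctx)
        entry = scope.find(stmt.name)
        tag = entry[0]
        if stmt.op == "=":
            entry[1] = self._coerce(tag, value)
            return
        current = entry[1]
        op = "+" if stmt.op == "+=" else "-"
        entry[1] = self._coerce(tag, self._binop(op, current, value, tag, stmt.pos))

    def _exec_incdec(self, stmt: A.IncDec, scope, ctx):
        entry = scope.find(stmt.name)
        entry[1] = entry[1] + (1 if stmt.op == "++" else -1)

    def _exec_if(self, stmt: A.If, scope, ctx):
        if self.eval(stmt.cond, scope, ctx):
            self.exec_stmt(stmt.then, scope, ctx)
        elif stmt.els is not None:
            self.exec_stmt(stmt.els, scope, ctx)

    def _exec_while(self, stmt: A.While, scope, ctx):
        self._run_while(stmt, scope, ctx)

    def _run_while(self, stmt, scope, ctx):
        while self.eval(stmt.cond, scope, ctx):
            try:
                self.exec_stmt(stmt.body, scope, ctx)
            except _Break:
                break
            except _Continue:
                continue

    def _exec_forc(self, stmt: A.ForC, scope, ctx):
        for_scope = Scope(scope)
        if stmt.init is not None:
            self._dispatch(stmt.init, for_scope, ctx)
        self._run_forc_loop(stmt, for_scope, ctx)

    def _run_forc_loop(self, stmt, for_scope, ctx):
        while self.eval(stmt.cond, for_scope, ctx):
            try:
                self.exec_stmt(stmt.body, for_scope, ctx)
            except _Break:
                return
            except _Continue:
                pass
            if stmt.update is not None:
                self._dispatch(stmt.update, for_scope, ctx)

    def _exec_forin(self, stmt: A.ForIn, scope, ctx):
        items = self._as_iter(self.eval(stmt.iterable, scope, ctx))
        for_scope = Scope(scope)
        elem_tag = stmt.var_type or self._elem_tag(stmt.iterable)
        for_scope.declare(stmt.var_name, elem_tag, None)
        for_scope.declare(_ITER_KEY, T.INT, 0)
        self._run_forin_loop(stmt, for_scope, ctx, items, 0)

    def _elem_tag(self, iterable_node):
        tag = self.typed.types[iterable_node.nid]
        return tag.element if tag.is_list else T.ERROR

    def _run_forin_loop(self, stmt, for_scope, ctx, items, start_idx):
        idx = start_idx
        while idx < len(items):
            for_scope.set(stmt.var_name, items[idx])
            for_scope.set(_ITER_KEY, idx)
            try:
                self.exec_stmt(stmt.body, for_scope, ctx)
            except _Break:
                return
            except _Continue:
                pass
            idx += 1

    @staticmethod
    def _as_iter(value):
        if not isinstance(value, list):
            raise RuntimeFault("for-in requires a list value")
        return value

    def _exec_block(self, stmt: A.Block, scope, ctx):
        self.exec_stmts(stmt.stmts, Scope(scope), ctx)

    def _exec_break(self, stmt, scope, ctx):
        raise _Break()

    def _exec_continue(self, stmt, scope, ctx):
        raise _Continue()

    def _exec_return(self, stmt: A.Return, scope, ctx):
        value = self.eval(stmt.value, scope, ctx) if stmt.value is not None else None
        raise _Return(value)

    def _exec_funcdef(self, stmt, scope, ctx):
        pass  # signatures are hoisted; definition execution is a no-op

    def _exec_print(self, stmt: A.Print, scope, ctx):
        text = display(self.eval(stmt.value, scope, ctx)) if stmt.value else ""
        self._emit(text + ("\n" if stmt.newline else ""))

    def _exec_exit(self, stmt: A.ExitStmt, scope, ctx):
        code = self.eval(stmt.code, scope, ctx) if stmt.code is not None else 0
        raise _Exit(code)

    def _exec_sys(self, stmt: A.SysStmt, scope, ctx):
        line = self.interpolate_line(stmt.command.lines[0], scope, ctx)
        self.exec_sys(line, pos=stmt.pos)

    def exec_sys(self, line: str, pos=None) -> str:
        """Run a foreground shell line; nonzero exit aborts the program."""
        proc = subprocess.run(["/bin/sh", "-c", line], cwd=self.work_dir,
                              capture_output=True, text=True)
        if proc.stdout:
            self._emit(proc.stdout)
        if proc.stderr:
            _sys.stderr.write(proc.stderr)
        if proc.returncode != 0:
            raise SysFailure(proc.returncode, line, pos)
        return proc.stdout

    def _exec_wait(self, stmt: A.Wait, scope, ctx):
        ids = None
        if stmt.ids is not None:
            value = self.eval(stmt.ids, scope, ctx)
            ids = value if isinstance(value, list) else [value]
        self.exec_wait(ids, ctx)

    def exec_wait(self, ids, ctx) -> bool:
        """Barrier: block until the named units (or this thread's spawned
        units) are terminal; on any failure, waits for the rest and then
        triggers checkpoint-and-stop via WaitFailure."""
        if ids is None:
            ids = list(ctx.spawned)
        for unit in ids:
            if unit not in self.scheduler.records and unit not in self.par_records \
                    and unit not in self.dep_nodes:
                raise UnknownIdError(f"wait on unknown id {unit!r}")
        par_ids = [u for u in ids if u in self.par_records]
        task_ids = [u for u in ids if u in self.scheduler.records]
        for pid in par_ids:
            thread = self.par_threads.get(pid)
            if thread is not None:
                thread.join()
        self.scheduler.wait_for(task_ids)
        failed = [u for u in task_ids
                  if self.scheduler.records[u].state not in ("DONE", "SKIPPED")]
        failed += [u for u in par_ids
                   if self.par_records[u].get("status") == "failed"]
        if failed:
            raise WaitFailure(failed)
        return True

    def _exec_checkpoint(self, stmt: A.CheckpointStmt, scope, ctx):
        name = self.eval(stmt.name, scope, ctx) if stmt.name is not None else None
        self.exec_checkpoint(name, ctx)

    def exec_checkpoint(self, name, ctx) -> Optional[str]:
        if ctx.id != "main":
            log.warning("checkpoint statement inside a par thread is ignored")
            return None
        path = name
        if path is not None and not os.path.isabs(path):
            path = os.path.join(self.work_dir, path)
        return self._checkpoint(ctx, "explicit-statement", path=path)

    def _exec_exprstmt(self, stmt: A.ExprStmt, scope, ctx):
        self.eval(stmt.expr, scope, ctx)

    _DISPATCH = {
        A.VarDecl: _exec_decl,
        A.Assign: _exec_assign,
        A.IncDec: _exec_incdec,
        A.If: _exec_if,
        A.While: _exec_while,
        A.ForC: _exec_forc,
        A.ForIn: _exec_forin,
        A.Block: _exec_block,
        A.Break: _exec_break,
        A.Continue: _exec_continue,
        A.Return: _exec_return,
        A.FuncDef: _exec_funcdef,
        A.Print: _exec_print,
        A.ExitStmt: _exec_exit,
        A.SysStmt: _exec_sys,
        A.Wait: _exec_wait,
        A.CheckpointStmt: _exec_checkpoint,
        A.ExprStmt: _exec_exprstmt,
    }

    # -------------------------------------------------------- expressions

    def eval(self, node, scope, ctx):
        if isinstance(node, A.Num):
            return node.value
        if isinstance(node, A.Str):
            return node.value
        if isinstance(node, A.BoolLit):
            return node.value
        if isinstance(node, A.Ident):
            return scope.get(node.name)
        if isinstance(node, A.ListLit):
            return [self.eval(item, scope, ctx) for item in node.items]
        if isinstance(node, A.Unary):
            value = self.eval(node.operand, scope, ctx)
            if node.op == "!":
                return not value
            if node.op == "-":
                return -value
            return value
        if isinstance(node, A.Binary):
            if node.op == "&&":
                return self.eval(node.left, scope, ctx) and \
                    self.eval(node.right, scope, ctx)
            if node.op == "||":
                return self.eval(node.left, scope, ctx) or \
                    self.eval(node.right, scope, ctx)
            left = self.eval(node.left, scope, ctx)
            right = self.eval(node.right, scope, ctx)
            return self._binop(node.op, left, right,
                               self.typed.types.get(node.nid), node.pos)
        if isinstance(node, A.DepCheck):
            outs = self.eval(node.outs, scope, ctx)
            ins = self.eval(node.ins, scope, ctx)
            return needs_update(outs, ins, base_dir=self.work_dir,
                                mtime_slack=self.options.mtime_slack)
        if isinstance(node, A.Call):
            return self.eval_call(node, scope, ctx)
        if isinstance(node, A.Index):
            seq = self.eval(node.seq, scope, ctx)
            idx = self.eval(node.idx, scope, ctx)
            if not -len(seq) <= idx < len(seq):
                raise RuntimeFault(f"list index {idx} out of range "
                                   f"(length {len(seq)})", node.pos)
            return seq[idx]
        if isinstance(node, A.TaskExpr):
            return self.exec_task(node, scope, ctx)
        if isinstance(node, A.ParExpr):
            return self.exec_par(node, scope, ctx)
        if isinstance(node, A.GoalExpr):
            return self.exec_goal(node, scope, ctx)
        raise RuntimeFault(f"cannot evaluate {node.kind}", node.pos)

    def _binop(self, op, left, right, result_tag, pos):
        if op in ("==", "!="):
            eq = left == right
            return eq if op == "==" else not eq
        if op in ("<", "<=", ">", ">="):
            import operator
            fn = {"<": operator.lt, "<=": operator.le,
                  ">": operator.gt, ">=": operator.ge}[op]
            return fn(left, right)
        if op == "+":
            if isinstance(left, list):
                if isinstance(right, list):
                    return left + right
                return left + [right]
            if result_tag == T.STRING or isinstance(left, str) or isinstance(right, str):
                if isinstance(left, str) and isinstance(right, str):
                    return left + right
                return (left if isinstance(left, str) else display(left)) + \
                       (right if isinstance(right, str) else display(right))
            return self._numeric(op, left, right, result_tag, pos)
        return self._numeric(op, left, right, result_tag, pos)

    def _numeric(self, op, left, right, result_tag, pos):
        want_int = result_tag == T.INT or (
            result_tag is None and isinstance(left, int) and isinstance(right, int)
            and not isinstance(left, float) and not isinstance(right, float))
        try:
            if op == "+":
                result = left + right
            elif op == "-":
                result = left - right
            elif op == "*":
                result = left * right
            elif op == "/":
                if want_int:
                    # truncating integer division (C-style, toward zero)
                    quotient = abs(left) // abs(right)
                    return -quotient if (left < 0) != (right < 0) else quotient
                return left / right
            elif op == "%":
                quotient = abs(left) // abs(right)
                quotient = -quotient if (left < 0) != (right < 0) else quotient
                return left - quotient * right
            else:
                raise RuntimeFault(f"unknown operator {op!r}", pos)
        except ZeroDivisionError:
            raise RuntimeFault("division by zero", pos) from None
        if result_tag == T.REAL and isinstance(result, int):
            return float(result)
        return result

    def eval_call(self, node: A.Call, scope, ctx):
        args = [self.eval(a, scope, ctx) for a in node.args]
        if node.name == "toInt":
            return self._to_int(args[0], node.pos)
        if node.name == "toStr":
            return display(args[0])
        if node.name == "toReal":
            try:
                return float(args[0])
            except (TypeError, ValueError):
                raise RuntimeFault(f"cannot convert {args[0]!r} to real",
                                   node.pos) from None
        sig = self.typed.functions[node.name]
        return self.call_function(sig, args, ctx)

    @staticmethod
    def _to_int(value, pos=None):
        try:
            if isinstance(value, str):
                return int(value.strip())
            if isinstance(value, bool):
                return int(value)
            return int(value)  # truncates reals toward zero
        except (TypeError, ValueError):
            raise RuntimeFault(f"cannot convert {value!r} to int", pos) from None

    def call_function(self, sig, args, ctx):
        scope = Scope(self.global_scope)
        for (ptag, pname), value in zip(sig.params, args):
            if isinstance(value, list):
                value = list(value)
            scope.declare(pname, ptag, self._coerce(ptag, value))
        ctx.fn_depth += 1
        try:
            self.exec_stmts(sig.node.body.stmts, scope, ctx)
        except _Return as r:
            return r.value
        finally:
            ctx.fn_depth -= 1
        return T.default_value(sig.ret) if sig.ret is not None else None

    # -------------------------------------------------------- interpolation

    def interpolate_line(self, segments, scope, ctx) -> str:
        parts = []
        for seg in segments:
            if seg[0] == "lit":
                parts.append(seg[1])
            elif seg[0] == "var":
                parts.append(interp_value(scope.get(seg[1])))
            else:
                parts.append(interp_value(self.eval(seg[1], scope, ctx)))
        return "".join(parts)

    # -------------------------------------------------------- tasks

    def _next_id(self, kind: str) -> str:
        with self._seq_lock:
            if kind == "task":
                self.task_seq += 1
                return f"task.{self.task_seq}"
            if kind == "dep":
                self.dep_seq += 1
                return f"dep.{self.dep_seq}"
            self.par_seq += 1
            return f"par.{self.par_seq}"

    def _build_spec(self, node: A.TaskExpr, scope, ctx, task_id) -> tuple:
        outs = ins = []
        if node.outs is not None:
            outs = self._path_list(self.eval(node.outs, scope, ctx))
            ins = self._path_list(self.eval(node.ins, scope, ctx))
        opts = {name: self.eval(expr, scope, ctx)
                for name, expr in node.options.items()}
        cpus = int(opts.get("cpus", 1))
        if cpus < 1:
            raise RuntimeFault("cpus must be >= 1", node.pos)
        retry = int(opts.get("retry", self.options.retry))
        if retry < 0:
            raise RuntimeFault("retry must be >= 0", node.pos)
        mem = int(opts.get("mem", 0))
        timeout = float(opts.get("timeout", 0))
        command = [self.interpolate_line(line, scope, ctx)
                   for line in node.body.lines]
        spec = TaskSpec(id=task_id, command=command, name=opts.get("taskName"),
                        ins=ins, outs=outs, cpus=cpus, mem=mem,
                        timeout=timeout, retry=retry)
        return spec, outs, ins

    @staticmethod
    def _path_list(value):
        return [str(v) for v in (value if isinstance(value, list) else [value])]

    def exec_task(self, node: A.TaskExpr, scope, ctx) -> str:
        """Evaluate a task/dep declaration; returns the unit id immediately.

        `dep` registers a deferred node (run only if a goal demands it);
        `task` applies the lazy rule now and either records a SKIPPED task
        or submits a TaskSpec to the scheduler.
        """
        kind = "dep" if node.is_dep else "task"
        unit_id = self._next_id(kind)
        spec, outs, ins = self._build_spec(node, scope, ctx, unit_id)
        dnode = DepNode(node_id=unit_id, kind=kind, spec=spec, outs=outs, ins=ins)
        if node.outs is not None or node.is_dep:
            self.graph.register(dnode)
            self.dep_nodes[unit_id] = dnode
        if node.is_dep:
            self.events.record(unit_id, "-", "DEFERRED")
            return unit_id
        if node.outs is not None and not needs_update(
                outs, ins, base_dir=self.work_dir,
                mtime_slack=self.options.mtime_slack):
            dnode.state = "done"
            self.scheduler.record_skipped(spec, owner=ctx.id)
            ctx.spawned.append(unit_id)
            return unit_id
        if self.options.dry_run:
            self._emit(f"[dry-run] {unit_id}: {'; '.join(spec.command)}\n")
            dnode.state = "done"
            self.scheduler.record_skipped(spec, owner=ctx.id)
            ctx.spawned.append(unit_id)
            return unit_id
        after = self._producers_of(ins)
        dnode.state = "submitted"
        self.scheduler.submit(spec, after=after, owner=ctx.id)
        ctx.spawned.append(unit_id)
        return unit_id

    def _producers_of(self, ins) -> list:
        after = []
        for path in ins:
            producer = self.graph.producer_of(path)
            if producer is not None and producer.node_id in self.scheduler.records:
                after.append(producer.node_id)
        return after

    def exec_goal(self, node: A.GoalExpr, scope, ctx) -> list:
        """Resolve the minimal deferred plan for the targets and submit it
        in topological order, with predecessor constraints."""
        targets = self._path_list(self.eval(node.targets, scope, ctx))
        plan = self.graph.resolve_goal(targets)
        plan = [d for d in plan if d.kind == "dep" and d.state in ("deferred",)]
        if self.options.dry_run:
            for dnode in plan:
                self._emit(f"[dry-run] plan {dnode.node_id}: "
                           f"{'; '.join(dnode.spec.command)}\n")
            return [d.node_id for d in plan]
        planned_ids = {d.node_id for d in plan}
        submitted = []
        for dnode in plan:
            after = [p for p in self.graph.predecessors(dnode.node_id)
                     if p in planned_ids or p in self.scheduler.records]
            dnode.state = "planned"
            self.events.record(dnode.node_id, "DEFERRED", "PLANNED")
            self.scheduler.submit(dnode.spec, after=after, owner=ctx.id)
            dnode.state = "submitted"
            ctx.spawned.append(dnode.node_id)
            submitted.append(dnode.node_id)
        return submitted

    # -------------------------------------------------------- par threads

    def exec_par(self, node: A.ParExpr, scope, ctx) -> str:
        par_id = self._next_id("par")
        snapshot = scope.flatten()
        self._spawn_par(par_id, node, snapshot, ctx)
        return par_id

    def _spawn_par(self, par_id, node, snapshot, parent_ctx):
        record = {"status": "running", "node": node.nid, "scope": snapshot,
                  "error": None}
        self.par_records[par_id] = record
        par_ctx = ThreadCtx(par_id)
        self.par_ctxs[par_id] = par_ctx
        self.events.record(par_id, "-", "RUNNING")

        def body():
            try:
                if node.call is not None:
                    args = [self.eval(a, snapshot, par_ctx)
                            for a in node.call.args]
                    sig = self.typed.functions[node.call.name]
                    self.call_function(sig, args, par_ctx)
                else:
                    self.exec_stmts(node.body.stmts, Scope(snapshot), par_ctx)
                # implicit join of the thread's own spawned units
                task_ids = [u for u in par_ctx.spawned
                            if u in self.scheduler.records]
                ok = self.scheduler.wait_for(task_ids) if task_ids else True
                record["status"] = "done" if ok else "failed"
                if not ok:
                    record["error"] = "task failure inside par thread"
            except WaitFailure as e:
                record["status"] = "failed"
                record["error"] = str(e)
            except (_Exit, RuntimeFault, PipeScriptError) as e:
                record["status"] = "failed"
                record["error"] = str(e)
            self.events.record(par_id, "RUNNING",
                               "DONE" if record["status"] == "done" else "FAILED")

        thread = threading.Thread(target=body, name=par_id, daemon=True)
        self.par_threads[par_id] = thread
        parent_ctx.spawned.append(par_id)
        thread.start()

    # -------------------------------------------------------- checkpoints

    def _checkpoint(self, ctx, reason, path=None) -> Optional[str]:
        from .checkpoint import serialize_state
        pc, reexec, capture_scope = self._capture_pc(ctx, reason)
        if path is None:
            base = os.path.splitext(os.path.basename(self.script_path))[0]
            path = os.path.join(self.run_dir, f"{base}.{reason}.chp")
        try:
            serialize_state(self, ctx, path, reason, pc, reexec, capture_scope)
        except OSError as exc:
            log.warning("could not write checkpoint: %s", exc)
            return None
        self.last_checkpoint = path
        self._emit(f"# checkpoint written: {path}\n")
        return path

    def _capture_pc(self, ctx, reason):
        """Program counter for a checkpoint: the innermost statement on the
        main-thread stack outside any function call.  Explicit checkpoint
        statements resume at their successor; every other reason (and any
        checkpoint buried inside a function call) re-executes the pc
        statement on resume."""
        stack = ctx.fault_stack if ctx.fault_stack is not None else ctx.stmt_stack
        for stmt, scope, fn_depth in reversed(stack):
            if fn_depth == 0:
                top = stack[-1][0] is stmt
                reexec = not (reason == "explicit-statement" and top)
                return stmt.nid, reexec, scope
        return PC_PROGRAM_END, True, self.global_scope

    # -------------------------------------------------------- resume

    def _apply_restore(self, ctx):
        from .checkpoint import restore_into_engine
        restore_into_engine(self, ctx, self.restore)
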