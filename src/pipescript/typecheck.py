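"""Static typechecker with local type inference.

Runs after parsing and before any execution ("pseudo-compilation"): every
expression gets a TypeTag, every identifier must resolve, and all errors
are collected and reported together rather than stopping at the first.

Rules: int op int -> int (truncating division); int/real mix widens to
real; `+` with a string operand concatenates (scalars are rendered);
comparisons yield bool; list literals must unify their element types;
implicit conversion is limited to int -> real, everything else goes
through the `toInt` / `toReal` / `toStr` builtins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import ast_nodes as A
from . import typesys as T
from .errors import TypecheckError

#: predefined duration constants (seconds scale), bound in the global scope
TIME_CONSTANTS = {"second": 1, "minute": 60, "hour": 3600, "day": 86400}

#: cast-like builtins: name -> result tag
BUILTIN_FUNCS = {"toInt": T.INT, "toReal": T.REAL, "toStr": T.STRING}

_INT_OPTIONS = ("cpus", "mem", "timeout", "retry")


@dataclass
class SymbolTable:
    parent: "SymbolTable | None" = None
    symbols: dict = field(default_factory=dict)  # name -> (TypeTag, SourcePos)

    def declare(self, name, tag, pos):
        self.symbols[name] = (tag, pos)

    def lookup(self, name):
        table = self
        while table is not None:
            if name in table.symbols:
                return table.symbols[name]
            table = table.parent
        return None

    def declared_here(self, name):
        return name in self.symbols


@dataclass
class FuncSig:
    name: str
    ret: T.TypeTag | None
    params: list  # (TypeTag, name)
    node: A.FuncDef


@dataclass
class TypedTree:
    """Type-annotated program: the tree plus per-node tags and symbol info."""

    tree: A.SyntaxTree
    types: dict  # nid -> TypeTag
    functions: dict  # name -> FuncSig
    globals_table: dict  # name -> (TypeTag, decl nid, overridable: bool)

    @property
    def root(self):
        return self.tree.root

    def tag(self, node) -> T.TypeTag:
        return self.types[node.nid]


class _Checker:
    def __init__(self, tree: A.SyntaxTree):
        self.tree = tree
        self.types = {}
        self.errors = []  # (message, pos)
        self.functions = {}
        self.globals_table = {}
        self.global_scope = SymbolTable()
        for name in TIME_CONSTANTS:
            self.global_scope.declare(name, T.INT, A.SourcePos("<builtin>", 1, 1))

    def error(self, msg, pos):
        self.errors.append((msg, pos))

    # ------------------------------------------------------------ driver

    def run(self) -> TypedTree:
        # hoist top-level function signatures so forward calls typecheck
        for stmt in self.tree.root.stmts:
            if isinstance(stmt, A.FuncDef):
                if stmt.name in self.functions or stmt.name in BUILTIN_FUNCS:
                    self.error(f"function {stmt.name!r} already defined "
                               "(one signature per name)", stmt.pos)
                else:
                    self.functions[stmt.name] = FuncSig(stmt.name, stmt.ret,
                                                        stmt.params, stmt)
        side_effects_seen = False
        for stmt in self.tree.root.stmts:
            if isinstance(stmt, A.FuncDef):
                self.check_funcdef(stmt)
                continue
            is_decl = isinstance(stmt, A.VarDecl)
            self.check_stmt(stmt, self.global_scope, in_loop=False, fn=None)
            if is_decl and not side_effects_seen:
                tag, _ = self.global_scope.symbols.get(stmt.name, (T.ERROR, None))
                self.globals_table[stmt.name] = (tag, stmt.nid, True)
            elif is_decl:
                tag, _ = self.global_scope.symbols.get(stmt.name, (T.ERROR, None))
                self.globals_table[stmt.name] = (tag, stmt.nid, False)
            if self._has_side_effects(stmt):
                side_effects_seen = True
        if self.errors:
            raise TypecheckError(self.errors)
        return TypedTree(self.tree, self.types, self.functions, self.globals_table)

    @staticmethod
    def _has_side_effects(stmt) -> bool:
        """Conservative: any statement that could launch work or do I/O.

        Used to decide which global declarations remain overridable from the
        command line (only those preceding the first effectful statement)."""
        effectful = (A.SysStmt, A.Wait, A.CheckpointStmt, A.ExitStmt)
        if isinstance(stmt, effectful):
            return True
        found = False

        def walk(node):
            nonlocal found
            if isinstance(node, (A.TaskExpr, A.ParExpr, A.GoalExpr)) or \
                    isinstance(node, effectful):
                found = True
            for child in node.children():
                walk(child)

        walk(stmt)
        return found

    # ------------------------------------------------------------ statements

    def check_funcdef(self, node: A.FuncDef):
        scope = SymbolTable(self.global_scope)
        seen = set()
        for ptag, pname in node.params:
            if pname in seen:
                self.error(f"duplicate parameter {pname!r}", node.pos)
            seen.add(pname)
            scope.declare(pname, ptag, node.pos)
        self.check_block(node.body, scope, in_loop=False, fn=node)

    def check_block(self, block: A.Block, parent, in_loop, fn):
        scope = SymbolTable(parent)
        for stmt in block.stmts:
            self.check_stmt(stmt, scope, in_loop, fn)

    def check_stmt(self, stmt, scope, in_loop, fn):
        if isinstance(stmt, A.VarDecl):
            self.check_decl(stmt, scope)
        elif isinstance(stmt, A.Assign):
            sym = scope.lookup(stmt.name)
            if sym is None:
                self.error(f"assignment to undeclared variable {stmt.name!r}", stmt.pos)
                self.infer(stmt.value, scope)
                return
            target, _ = sym
            vtag = self.infer(stmt.value, scope)
            if stmt.op == "=":
                if not T.assignable(target, vtag):
                    self.error(f"cannot assign {vtag} to {stmt.name!r} of type {target}",
                               stmt.pos)
            else:  # += / -=
                rtag = self.binary_result("+" if stmt.op == "+=" else "-",
                                          target, vtag, stmt.pos,
                                          augmented_target=target)
                if rtag is not None and not T.assignable(target, rtag):
                    self.error(f"{stmt.op} would change {stmt.name!r} from "
                               f"{target} to {rtag}", stmt.pos)
        elif isinstance(stmt, A.IncDec):
            sym = scope.lookup(stmt.name)
            if sym is None:
                self.error(f"{stmt.op} on undeclared variable {stmt.name!r}", stmt.pos)
            elif not sym[0].is_numeric and sym[0] != T.ERROR:
                self.error(f"{stmt.op} requires a numeric variable, "
                           f"{stmt.name!r} is {sym[0]}", stmt.pos)
        elif isinstance(stmt, A.If):
            ctag = self.infer(stmt.cond, scope)
            self.require(ctag, T.BOOL, "if condition", stmt.cond.pos)
            self.check_block(stmt.then, scope, in_loop, fn)
            if isinstance(stmt.els, A.If):
                self.check_stmt(stmt.els, scope, in_loop, fn)
            elif stmt.els is not None:
                self.check_block(stmt.els, scope, in_loop, fn)
        elif isinstance(stmt, A.While):
            ctag = self.infer(stmt.cond, scope)
            self.require(ctag, T.BOOL, "while condition", stmt.cond.pos)
            self.check_block(stmt.body, scope, True, fn)
        elif isinstance(stmt, A.ForC):
            for_scope = SymbolTable(scope)
            if stmt.init is not None:
                self.check_stmt(stmt.init, for_scope, in_loop, fn)
            ctag = self.infer(stmt.cond, for_scope)
            self.require(ctag, T.BOOL, "for condition", stmt.cond.pos)
            if stmt.update is not None:
                self.check_stmt(stmt.update, for_scope, in_loop, fn)
            self.check_block(stmt.body, for_scope, True, fn)
        elif isinstance(stmt, A.ForIn):
            itag = self.infer(stmt.iterable, scope)
            if itag == T.ERROR:
                elem = T.ERROR
            elif not itag.is_list:
                self.error(f"for-in requires a list, got {itag}", stmt.iterable.pos)
                elem = T.ERROR
            else:
                elem = itag.element
            if stmt.var_type is not None and elem != T.ERROR and \
                    not T.assignable(stmt.var_type, elem):
                self.error(f"loop variable type {stmt.var_type} does not match "
                           f"element type {elem}", stmt.pos)
            for_scope = SymbolTable(scope)
            for_scope.declare(stmt.var_name, stmt.var_type or elem, stmt.pos)
            self.check_block(stmt.body, for_scope, True, fn)
        elif isinstance(stmt, (A.Break, A.Continue)):
            if not in_loop:
                self.error(f"{stmt.kind} outside of a loop", stmt.pos)
        elif isinstance(stmt, A.Return):
            if fn is None:
                self.error("return outside of a function", stmt.pos)
                if stmt.value is not None:
                    self.infer(stmt.value, scope)
                return
            if fn.ret is None:
                if stmt.value is not None:
                    self.error(f"void function {fn.name!r} cannot return a value",
                               stmt.pos)
                    self.infer(stmt.value, scope)
            else:
                if stmt.value is None:
                    self.error(f"function {fn.name!r} must return {fn.ret}", stmt.pos)
                else:
                    vtag = self.infer(stmt.value, scope)
                    if not T.assignable(fn.ret, vtag):
                        self.error(f"function {fn.name!r} returns {fn.ret}, "
                                   f"got {vtag}", stmt.pos)
        elif isinstance(stmt, A.FuncDef):
            self.error("functions may only be defined at the top level", stmt.pos)
        elif isinstance(stmt, A.Print):
            if stmt.value is not None:
                self.infer(stmt.value, scope)
        elif isinstance(stmt, A.ExitStmt):
            if stmt.code is not None:
                ctag = self.infer(stmt.code, scope)
                self.require(ctag, T.INT, "exit code", stmt.code.pos)
        elif isinstance(stmt, A.SysStmt):
            self.check_template(stmt.command, scope)
        elif isinstance(stmt, A.Wait):
            if stmt.ids is not None:
                tag = self.infer(stmt.ids, scope)
                if tag not in (T.STRING, T.STRING_LIST, T.ERROR):
                    self.error(f"wait expects a task id (string) or list of ids, "
                               f"got {tag}", stmt.ids.pos)
        elif isinstance(stmt, A.CheckpointStmt):
            if stmt.name is not None:
                tag = self.infer(stmt.name, scope)
                self.require(tag, T.STRING, "checkpoint file name", stmt.name.pos)
        elif isinstance(stmt, A.Block):
            self.check_block(stmt, scope, in_loop, fn)
        elif isinstance(stmt, A.ExprStmt):
            self.infer(stmt.expr, scope)
        else:
            raise TypeError(f"unhandled statement {stmt!r}")

    def check_decl(self, stmt: A.VarDecl, scope):
        if scope.declared_here(stmt.name):
            self.error(f"variable {stmt.name!r} already declared in this scope",
                       stmt.pos)
        if stmt.infer:
            tag = self.infer(stmt.init, scope)
            if tag in (T.VOID,):
                self.error("cannot infer a variable from a void expression", stmt.pos)
                tag = T.ERROR
            scope.declare(stmt.name, tag, stmt.pos)
        else:
            if stmt.init is not None:
                vtag = self.infer(stmt.init, scope)
                if not T.assignable(stmt.declared, vtag):
                    self.error(f"cannot initialize {stmt.declared} {stmt.name!r} "
                               f"with {vtag}", stmt.pos)
            scope.declare(stmt.name, stmt.declared, stmt.pos)

    def check_template(self, tmpl: A.CmdTemplate, scope):
        for name, pos in tmpl.var_segments():
            sym = scope.lookup(name)
            if sym is None:
                self.error(f"interpolated variable {name!r} is not declared", pos)
        for line in tmpl.lines:
            for seg in line:
                if seg[0] == "expr":
                    self.infer(seg[1], scope)

    # ------------------------------------------------------------ expressions

    def require(self, tag, expected, what, pos):
        if tag not in (expected, T.ERROR):
            self.error(f"{what} must be {expected}, got {tag}", pos)

    def infer(self, node, scope) -> T.TypeTag:
        tag = self._infer(node, scope)
        self.types[node.nid] = tag
        return tag

    def _infer(self, node, scope) -> T.TypeTag:
        if isinstance(node, A.Num):
            return T.REAL if node.is_real else T.INT
        if isinstance(node, A.Str):
            return T.STRING
        if isinstance(node, A.BoolLit):
            return T.BOOL
        if isinstance(node, A.Ident):
            sym = scope.lookup(node.name)
            if sym is None:
                self.error(f"undeclared variable {node.name!r}", node.pos)
                return T.ERROR
            return sym[0]
        if isinstance(node, A.ListLit):
            if not node.items:
                self.error("empty list literal has no type; declare the variable "
                           "with an explicit list type instead", node.pos)
                return T.ERROR
            tags = [self.infer(item, scope) for item in node.items]
            unified = tags[0]
            for t in tags[1:]:
                u = self.unify(unified, t)
                if u is None:
                    self.error(f"list elements do not unify: {unified} vs {t}",
                               node.pos)
                    return T.ERROR
                unified = u
            return T.list_of(unified)
        if isinstance(node, A.Unary):
            otag = self.infer(node.operand, scope)
            if node.op == "!":
                self.require(otag, T.BOOL, "operand of '!'", node.pos)
                return T.BOOL
            if otag in (T.INT, T.REAL, T.ERROR):
                return otag
            self.error(f"unary {node.op!r} requires a number, got {otag}", node.pos)
            return T.ERROR
        if isinstance(node, A.Binary):
            ltag = self.infer(node.left, scope)
            rtag = self.infer(node.right, scope)
            result = self.binary_result(node.op, ltag, rtag, node.pos)
            return result if result is not None else T.ERROR
        if isinstance(node, A.DepCheck):
            for side, what in ((node.outs, "left"), (node.ins, "right")):
                tag = self.infer(side, scope)
                if tag not in (T.STRING, T.STRING_LIST, T.ERROR):
                    self.error(f"{what} side of '<-' must be string or string[], "
                               f"got {tag}", side.pos)
            return T.BOOL
        if isinstance(node, A.Call):
            return self.infer_call(node, scope)
        if isinstance(node, A.Index):
            stag = self.infer(node.seq, scope)
            itag = self.infer(node.idx, scope)
            self.require(itag, T.INT, "list index", node.idx.pos)
            if stag == T.ERROR:
                return T.ERROR
            if not stag.is_list:
                self.error(f"cannot index into {stag}", node.pos)
                return T.ERROR
            return stag.element
        if isinstance(node, A.TaskExpr):
            return self.infer_task(node, scope)
        if isinstance(node, A.ParExpr):
            if node.call is not None:
                self.infer_call(node.call, scope, allow_void=True)
            else:
                self.check_block(node.body, scope, in_loop=False, fn=None)
            return T.STRING
        if isinstance(node, A.GoalExpr):
            tag = self.infer(node.targets, scope)
            if tag not in (T.STRING, T.STRING_LIST, T.ERROR):
                self.error(f"goal targets must be string or string[], got {tag}",
                           node.targets.pos)
            return T.STRING_LIST
        raise TypeError(f"unhandled expression {node!r}")

    def infer_task(self, node: A.TaskExpr, scope) -> T.TypeTag:
        if node.outs is not None:
            for side, what in ((node.outs, "outputs"), (node.ins, "inputs")):
                tag = self.infer(side, scope)
                if tag not in (T.STRING, T.STRING_LIST, T.ERROR):
                    self.error(f"task {what} must be string or string[], got {tag}",
                               side.pos)
        for name, expr in node.options.items():
            tag = self.infer(expr, scope)
            if name in _INT_OPTIONS:
                self.require(tag, T.INT, f"task option {name!r}", expr.pos)
            else:  # taskName
                self.require(tag, T.STRING, f"task option {name!r}", expr.pos)
        self.check_template(node.body, scope)
        return T.STRING

    def infer_call(self, node: A.Call, scope, allow_void=False) -> T.TypeTag:
        arg_tags = [self.infer(a, scope) for a in node.args]
        if node.name in BUILTIN_FUNCS:
            if len(node.args) != 1:
                self.error(f"{node.name} takes exactly one argument", node.pos)
            elif not arg_tags[0].is_scalar and arg_tags[0] != T.ERROR:
                self.error(f"{node.name} requires a scalar argument, got {arg_tags[0]}",
                           node.pos)
            return BUILTIN_FUNCS[node.name]
        sig = self.functions.get(node.name)
        if sig is None:
            self.error(f"call to undefined function {node.name!r}", node.pos)
            return T.ERROR
        if len(arg_tags) != len(sig.params):
            self.error(f"function {node.name!r} takes {len(sig.params)} argument(s), "
                       f"got {len(arg_tags)}", node.pos)
        else:
            for (ptag, pname), atag in zip(sig.params, arg_tags):
                if not T.assignable(ptag, atag):
                    self.error(f"argument {pname!r} of {node.name!r} expects {ptag}, "
                               f"got {atag}", node.pos)
        if sig.ret is None:
            if not allow_void:
                return T.VOID
            return T.VOID
        return sig.ret

    # ------------------------------------------------------------ operators

    def unify(self, a, b):
        if a == b:
            return a
        if T.ERROR in (a, b):
            return T.ERROR
        if {a, b} == {T.INT, T.REAL}:
            return T.REAL
        return None

    def binary_result(self, op, ltag, rtag, pos, augmented_target=None):
        """Result tag of a binary operation, or None after reporting."""
        if T.ERROR in (ltag, rtag):
            return T.ERROR
        if op in ("&&", "||"):
            ok = ltag == T.BOOL and rtag == T.BOOL
            if not ok:
                self.error(f"{op} requires bool operands, got {ltag} and {rtag}", pos)
                return None
            return T.BOOL
        if op in ("==", "!=", "<", "<=", ">", ">="):
            if ltag.is_numeric and rtag.is_numeric:
                return T.BOOL
            if ltag == rtag and ltag.is_scalar:
                if ltag == T.BOOL and op not in ("==", "!="):
                    self.error(f"{op} is not defined for bool", pos)
                    return None
                return T.BOOL
            self.error(f"cannot compare {ltag} with {rtag}", pos)
            return None
        if op in ("+", "-", "*", "/", "%"):
            if ltag.is_numeric and rtag.is_numeric:
                if op == "%" and (ltag == T.REAL or rtag == T.REAL):
                    self.error("% requires int operands", pos)
                    return None
                return T.REAL if T.REAL in (ltag, rtag) else T.INT
            if op == "+":
                # string concatenation (either side string, other scalar)
                if ltag == T.STRING and (rtag.is_scalar or rtag == T.STRING):
                    return T.STRING
                if rtag == T.STRING and ltag.is_scalar:
                    return T.STRING
                # list concat / append
                if ltag.is_list:
                    if rtag == ltag:
                        return ltag
                    if T.assignable(ltag.element, rtag):
                        return ltag
                self.error(f"+ is not defined for {ltag} and {rtag}", pos)
                return None
            self.error(f"{op} requires numeric operands, got {ltag} and {rtag}", pos)
            return None
        raise ValueError(f"unknown operator {op!r}")


def check_program(tree: A.SyntaxTree) -> TypedTree:
    """Typecheck a parsed tree; raises TypecheckError listing every error."""
    return _Checker(tree).run()
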