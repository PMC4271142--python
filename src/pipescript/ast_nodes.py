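"""Syntax-tree node definitions.

Every node carries a source position and, after `number_tree`, a unique
integer id assigned in pre-order.  Pre-order numbering makes subtree
containment an interval test (``a.nid <= x <= a.max_nid``), which the
interpreter's recovery-mode traversal and the checkpoint format rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class SourcePos:
    file: str
    line: int  # 1-based
    column: int  # 1-based

    def __str__(self):
        return f"{self.file}:{self.line}:{self.column}"


class Node:
    """Base class; subclasses declare `_child_fields` for generic traversal."""

    _child_fields: tuple = ()
    kind = "node"

    def __init__(self, pos: SourcePos):
        self.pos = pos
        self.nid: int = -1
        self.max_nid: int = -1

    def children(self):
        for name in self._child_fields:
            value = getattr(self, name)
            if value is None:
                continue
            if isinstance(value, list):
                for item in value:
                    if isinstance(item, Node):
                        yield item
            elif isinstance(value, Node):
                yield value

    def contains(self, nid: int) -> bool:
        return self.nid <= nid <= self.max_nid

    def __repr__(self):
        return f"<{type(self).__name__} nid={self.nid} at {self.pos}>"


# ---------------------------------------------------------------- command templates

class CmdTemplate(Node):
    """Verbatim command body with interpolation markers.

    ``lines`` is a list of segment lists; a segment is one of
    ``('lit', text)``, ``('var', name, pos)`` or ``('expr', node)``.
    """

    kind = "cmd_template"

    def __init__(self, pos, lines, raw: str):
        super().__init__(pos)
        self.lines = lines
        self.raw = raw

    def children(self):
        for line in self.lines:
            for seg in line:
                if seg[0] == "expr":
                    yield seg[1]

    def var_segments(self):
        for line in self.lines:
            for seg in line:
                if seg[0] == "var":
                    yield seg[1], seg[2]


# ---------------------------------------------------------------- expressions

class Expr(Node):
    pass


class Num(Expr):
    kind = "num"

    def __init__(self, pos, value, is_real: bool):
        super().__init__(pos)
        self.value = value
        self.is_real = is_real


class Str(Expr):
    kind = "str"

    def __init__(self, pos, value: str):
        super().__init__(pos)
        self.value = value


class BoolLit(Expr):
    kind = "bool"

    def __init__(self, pos, value: bool):
        super().__init__(pos)
        self.value = value


class Ident(Expr):
    kind = "ident"

    def __init__(self, pos, name: str):
        super().__init__(pos)
        self.name = name


class ListLit(Expr):
    kind = "list"
    _child_fields = ("items",)

    def __init__(self, pos, items):
        super().__init__(pos)
        self.items = items


class Unary(Expr):
    kind = "unary"
    _child_fields = ("operand",)

    def __init__(self, pos, op: str, operand):
        super().__init__(pos)
        self.op = op
        self.operand = operand


class Binary(Expr):
    kind = "binary"
    _child_fields = ("left", "right")

    def __init__(self, pos, op: str, left, right):
        super().__init__(pos)
        self.op = op
        self.left = left
        self.right = right


class DepCheck(Expr):
    """The dependency operator `outs <- ins`: true iff outs are out of date."""

    kind = "depcheck"
    _child_fields = ("outs", "ins")

    def __init__(self, pos, outs, ins):
        super().__init__(pos)
        self.outs = outs
        self.ins = ins


class Call(Expr):
    kind = "call"
    _child_fields = ("args",)

    def __init__(self, pos, name: str, args):
        super().__init__(pos)
        self.name = name
        self.args = args


class Index(Expr):
    kind = "index"
    _child_fields = ("seq", "idx")

    def __init__(self, pos, seq, idx):
        super().__init__(pos)
        self.seq = seq
        self.idx = idx


class TaskExpr(Expr):
    """`task` / `dep` — declares a unit of work; evaluates to its id (string).

    ``outs``/``ins`` are the two sides of the optional dependency clause;
    ``options`` maps option names (cpus, mem, timeout, retry, taskName) to
    expression nodes; ``body`` is the raw command template.
    """

    kind = "task"
    _child_fields = ("outs", "ins", "option_exprs", "body")

    OPTION_NAMES = ("cpus", "mem", "timeout", "retry", "taskName")

    def __init__(self, pos, is_dep: bool, outs, ins, options: dict, body: CmdTemplate):
        super().__init__(pos)
        self.is_dep = is_dep
        self.outs = outs
        self.ins = ins
        self.options = options
        self.option_exprs = list(options.values())
        self.body = body


class ParExpr(Expr):
    """`par { block }` or `par f(args)` — evaluates to the par-thread id."""

    kind = "par"
    _child_fields = ("call", "body")

    def __init__(self, pos, call, body):
        super().__init__(pos)
        self.call = call
        self.body = body


class GoalExpr(Expr):
    """`goal targets` — resolves and submits the minimal deferred plan."""

    kind = "goal"
    _child_fields = ("targets",)

    def __init__(self, pos, targets):
        super().__init__(pos)
        self.targets = targets


# ---------------------------------------------------------------- statements

class Stmt(Node):
    pass


class Program(Node):
    kind = "program"
    _child_fields = ("stmts",)

    def __init__(self, pos, stmts):
        super().__init__(pos)
        self.stmts = stmts


class Block(Stmt):
    kind = "block"
    _child_fields = ("stmts",)

    def __init__(self, pos, stmts):
        super().__init__(pos)
        self.stmts = stmts


class VarDecl(Stmt):
    kind = "decl"
    _child_fields = ("init",)

    def __init__(self, pos, name, declared, init, infer: bool):
        super().__init__(pos)
        self.name = name
        self.declared = declared  # TypeTag or None when inferred
        self.init = init
        self.infer = infer


class Assign(Stmt):
    kind = "assign"
    _child_fields = ("value",)

    def __init__(self, pos, name, op, value):
        super().__init__(pos)
        self.name = name
        self.op = op  # '=', '+=', '-='
        self.value = value


class IncDec(Stmt):
    kind = "incdec"

    def __init__(self, pos, name, op):
        super().__init__(pos)
        self.name = name
        self.op = op  # '++' or '--'


class If(Stmt):
    kind = "if"
    _child_fields = ("cond", "then", "els")

    def __init__(self, pos, cond, then, els):
        super().__init__(pos)
        self.cond = cond
        self.then = then
        self.els = els  # Block, If, or None


class While(Stmt):
    kind = "while"
    _child_fields = ("cond", "body")

    def __init__(self, pos, cond, body):
        super().__init__(pos)
        self.cond = cond
        self.body = body


class ForC(Stmt):
    kind = "for"
    _child_fields = ("init", "cond", "update", "body")

    def __init__(self, pos, init, cond, update, body):
        super().__init__(pos)
        self.init = init
        self.cond = cond
        self.update = update
        self.body = body


class ForIn(Stmt):
    kind = "forin"
    _child_fields = ("iterable", "body")

    def __init__(self, pos, var_name, var_type, iterable, body):
        super().__init__(pos)
        self.var_name = var_name
        self.var_type = var_type  # TypeTag or None
        self.iterable = iterable
        self.body = body


class Break(Stmt):
    kind = "break"


class Continue(Stmt):
    kind = "continue"


class Return(Stmt):
    kind = "return"
    _child_fields = ("value",)

    def __init__(self, pos, value):
        super().__init__(pos)
        self.value = value


class FuncDef(Stmt):
    kind = "funcdef"
    _child_fields = ("body",)

    def __init__(self, pos, name, ret, params, body):
        super().__init__(pos)
        self.name = name
        self.ret = ret  # TypeTag or None (void)
        self.params = params  # list of (TypeTag, name)
        self.body = body


class Print(Stmt):
    kind = "print"
    _child_fields = ("value",)

    def __init__(self, pos, value, newline: bool):
        super().__init__(pos)
        self.value = value
        self.newline = newline


class ExitStmt(Stmt):
    kind = "exit"
    _child_fields = ("code",)

    def __init__(self, pos, code):
        super().__init__(pos)
        self.code = code


class SysStmt(Stmt):
    kind = "sys"
    _child_fields = ("command",)

    def __init__(self, pos, command: CmdTemplate):
        super().__init__(pos)
        self.command = command


class Wait(Stmt):
    kind = "wait"
    _child_fields = ("ids",)

    def __init__(self, pos, ids):
        super().__init__(pos)
        self.ids = ids  # Expr or None (join thread-local units)


class CheckpointStmt(Stmt):
    kind = "checkpoint"
    _child_fields = ("name",)

    def __init__(self, pos, name):
        super().__init__(pos)
        self.name = name


class ExprStmt(Stmt):
    kind = "exprstmt"
    _child_fields = ("expr",)

    def __init__(self, pos, expr):
        super().__init__(pos)
        self.expr = expr


# ---------------------------------------------------------------- numbering

def number_tree(root: Node) -> dict:
    """Assign dense pre-order ids; return the nid -> node index."""
    by_id = {}
    counter = 0

    def visit(node):
        nonlocal counter
        node.nid = counter
        by_id[counter] = node
        counter += 1
        for child in node.children():
            visit(child)
        node.max_nid = counter - 1

    visit(root)
    return by_id


@dataclass
class SyntaxTree:
    """Parsed program plus provenance: source texts in include order."""

    root: Program
    sources: dict  # origin -> text
    order: list  # origins in include order
    source_hash: str
    by_id: dict = field(default_factory=dict)

    def node(self, nid: int) -> Node:
        return self.by_id[nid]
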