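"""Recursive-descent parser producing a `SyntaxTree`.

`include "file"` splices the included file's statements in place (the tree
keeps no include node); cycles and missing files are reported with the
position of the offending include.  Node ids are assigned in a final
pre-order pass over the complete post-include tree, so identical source
always yields identical ids — the property checkpoints depend on.
"""

from __future__ import annotations

import hashlib
import os

from . import ast_nodes as A
from . import typesys as T
from .errors import IncludeCycleError, IncludeNotFoundError, ParseError
from .lexer import RESERVED, TYPE_NAMES, Token, tokenize

_STMT_KEYWORDS = {
    "if", "while", "for", "break", "continue", "return", "print", "println",
    "exit", "include", "sys", "task", "dep", "goal", "wait", "par",
    "checkpoint",
}


def default_resolver(include_path=()):
    """Resolve include targets relative to the including file, then along
    an explicit include path list."""

    def resolve(name: str, from_file: str):
        candidates = []
        if from_file and from_file != "<string>":
            candidates.append(os.path.join(os.path.dirname(os.path.abspath(from_file)), name))
        candidates.append(name)
        for d in include_path:
            candidates.append(os.path.join(d, name))
        for cand in candidates:
            if os.path.isfile(cand):
                with open(cand, "r", encoding="utf-8") as fh:
                    return os.path.abspath(cand), fh.read()
        return None

    return resolve


class _Parser:
    def __init__(self, tokens: list[Token], origin: str, resolver, include_stack,
                 sources, order):
        self.toks = tokens
        self.i = 0
        self.origin = origin
        self.resolver = resolver
        self.include_stack = include_stack
        self.sources = sources
        self.order = order

    # ------------------------------------------------------------ helpers

    def peek(self, ahead=0) -> Token:
        j = min(self.i + ahead, len(self.toks) - 1)
        return self.toks[j]

    def next(self) -> Token:
        tok = self.toks[self.i]
        if tok.kind != "EOF":
            self.i += 1
        return tok

    def at(self, kind: str, text=None) -> bool:
        tok = self.peek()
        return tok.kind == kind and (text is None or tok.text == text)

    def expect(self, kind: str, what=None) -> Token:
        tok = self.peek()
        if tok.kind != kind:
            raise ParseError(
                f"expected {what or kind}, found {tok.text!r}", tok.pos)
        return self.next()

    def skip_newlines(self):
        while self.at("NEWLINE"):
            self.next()

    def end_of_stmt(self):
        if self.at(";"):
            self.next()
            return
        if self.at("NEWLINE") or self.at("EOF") or self.at("}"):
            return
        tok = self.peek()
        raise ParseError(f"expected end of statement, found {tok.text!r}", tok.pos)

    # ------------------------------------------------------------ program

    def parse_program(self) -> list[A.Stmt]:
        stmts = []
        self.skip_newlines()
        while not self.at("EOF"):
            stmt = self.parse_statement()
            if isinstance(stmt, list):  # spliced include
                stmts.extend(stmt)
            elif stmt is not None:
                stmts.append(stmt)
            self.skip_newlines()
        return stmts

    # ------------------------------------------------------------ statements

    def parse_statement(self):
        tok = self.peek()
        if tok.kind == "IDENT":
            name = tok.text
            if name in TYPE_NAMES:
                return self.parse_typed_decl_or_func()
            if name == "if":
                return self.parse_if()
            if name == "while":
                return self.parse_while()
            if name == "for":
                return self.parse_for()
            if name == "break":
                self.next()
                stmt = A.Break(tok.pos)
                self.end_of_stmt()
                return stmt
            if name == "continue":
                self.next()
                stmt = A.Continue(tok.pos)
                self.end_of_stmt()
                return stmt
            if name == "return":
                self.next()
                value = None
                if not (self.at("NEWLINE") or self.at("EOF") or self.at("}") or self.at(";")):
                    value = self.parse_expr()
                stmt = A.Return(tok.pos, value)
                self.end_of_stmt()
                return stmt
            if name in ("print", "println"):
                self.next()
                value = None
                if not (self.at("NEWLINE") or self.at("EOF") or self.at("}") or self.at(";")):
                    value = self.parse_expr()
                if value is None and name == "print":
                    raise ParseError("print requires an expression", tok.pos)
                stmt = A.Print(tok.pos, value, newline=(name == "println"))
                self.end_of_stmt()
                return stmt
            if name == "exit":
                self.next()
                code = None
                if not (self.at("NEWLINE") or self.at("EOF") or self.at("}") or self.at(";")):
                    code = self.parse_expr()
                stmt = A.ExitStmt(tok.pos, code)
                self.end_of_stmt()
                return stmt
            if name == "include":
                return self.parse_include()
            if name == "sys":
                self.next()
                raw = self.expect("RAWLINE", "command after sys")
                if not raw.value:
                    raise ParseError("sys requires a command", tok.pos)
                tmpl = parse_cmd_template([raw.value], raw.value, raw.pos, self.origin)
                stmt = A.SysStmt(tok.pos, tmpl)
                self.end_of_stmt()
                return stmt
            if name in ("task", "dep"):
                expr = self.parse_task_expr()
                stmt = A.ExprStmt(tok.pos, expr)
                self.end_of_stmt()
                return stmt
            if name == "goal":
                self.next()
                targets = self.parse_expr()
                stmt = A.ExprStmt(tok.pos, A.GoalExpr(tok.pos, targets))
                self.end_of_stmt()
                return stmt
            if name == "wait":
                self.next()
                ids = None
                if not (self.at("NEWLINE") or self.at("EOF") or self.at("}") or self.at(";")):
                    ids = self.parse_expr()
                stmt = A.Wait(tok.pos, ids)
                self.end_of_stmt()
                return stmt
            if name == "par":
                expr = self.parse_par_expr()
                stmt = A.ExprStmt(tok.pos, expr)
                self.end_of_stmt()
                return stmt
            if name == "checkpoint":
                self.next()
                cname = None
                if not (self.at("NEWLINE") or self.at("EOF") or self.at("}") or self.at(";")):
                    cname = self.parse_expr()
                stmt = A.CheckpointStmt(tok.pos, cname)
                self.end_of_stmt()
                return stmt
            if name in ("else", "true", "false"):
                if name == "else":
                    raise ParseError("'else' without matching 'if'", tok.pos)
                # fall through: boolean literal expression statement
            # identifier-led statement
            nxt = self.peek(1)
            if nxt.kind == "DECLINFER":
                self.next()
                self.next()
                init = self.parse_expr()
                stmt = A.VarDecl(tok.pos, name, None, init, infer=True)
                self.end_of_stmt()
                return stmt
            if nxt.kind in ("=", "+=", "-="):
                self.next()
                op = self.next().text
                value = self.parse_expr()
                stmt = A.Assign(tok.pos, name, op, value)
                self.end_of_stmt()
                return stmt
            if nxt.kind in ("++", "--"):
                self.next()
                op = self.next().text
                stmt = A.IncDec(tok.pos, name, op)
                self.end_of_stmt()
                return stmt
        if tok.kind == "{":
            return self.parse_block()
        # expression statement (e.g. function call)
        expr = self.parse_expr()
        stmt = A.ExprStmt(tok.pos, expr)
        self.end_of_stmt()
        return stmt

    def parse_typed_decl_or_func(self):
        tok = self.peek()
        tag = self.parse_type()
        name_tok = self.expect("IDENT", "name")
        if name_tok.text in RESERVED:
            raise ParseError(f"{name_tok.text!r} is a reserved word", name_tok.pos)
        if self.at("("):
            return self.parse_funcdef(tok.pos, tag, name_tok.text)
        if tag == T.VOID:
            raise ParseError("void is only valid as a function return type", tok.pos)
        init = None
        if self.at("="):
            self.next()
            init = self.parse_expr()
        stmt = A.VarDecl(tok.pos, name_tok.text, tag, init, infer=False)
        self.end_of_stmt()
        return stmt

    def parse_type(self) -> T.TypeTag:
        tok = self.expect("IDENT", "type name")
        if tok.text not in TYPE_NAMES:
            raise ParseError(f"unknown type {tok.text!r}", tok.pos)
        tag = T.TypeTag(tok.text) if tok.text != "void" else T.VOID
        while self.at("[") and self.peek(1).kind == "]":
            if tag == T.VOID:
                raise ParseError("void[] is not a type", tok.pos)
            self.next()
            self.next()
            tag = T.list_of(tag)
        return tag

    def parse_funcdef(self, pos, ret, name):
        self.expect("(")
        params = []
        if not self.at(")"):
            while True:
                ptag = self.parse_type()
                if ptag == T.VOID:
                    raise ParseError("parameters cannot be void", pos)
                pname = self.expect("IDENT", "parameter name")
                if pname.text in RESERVED:
                    raise ParseError(f"{pname.text!r} is a reserved word", pname.pos)
                params.append((ptag, pname.text))
                if self.at(","):
                    self.next()
                    continue
                break
        self.expect(")")
        self.skip_newlines()
        body = self.parse_block()
        ret_tag = None if ret == T.VOID else ret
        return A.FuncDef(pos, name, ret_tag, params, body)

    def parse_block(self) -> A.Block:
        tok = self.expect("{")
        stmts = []
        self.skip_newlines()
        while not self.at("}"):
            if self.at("EOF"):
                raise ParseError("unterminated block", tok.pos)
            stmt = self.parse_statement()
            if isinstance(stmt, list):
                stmts.extend(stmt)
            elif stmt is not None:
                stmts.append(stmt)
            self.skip_newlines()
        self.next()
        return A.Block(tok.pos, stmts)

    def parse_if(self) -> A.If:
        tok = self.next()
        self.expect("(")
        cond = self.parse_expr()
        self.expect(")")
        self.skip_newlines()
        then = self.parse_block()
        els = None
        save = self.i
        self.skip_newlines()
        if self.at("IDENT", "else"):
            self.next()
            self.skip_newlines()
            if self.at("IDENT", "if"):
                els = self.parse_if()
            else:
                els = self.parse_block()
        else:
            self.i = save
        return A.If(tok.pos, cond, then, els)

    def parse_while(self) -> A.While:
        tok = self.next()
        self.expect("(")
        cond = self.parse_expr()
        self.expect(")")
        self.skip_newlines()
        body = self.parse_block()
        return A.While(tok.pos, cond, body)

    def parse_for(self):
        tok = self.next()
        self.expect("(")
        # for-in: `for( x in xs )` or `for( string x in xs )`
        j = self.i
        var_type = None
        if self.peek().kind == "IDENT" and self.peek().text in TYPE_NAMES:
            k = 1
            while self.peek(k).kind == "[" and self.peek(k + 1).kind == "]":
                k += 2
            if self.peek(k).kind == "IDENT" and self.peek(k + 1).kind == "IDENT" \
                    and self.peek(k + 1).text == "in":
                var_type = self.parse_type()
        if self.peek().kind == "IDENT" and self.peek(1).kind == "IDENT" \
                and self.peek(1).text == "in":
            var_tok = self.next()
            if var_tok.text in RESERVED:
                raise ParseError(f"{var_tok.text!r} is a reserved word", var_tok.pos)
            self.next()  # 'in'
            iterable = self.parse_expr()
            self.expect(")")
            self.skip_newlines()
            body = self.parse_block()
            return A.ForIn(tok.pos, var_tok.text, var_type, iterable, body)
        self.i = j
        # C-style
        init = None
        if not self.at(";"):
            init = self.parse_simple_stmt()
        self.expect(";")
        cond = None
        if not self.at(";"):
            cond = self.parse_expr()
        self.expect(";")
        update = None
        if not self.at(")"):
            update = self.parse_simple_stmt()
        self.expect(")")
        self.skip_newlines()
        body = self.parse_block()
        if cond is None:
            cond = A.BoolLit(tok.pos, True)
        return A.ForC(tok.pos, init, cond, update, body)

    def parse_simple_stmt(self):
        """Declaration / assignment / inc-dec, as used in for-headers."""
        tok = self.peek()
        if tok.kind == "IDENT" and tok.text in TYPE_NAMES:
            tag = self.parse_type()
            name_tok = self.expect("IDENT", "name")
            init = None
            if self.at("="):
                self.next()
                init = self.parse_expr()
            return A.VarDecl(tok.pos, name_tok.text, tag, init, infer=False)
        if tok.kind == "IDENT":
            nxt = self.peek(1)
            if nxt.kind == "DECLINFER":
                self.next()
                self.next()
                return A.VarDecl(tok.pos, tok.text, None, self.parse_expr(), infer=True)
            if nxt.kind in ("=", "+=", "-="):
                self.next()
                op = self.next().text
                return A.Assign(tok.pos, tok.text, op, self.parse_expr())
            if nxt.kind in ("++", "--"):
                self.next()
                op = self.next().text
                return A.IncDec(tok.pos, tok.text, op)
        raise ParseError(f"expected declaration or assignment, found {tok.text!r}", tok.pos)

    def parse_include(self):
        tok = self.next()
        name_tok = self.expect("STRING", "include file name")
        self.end_of_stmt()
        name = name_tok.value
        resolved = self.resolver(name, self.origin)
        if resolved is None:
            raise IncludeNotFoundError(f"cannot find include file {name!r}", name_tok.pos)
        origin, text = resolved
        if origin in self.include_stack:
            raise IncludeCycleError(
                f"include cycle: {' -> '.join(self.include_stack + [origin])}",
                name_tok.pos)
        if origin not in self.sources:
            self.sources[origin] = text
            self.order.append(origin)
        sub_tokens = tokenize(text, origin)
        sub = _Parser(sub_tokens, origin, self.resolver,
                      self.include_stack + [origin], self.sources, self.order)
        return sub.parse_program()

    # ------------------------------------------------------------ task / par

    def parse_task_expr(self) -> A.TaskExpr:
        tok = self.next()  # task | dep
        is_dep = tok.text == "dep"
        outs = ins = None
        options = {}
        if self.at("("):
            self.next()
            first = True
            while not self.at(")"):
                if not first:
                    self.expect(",")
                first = False
                if self.peek().kind == "IDENT" and self.peek(1).kind == "DECLINFER":
                    opt_tok = self.next()
                    self.next()
                    if opt_tok.text not in A.TaskExpr.OPTION_NAMES:
                        raise ParseError(
                            f"unknown task option {opt_tok.text!r} "
                            f"(expected one of {', '.join(A.TaskExpr.OPTION_NAMES)})",
                            opt_tok.pos)
                    if opt_tok.text in options:
                        raise ParseError(f"duplicate task option {opt_tok.text!r}", opt_tok.pos)
                    options[opt_tok.text] = self.parse_or()
                else:
                    if outs is not None:
                        raise ParseError("duplicate dependency clause", self.peek().pos)
                    outs = self.parse_or()
                    self.expect("DEPOP", "'<-'")
                    ins = self.parse_or()
            self.expect(")")
        if is_dep and outs is None:
            raise ParseError("dep requires a dependency clause (outs <- ins)", tok.pos)
        body_tok = self.expect("TASKBODY", "task body in braces")
        if not body_tok.value:
            raise ParseError("task body is empty", body_tok.pos)
        tmpl = parse_cmd_template(body_tok.value, body_tok.text, body_tok.pos, self.origin)
        return A.TaskExpr(tok.pos, is_dep, outs, ins, options, tmpl)

    def parse_par_expr(self) -> A.ParExpr:
        tok = self.next()
        if self.at("{"):
            body = self.parse_block()
            return A.ParExpr(tok.pos, None, body)
        name_tok = self.expect("IDENT", "function call or block after par")
        self.expect("(")
        args = []
        if not self.at(")"):
            while True:
                args.append(self.parse_expr())
                if self.at(","):
                    self.next()
                    continue
                break
        self.expect(")")
        return A.ParExpr(tok.pos, A.Call(name_tok.pos, name_tok.text, args), None)

    # ------------------------------------------------------------ expressions

    def parse_expr(self) -> A.Expr:
        left = self.parse_or()
        if self.at("DEPOP"):
            tok = self.next()
            right = self.parse_or()
            return A.DepCheck(tok.pos, left, right)
        return left

    def parse_or(self):
        left = self.parse_and()
        while self.at("||"):
            tok = self.next()
            left = A.Binary(tok.pos, "||", left, self.parse_and())
        return left

    def parse_and(self):
        left = self.parse_cmp()
        while self.at("&&"):
            tok = self.next()
            left = A.Binary(tok.pos, "&&", left, self.parse_cmp())
        return left

    def parse_cmp(self):
        left = self.parse_add()
        while self.peek().kind in ("==", "!=", "<", "<=", ">", ">="):
            tok = self.next()
            left = A.Binary(tok.pos, tok.kind, left, self.parse_add())
        return left

    def parse_add(self):
        left = self.parse_mul()
        while self.peek().kind in ("+", "-"):
            tok = self.next()
            left = A.Binary(tok.pos, tok.kind, left, self.parse_mul())
        return left

    def parse_mul(self):
        left = self.parse_unary()
        while self.peek().kind in ("*", "/", "%"):
            tok = self.next()
            left = A.Binary(tok.pos, tok.kind, left, self.parse_unary())
        return left

    def parse_unary(self):
        tok = self.peek()
        if tok.kind in ("!", "-", "+"):
            self.next()
            return A.Unary(tok.pos, tok.kind, self.parse_unary())
        return self.parse_postfix()

    def parse_postfix(self):
        expr = self.parse_primary()
        while True:
            if self.at("["):
                tok = self.next()
                idx = self.parse_expr()
                self.expect("]")
                expr = A.Index(tok.pos, expr, idx)
            else:
                return expr

    def parse_primary(self):
        tok = self.peek()
        if tok.kind == "INT":
            self.next()
            return A.Num(tok.pos, tok.value, is_real=False)
        if tok.kind == "REAL":
            self.next()
            return A.Num(tok.pos, tok.value, is_real=True)
        if tok.kind == "STRING":
            self.next()
            return A.Str(tok.pos, tok.value)
        if tok.kind == "(":
            self.next()
            expr = self.parse_expr()
            self.expect(")")
            return expr
        if tok.kind == "[":
            self.next()
            items = []
            if not self.at("]"):
                while True:
                    items.append(self.parse_expr())
                    if self.at(","):
                        self.next()
                        continue
                    break
            self.expect("]")
            return A.ListLit(tok.pos, items)
        if tok.kind == "IDENT":
            name = tok.text
            if name in ("true", "false"):
                self.next()
                return A.BoolLit(tok.pos, name == "true")
            if name in ("task", "dep"):
                return self.parse_task_expr()
            if name == "par":
                return self.parse_par_expr()
            if name == "goal":
                self.next()
                return A.GoalExpr(tok.pos, self.parse_expr())
            if name in RESERVED:
                raise ParseError(f"unexpected keyword {name!r} in expression", tok.pos)
            self.next()
            if self.at("("):
                self.next()
                args = []
                if not self.at(")"):
                    while True:
                        args.append(self.parse_expr())
                        if self.at(","):
                            self.next()
                            continue
                        break
                self.expect(")")
                return A.Call(tok.pos, name, args)
            return A.Ident(tok.pos, name)
        raise ParseError(f"unexpected token {tok.text!r}", tok.pos)


# ---------------------------------------------------------------- interpolation

def parse_cmd_template(lines, raw, pos, origin) -> A.CmdTemplate:
    """Split raw command lines into literal / ``$name`` / ``${expr}`` segments.

    ``\\$`` escapes a literal dollar sign.
    """
    out_lines = []
    for line_no, line in enumerate(lines):
        segs = []
        buf = []
        i = 0
        n = len(line)
        seg_pos = A.SourcePos(pos.file, pos.line + line_no, 1)
        while i < n:
            ch = line[i]
            if ch == "\\" and i + 1 < n and line[i + 1] == "$":
                buf.append("$")
                i += 2
                continue
            if ch == "$" and i + 1 < n:
                nxt = line[i + 1]
                if nxt == "{":
                    depth = 1
                    j = i + 2
                    while j < n and depth:
                        if line[j] == "{":
                            depth += 1
                        elif line[j] == "}":
                            depth -= 1
                        j += 1
                    if depth:
                        raise ParseError("unterminated ${...} interpolation", seg_pos)
                    inner = line[i + 2:j - 1]
                    if buf:
                        segs.append(("lit", "".join(buf)))
                        buf = []
                    toks = tokenize(inner, origin)
                    sub = _Parser(toks, origin, lambda n, f: None, [], {}, [])
                    expr = sub.parse_expr()
                    if not (sub.at("NEWLINE") or sub.at("EOF")):
                        raise ParseError("trailing tokens in ${...} interpolation", seg_pos)
                    segs.append(("expr", expr))
                    i = j
                    continue
                if nxt.isalpha() or nxt == "_":
                    j = i + 1
                    while j < n and (line[j].isalnum() or line[j] == "_"):
                        j += 1
                    if buf:
                        segs.append(("lit", "".join(buf)))
                        buf = []
                    segs.append(("var", line[i + 1:j], seg_pos))
                    i = j
                    continue
            buf.append(ch)
            i += 1
        if buf:
            segs.append(("lit", "".join(buf)))
        out_lines.append(segs)
    return A.CmdTemplate(pos, out_lines, raw)


# ---------------------------------------------------------------- entry points

def parse(source: str, origin: str = "<string>", resolver=None,
          include_path=()) -> A.SyntaxTree:
    """Tokenize + parse `source`, resolving includes, into a numbered tree."""
    if resolver is None:
        resolver = default_resolver(include_path)
    sources = {origin: source}
    order = [origin]
    tokens = tokenize(source, origin)
    parser = _Parser(tokens, origin, resolver, [origin], sources, order)
    stmts = parser.parse_program()
    root = A.Program(A.SourcePos(origin, 1, 1), stmts)
    by_id = A.number_tree(root)
    digest = hashlib.sha256()
    for o in order:
        digest.update(sources[o].encode("utf-8"))
    return A.SyntaxTree(root=root, sources=sources, order=order,
                        source_hash=digest.hexdigest(), by_id=by_id)


def parse_file(path: str, include_path=()) -> A.SyntaxTree:
    with open(path, "r", encoding="utf-8") as fh:
        source = fh.read()
    return parse(source, origin=os.path.abspath(path), include_path=include_path)


# ---------------------------------------------------------------- unparser

def unparse(tree: A.SyntaxTree) -> str:
    """Pretty-print the tree back to source; re-parsing the result yields a
    structurally identical tree (includes come out spliced inline)."""
    out = []

    def emit_stmts(stmts, indent):
        for s in stmts:
            emit(s, indent)

    def pad(indent):
        return "    " * indent

    def emit(node, indent):
        p = pad(indent)
        if isinstance(node, A.VarDecl):
            if node.infer:
                out.append(f"{p}{node.name} := {ex(node.init)}\n")
            elif node.init is not None:
                out.append(f"{p}{node.declared} {node.name} = {ex(node.init)}\n")
            else:
                out.append(f"{p}{node.declared} {node.name}\n")
        elif isinstance(node, A.Assign):
            out.append(f"{p}{node.name} {node.op} {ex(node.value)}\n")
        elif isinstance(node, A.IncDec):
            out.append(f"{p}{node.name}{node.op}\n")
        elif isinstance(node, A.If):
            out.append(f"{p}if( {ex(node.cond)} ) {{\n")
            emit_stmts(node.then.stmts, indent + 1)
            if node.els is None:
                out.append(f"{p}}}\n")
            elif isinstance(node.els, A.If):
                out.append(f"{p}}} else ")
                # nested if rendered flat at same indent; emit recursively
                nested = unparse_if_inline(node.els, indent)
                out.append(nested)
            else:
                out.append(f"{p}}} else {{\n")
                emit_stmts(node.els.stmts, indent + 1)
                out.append(f"{p}}}\n")
        elif isinstance(node, A.While):
            out.append(f"{p}while( {ex(node.cond)} ) {{\n")
            emit_stmts(node.body.stmts, indent + 1)
            out.append(f"{p}}}\n")
        elif isinstance(node, A.ForC):
            init = inline_stmt(node.init) if node.init else ""
            update = inline_stmt(node.update) if node.update else ""
            out.append(f"{p}for( {init} ; {ex(node.cond)} ; {update} ) {{\n")
            emit_stmts(node.body.stmts, indent + 1)
            out.append(f"{p}}}\n")
        elif isinstance(node, A.ForIn):
            tname = f"{node.var_type} " if node.var_type else ""
            out.append(f"{p}for( {tname}{node.var_name} in {ex(node.iterable)} ) {{\n")
            emit_stmts(node.body.stmts, indent + 1)
            out.append(f"{p}}}\n")
        elif isinstance(node, A.Break):
            out.append(f"{p}break\n")
        elif isinstance(node, A.Continue):
            out.append(f"{p}continue\n")
        elif isinstance(node, A.Return):
            out.append(f"{p}return {ex(node.value)}\n" if node.value else f"{p}return\n")
        elif isinstance(node, A.FuncDef):
            ret = str(node.ret) if node.ret else "void"
            params = ", ".join(f"{t} {n}" for t, n in node.params)
            out.append(f"{p}{ret} {node.name}({params}) {{\n")
            emit_stmts(node.body.stmts, indent + 1)
            out.append(f"{p}}}\n")
        elif isinstance(node, A.Print):
            kw = "println" if node.newline else "print"
            out.append(f"{p}{kw} {ex(node.value)}\n" if node.value else f"{p}{kw}\n")
        elif isinstance(node, A.ExitStmt):
            out.append(f"{p}exit {ex(node.code)}\n" if node.code else f"{p}exit\n")
        elif isinstance(node, A.SysStmt):
            out.append(f"{p}sys {cmd_line(node.command.lines[0])}\n")
        elif isinstance(node, A.Wait):
            out.append(f"{p}wait {ex(node.ids)}\n" if node.ids else f"{p}wait\n")
        elif isinstance(node, A.CheckpointStmt):
            out.append(f"{p}checkpoint {ex(node.name)}\n" if node.name else f"{p}checkpoint\n")
        elif isinstance(node, A.Block):
            out.append(f"{p}{{\n")
            emit_stmts(node.stmts, indent + 1)
            out.append(f"{p}}}\n")
        elif isinstance(node, A.ExprStmt):
            out.append(f"{p}{ex(node.expr, indent)}\n")
        else:
            raise TypeError(f"cannot unparse {node!r}")

    def unparse_if_inline(node, indent):
        sub = []
        p = pad(indent)
        sub.append(f"if( {ex(node.cond)} ) {{\n")
        saved = out[:]
        del out[:]
        emit_stmts(node.then.stmts, indent + 1)
        body = "".join(out)
        del out[:]
        out.extend(saved)
        sub.append(body)
        if node.els is None:
            sub.append(f"{p}}}\n")
        elif isinstance(node.els, A.If):
            sub.append(f"{p}}} else ")
            sub.append(unparse_if_inline(node.els, indent))
        else:
            saved = out[:]
            del out[:]
            emit_stmts(node.els.stmts, indent + 1)
            ebody = "".join(out)
            del out[:]
            out.extend(saved)
            sub.append(f"{p}}} else {{\n{ebody}{p}}}\n")
        return "".join(sub)

    def inline_stmt(node):
        if isinstance(node, A.VarDecl):
            if node.infer:
                return f"{node.name} := {ex(node.init)}"
            if node.init is not None:
                return f"{node.declared} {node.name} = {ex(node.init)}"
            return f"{node.declared} {node.name}"
        if isinstance(node, A.Assign):
            return f"{node.name} {node.op} {ex(node.value)}"
        if isinstance(node, A.IncDec):
            return f"{node.name}{node.op}"
        raise TypeError(f"cannot inline {node!r}")

    def cmd_line(segs):
        parts = []
        for seg in segs:
            if seg[0] == "lit":
                parts.append(seg[1].replace("$", "\\$"))
            elif seg[0] == "var":
                parts.append(f"${seg[1]}")
            else:
                parts.append("${" + ex(seg[1]) + "}")
        return "".join(parts)

    def string_lit(value):
        body = (value.replace("\\", "\\\\").replace('"', '\\"')
                .replace("\n", "\\n").replace("\t", "\\t"))
        return f'"{body}"'

    def ex(node, indent=0):
        if isinstance(node, A.Num):
            if node.is_real:
                text = repr(float(node.value))
                return text
            return str(node.value)
        if isinstance(node, A.Str):
            return string_lit(node.value)
        if isinstance(node, A.BoolLit):
            return "true" if node.value else "false"
        if isinstance(node, A.Ident):
            return node.name
        if isinstance(node, A.ListLit):
            return "[" + ", ".join(ex(i) for i in node.items) + "]"
        if isinstance(node, A.Unary):
            return f"{node.op}({ex(node.operand)})"
        if isinstance(node, A.Binary):
            return f"({ex(node.left)} {node.op} {ex(node.right)})"
        if isinstance(node, A.DepCheck):
            return f"{ex(node.outs)} <- {ex(node.ins)}"
        if isinstance(node, A.Call):
            return f"{node.name}(" + ", ".join(ex(a) for a in node.args) + ")"
        if isinstance(node, A.Index):
            return f"{ex(node.seq)}[{ex(node.idx)}]"
        if isinstance(node, A.GoalExpr):
            return f"goal {ex(node.targets)}"
        if isinstance(node, A.ParExpr):
            if node.call is not None:
                return f"par {ex(node.call)}"
            saved = out[:]
            del out[:]
            emit_stmts(node.body.stmts, indent + 1)
            body = "".join(out)
            del out[:]
            out.extend(saved)
            return f"par {{\n{body}{pad(indent)}}}"
        if isinstance(node, A.TaskExpr):
            kw = "dep" if node.is_dep else "task"
            header = []
            if node.outs is not None:
                header.append(f"{ex(node.outs)} <- {ex(node.ins)}")
            for name in A.TaskExpr.OPTION_NAMES:
                if name in node.options:
                    header.append(f"{name} := {ex(node.options[name])}")
            head = f"{kw}( {', '.join(header)} )" if header else kw
            p = pad(indent)
            body = "".join(f"{p}    {cmd_line(line)}\n" for line in node.body.lines)
            return f"{head} {{\n{body}{p}}}"
        raise TypeError(f"cannot unparse expression {node!r}")

    emit_stmts(tree.root.stmts, 0)
    return "".join(out)
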