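"""Tokenizer for pipeline scripts.

Mostly a conventional hand-written scanner; two contextual modes make the
shell-flavoured parts of the language possible:

* after the ``sys`` keyword the rest of the line is captured verbatim as a
  single RAWLINE token;
* after a ``task``/``dep`` header, the brace-delimited command body is
  captured verbatim as a TASKBODY token.  A single-line body is the text
  between the first ``{`` and the *last* ``}`` on that line; a multi-line
  body runs until a line containing only ``}``.  The opening ``{`` must be
  on the same line as the end of the header.

Concatenating ``Token.text`` in order, plus skipped whitespace and
comments, reproduces the source exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ast_nodes import SourcePos
from .errors import LexError

# Statement-head keywords are reserved; note `in` and `out` are NOT reserved
# so that scripts can use them as ordinary variable names.
RESERVED = {
    "if", "else", "while", "for", "break", "continue", "return",
    "print", "println", "exit", "include", "sys", "task", "dep",
    "goal", "wait", "par", "checkpoint", "true", "false",
    "int", "real", "bool", "string", "void",
}

TYPE_NAMES = {"int", "real", "bool", "string", "void"}

_OPS2 = ["<-", "<=", ">=", "==", "!=", "&&", "||", "++", "--", "+=", "-=", ":="]
_OPS1 = list("+-*/%<>=!(){}[],;:")

_ESCAPES = {"n": "\n", "t": "\t", "r": "\r", '"': '"', "\\": "\\", "$": "$"}


@dataclass
class Token:
    kind: str  # IDENT, INT, REAL, STRING, NEWLINE, EOF, RAWLINE, TASKBODY,
    #            DEPOP, DECLINFER, or the operator text itself
    text: str  # verbatim lexeme
    pos: SourcePos
    value: object = None  # decoded payload for STRING/INT/REAL/RAWLINE/TASKBODY

    def __repr__(self):
        return f"Token({self.kind!r}, {self.text!r})"


class _Scanner:
    def __init__(self, source: str, origin: str):
        self.src = source
        self.origin = origin
        self.i = 0
        self.line = 1
        self.col = 1

    def pos(self) -> SourcePos:
        return SourcePos(self.origin, self.line, self.col)

    def eof(self) -> bool:
        return self.i >= len(self.src)

    def peek(self, ahead=0) -> str:
        j = self.i + ahead
        return self.src[j] if j < len(self.src) else ""

    def advance(self, n=1) -> str:
        chunk = self.src[self.i:self.i + n]
        for ch in chunk:
            if ch == "\n":
                self.line += 1
                self.col = 1
            else:
                self.col += 1
        self.i += n
        return chunk

    def take_line(self) -> str:
        """Consume up to (not including) the next newline."""
        j = self.src.find("\n", self.i)
        if j == -1:
            j = len(self.src)
        return self.advance(j - self.i)


def tokenize(source: str, origin: str = "<string>") -> list[Token]:
    """Lex `source` into tokens; raises LexError with a position on bad input."""
    sc = _Scanner(source, origin)
    tokens: list[Token] = []
    paren_depth = 0
    task_mode = False  # saw task/dep; waiting for `{` body at depth 0

    def emit(kind, text, pos, value=None):
        tokens.append(Token(kind, text, pos, value))

    while not sc.eof():
        ch = sc.peek()
        pos = sc.pos()

        if ch == "\n":
            sc.advance()
            if paren_depth == 0:
                emit("NEWLINE", "\n", pos)
                task_mode = False
            continue
        if ch in " \t\r":
            sc.advance()
            continue
        if ch == "#":
            sc.take_line()
            continue

        if ch == '"':
            start = sc.i
            sc.advance()
            value = []
            while True:
                if sc.eof() or sc.peek() == "\n":
                    raise LexError("unterminated string literal", pos)
                c = sc.advance()
                if c == '"':
                    break
                if c == "\\":
                    if sc.eof():
                        raise LexError("unterminated string literal", pos)
                    esc = sc.advance()
                    value.append(_ESCAPES.get(esc, esc))
                else:
                    value.append(c)
            emit("STRING", sc.src[start:sc.i], pos, "".join(value))
            continue

        if ch.isdigit():
            start = sc.i
            while sc.peek().isdigit():
                sc.advance()
            is_real = False
            if sc.peek() == "." and sc.peek(1).isdigit():
                is_real = True
                sc.advance()
                while sc.peek().isdigit():
                    sc.advance()
            if sc.peek() in "eE" and (sc.peek(1).isdigit() or
                                      (sc.peek(1) in "+-" and sc.peek(2).isdigit())):
                is_real = True
                sc.advance()
                if sc.peek() in "+-":
                    sc.advance()
                while sc.peek().isdigit():
                    sc.advance()
            text = sc.src[start:sc.i]
            if is_real:
                emit("REAL", text, pos, float(text))
            else:
                emit("INT", text, pos, int(text))
            continue

        if ch.isalpha() or ch == "_":
            start = sc.i
            while sc.peek().isalnum() or sc.peek() == "_":
                sc.advance()
            name = sc.src[start:sc.i]
            emit("IDENT", name, pos, name)
            if name == "sys":
                # capture the remainder of the line verbatim
                raw_pos = sc.pos()
                raw = sc.take_line()
                emit("RAWLINE", raw, raw_pos, raw.strip())
            elif name in ("task", "dep"):
                task_mode = True
            continue

        if ch == "{" and task_mode and paren_depth == 0:
            body_pos = sc.pos()
            start = sc.i
            sc.advance()  # consume '{'
            line_rest_end = sc.src.find("\n", sc.i)
            if line_rest_end == -1:
                line_rest_end = len(sc.src)
            line_rest = sc.src[sc.i:line_rest_end]
            if "}" in line_rest:
                # single-line body: up to the last '}' on this line
                cut = line_rest.rfind("}")
                body = line_rest[:cut].strip()
                sc.advance(cut + 1)
                lines = [body] if body else []
            else:
                sc.advance(line_rest_end - sc.i)  # rest of header line
                lines = []
                closed = False
                while not sc.eof():
                    sc.advance()  # newline
                    line_end = sc.src.find("\n", sc.i)
                    if line_end == -1:
                        line_end = len(sc.src)
                    line = sc.src[sc.i:line_end]
                    if line.strip() == "}":
                        sc.advance(line.index("}") + 1)
                        closed = True
                        break
                    sc.advance(line_end - sc.i)
                    if line.strip():
                        lines.append(line.strip())
                if not closed:
                    raise LexError("unterminated task body", body_pos)
            emit("TASKBODY", sc.src[start:sc.i], body_pos, lines)
            task_mode = False
            continue

        two = sc.src[sc.i:sc.i + 2]
        if two in _OPS2:
            sc.advance(2)
            kind = {"<-": "DEPOP", ":=": "DECLINFER"}.get(two, two)
            emit(kind, two, pos)
            continue
        if ch in _OPS1:
            sc.advance()
            if ch in "([":
                paren_depth += 1
            elif ch in ")]":
                paren_depth = max(0, paren_depth - 1)
            emit(ch, ch, pos)
            continue

        raise LexError(f"unexpected character {ch!r}", pos)

    emit("NEWLINE", "", sc.pos())
    emit("EOF", "", sc.pos())
    return tokens
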