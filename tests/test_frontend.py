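"""Lexer and parser behaviour: token classes, task headers, includes,
node-id determinism, and unparser round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pipescript import LexError, ParseError, parse, tokenize, unparse
from pipescript.errors import IncludeCycleError, IncludeNotFoundError


def kinds(source):
    return [t.kind for t in tokenize(source) if t.kind not in ("NEWLINE", "EOF")]


class TestLexer:
    def test_inferred_declaration_tokens(self):
        toks = [t for t in tokenize('in := "input.file"')
                if t.kind not in ("NEWLINE", "EOF")]
        assert [(t.kind, t.text) for t in toks] == [
            ("IDENT", "in"), ("DECLINFER", ":="), ("STRING", '"input.file"')]

    def test_dependency_operator_has_its_own_token(self):
        assert "DEPOP" in kinds("task ( out <- in )")

    def test_unterminated_string_reports_position(self):
        with pytest.raises(LexError) as err:
            tokenize('"abc')
        assert err.value.pos.line == 1

    def test_task_body_is_captured_verbatim(self):
        toks = tokenize("task( out <- in ) { myProcess $in > $out }")
        body = [t for t in toks if t.kind == "TASKBODY"]
        assert len(body) == 1
        assert body[0].value == ["myProcess $in > $out"]

    def test_multiline_task_body(self):
        toks = tokenize("task {\n  step one\n  step two\n}")
        body = [t for t in toks if t.kind == "TASKBODY"][0]
        assert body.value == ["step one", "step two"]

    def test_sys_captures_rest_of_line_raw(self):
        toks = tokenize("sys echo a > b # not a comment inside sys? it is raw")
        raw = [t for t in toks if t.kind == "RAWLINE"][0]
        assert raw.value.startswith("echo a > b")

    def test_comments_and_numbers(self):
        assert kinds("x := 42 # a comment\ny := 2.5e3") == [
            "IDENT", "DECLINFER", "INT", "IDENT", "DECLINFER", "REAL"]

    @given(st.integers(min_value=0, max_value=10**12))
    @settings(max_examples=50, deadline=None)
    def test_integer_literals_round_trip(self, value):
        tok = [t for t in tokenize(str(value)) if t.kind == "INT"][0]
        assert tok.value == value

    @given(st.text(alphabet=st.characters(blacklist_characters='"\\\n'),
                   max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_string_literals_preserve_content(self, text):
        tok = [t for t in tokenize(f'"{text}"') if t.kind == "STRING"][0]
        assert tok.value == text


SAMPLE = """\
count := 3
real ratio = 1.5
string[] files
for( int i = 0 ; i < count ; i++ ) {
    name := "file_" + i + ".txt"
    files += name
}
int total(int a, int b) {
    return a + b
}
if( total(1, 2) == 3 ) {
    println "sum ok"
} else {
    println "broken"
}
task( "out.txt" <- files, cpus := 2, timeout := 6*hour ) {
    combine $files > out.txt
}
wait
sys echo done
checkpoint "state.chp"
"""


class TestParser:
    def test_two_statement_program(self):
        tree = parse('a := 1\nb := 2\n')
        assert len(tree.root.stmts) == 2

    def test_node_ids_are_deterministic_and_dense(self):
        t1, t2 = parse(SAMPLE), parse(SAMPLE)
        ids1 = sorted(t1.by_id)
        assert ids1 == list(range(len(ids1)))  # dense
        assert ids1 == sorted(t2.by_id)
        for nid in ids1:
            assert t1.node(nid).kind == t2.node(nid).kind

    def test_task_header_fields(self):
        tree = parse(SAMPLE)
        tasks = [s.expr for s in tree.root.stmts
                 if s.kind == "exprstmt" and s.expr.kind == "task"]
        assert len(tasks) == 1
        task = tasks[0]
        assert task.outs is not None and task.ins is not None
        assert set(task.options) == {"cpus", "timeout"}
        assert len(task.body.lines) == 1

    def test_unknown_task_option_rejected(self):
        with pytest.raises(ParseError, match="gpus"):
            parse('task( "o" <- "i", gpus := 1 ) { x }')

    def test_dep_requires_dependency_clause(self):
        with pytest.raises(ParseError):
            parse("dep { echo hi }")

    def test_include_splices_function_definition(self, tmp_path):
        lib = tmp_path / "lib.bds"
        lib.write_text("int twice(int x) {\n    return 2 * x\n}\n")
        main = tmp_path / "main.bds"
        main.write_text('include "lib.bds"\nprintln twice(21)\n')
        tree = parse(main.read_text(), origin=str(main))
        assert any(s.kind == "funcdef" and s.name == "twice"
                   for s in tree.root.stmts)
        assert str(lib) in tree.sources

    def test_include_cycle_detected(self, tmp_path):
        a = tmp_path / "a.bds"
        b = tmp_path / "b.bds"
        a.write_text('include "b.bds"\n')
        b.write_text('include "a.bds"\n')
        with pytest.raises(IncludeCycleError):
            parse(a.read_text(), origin=str(a))

    def test_missing_include_reports_position(self):
        with pytest.raises(IncludeNotFoundError) as err:
            parse('include "nope.bds"')
        assert err.value.pos.line == 1

    def test_parse_error_carries_position(self):
        with pytest.raises(ParseError) as err:
            parse("a := 1\nwhile true {\n}\n")
        assert err.value.pos.line == 2

    def test_interpolation_segments(self):
        tree = parse("x := 1\ntask { echo $x ${x + 1} \\$HOME }\n")
        task = tree.root.stmts[1].expr
        segs = task.body.lines[0]
        assert ("var", ) == tuple(s[0] for s in segs if s[0] == "var")[:1]
        assert any(s[0] == "expr" for s in segs)
        assert any(s[0] == "lit" and "$HOME" in s[1] for s in segs)

    def test_unparse_reparse_fixpoint(self):
        tree = parse(SAMPLE)
        printed = unparse(tree)
        again = unparse(parse(printed))
        assert printed == again

    def test_unparse_preserves_structure(self):
        tree = parse(SAMPLE)
        re_tree = parse(unparse(tree))
        assert len(re_tree.by_id) == len(tree.by_id)
        assert [n.kind for n in tree.by_id.values()] == \
            [n.kind for n in re_tree.by_id.values()]
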