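"""Lazy out-of-date rule and goal resolution.

`needs_update` is checked against a literal four-clause reference
implementation on randomized file fixtures; `resolve_goal` is checked
against a brute-force minimal-subset oracle that enumerates every subset
of nodes, simulates executing it in topological order, and keeps the
smallest subset that leaves the targets up to date.
"""

import itertools
import os
import random

import pytest

from pipescript import (CycleError, DependencyGraph, DepNode,
                        DuplicateProducerError, UnproducibleTargetError,
                        needs_update, stamp)
from pipescript.scheduler import TaskSpec
from pipescript.testkit import make_file_tree


# ---------------------------------------------------------------- stamps

def test_stamp_examples(tmp_path):
    f = tmp_path / "f"
    f.write_bytes(b"0123456789")
    s = stamp(str(f))
    assert s.exists and s.size == 10 and not s.is_dir
    missing = stamp(str(tmp_path / "nope"))
    assert not missing.exists
    d = tmp_path / "emptydir"
    d.mkdir()
    sd = stamp(str(d))
    assert sd.is_dir and sd.dir_empty


# ---------------------------------------------------------------- needs_update

def reference_needs_update(outs, ins):
    """Literal four-clause rule, written independently of the library."""
    out_stamps = [stamp(p) for p in outs]
    for s in out_stamps:
        if not s.exists:
            return True
        if s.is_dir and s.dir_empty:
            return True
        if not s.is_dir and s.size == 0:
            return True
    in_stamps = [stamp(p) for p in ins]
    if not in_stamps:
        return False
    if any(not s.exists for s in in_stamps):
        return True
    return min(s.mtime for s in out_stamps) < max(s.mtime for s in in_stamps)


@pytest.mark.parametrize("scenario,expected", [
    ("out_missing", True),
    ("out_zero_length", True),
    ("out_empty_dir", True),
    ("out_older_than_in", True),
    ("out_fresh", False),
    ("no_inputs_out_present", False),
])
def test_four_clauses(tmp_path, scenario, expected):
    base = str(tmp_path)
    tree = {"in.txt": {"size": 3, "mtime_offset": 100}}
    ins = [os.path.join(base, "in.txt")]
    out = os.path.join(base, "out.txt")
    if scenario == "out_missing":
        pass
    elif scenario == "out_zero_length":
        tree["out.txt"] = {"size": 0, "mtime_offset": 200}
    elif scenario == "out_empty_dir":
        tree["out.txt"] = {"is_dir": True, "mtime_offset": 200}
    elif scenario == "out_older_than_in":
        tree["out.txt"] = {"size": 3, "mtime_offset": 50}
    elif scenario == "out_fresh":
        tree["out.txt"] = {"size": 3, "mtime_offset": 200}
    elif scenario == "no_inputs_out_present":
        tree["out.txt"] = {"size": 3, "mtime_offset": 200}
        ins = []
    make_file_tree(tree, base)
    assert needs_update([out], ins) is expected
    assert reference_needs_update([out], ins) is expected


def test_missing_input_triggers_update_with_warning(tmp_path, caplog):
    out = str(tmp_path / "out.txt")
    make_file_tree({"out.txt": {"size": 3, "mtime_offset": 0}}, str(tmp_path))
    assert needs_update([out], [str(tmp_path / "ghost.txt")]) is True


def test_needs_update_matches_reference_on_random_fixtures(tmp_path):
    rng = random.Random(7)
    for case in range(60):
        base = str(tmp_path / f"case{case}")
        os.makedirs(base)
        tree = {}
        outs, ins = [], []
        for i in range(rng.randint(1, 3)):
            name = f"out{i}"
            outs.append(os.path.join(base, name))
            if rng.random() < 0.8:
                if rng.random() < 0.15:
                    tree[name] = {"is_dir": True, "mtime_offset": rng.randint(0, 300)}
                else:
                    tree[name] = {"size": rng.choice([0, 1, 5]),
                                  "mtime_offset": rng.randint(0, 300)}
        for i in range(rng.randint(0, 3)):
            name = f"in{i}"
            ins.append(os.path.join(base, name))
            if rng.random() < 0.9:
                tree[name] = {"size": 3, "mtime_offset": rng.randint(0, 300)}
        make_file_tree(tree, base)
        assert needs_update(outs, ins) == reference_needs_update(outs, ins), \
            (case, tree)


# ---------------------------------------------------------------- graph basics

def node(node_id, outs, ins):
    spec = TaskSpec(id=node_id, command=["true"], outs=outs, ins=ins)
    return DepNode(node_id=node_id, kind="dep", spec=spec, outs=outs, ins=ins)


def test_fan_in_edges(tmp_path):
    g = DependencyGraph(base_dir=str(tmp_path))
    for i in range(100):
        g.register(node(f"p{i}", [f"out_{i}"], ["src"]))
    g.register(node("main", ["mainOut"], [f"out_{i}" for i in range(100)]))
    assert len(g.predecessors("main")) == 100


def test_duplicate_producer_rejected(tmp_path):
    g = DependencyGraph(base_dir=str(tmp_path))
    g.register(node("a", ["x"], []))
    with pytest.raises(DuplicateProducerError):
        g.register(node("b", ["x"], []))


def test_cycle_rejected(tmp_path):
    g = DependencyGraph(base_dir=str(tmp_path))
    g.register(node("a", ["b.txt"], ["a.txt"]))
    with pytest.raises(CycleError):
        g.register(node("b", ["a.txt"], ["b.txt"]))


# ---------------------------------------------------------------- goal oracle

def simulate(graph_nodes, fs, subset, topo_ids):
    """Execute `subset` in topological order over a simulated filesystem
    (path -> mtime); returns the updated fs or None if some executed node
    lacks an input."""
    fs = dict(fs)
    producers = {}
    for n in graph_nodes:
        for out in n.outs:
            producers[out] = n.node_id
    clock = [max(fs.values(), default=0) + 1]
    for nid in topo_ids:
        if nid not in subset:
            continue
        n = next(x for x in graph_nodes if x.node_id == nid)
        for inp in n.ins:
            if inp not in fs and inp in producers:
                return None  # input neither on disk nor regenerated
        for out in n.outs:
            fs[out] = clock[0]
            clock[0] += 1
    return fs


def sim_effective_time(graph_nodes, fs, path):
    """A present file's mtime; a missing produced file looks through to
    its producer's inputs; a missing source contributes nothing."""
    if path in fs:
        return fs[path]
    producers = {}
    for n in graph_nodes:
        for out in n.outs:
            producers[out] = n
    if path not in producers:
        return float("-inf")
    times = [sim_effective_time(graph_nodes, fs, p)
             for p in producers[path].ins]
    return max(times, default=float("-inf"))


def ancestor_nodes(graph_nodes, targets):
    """Nodes backward-reachable from the targets via produced inputs."""
    producers = {}
    for n in graph_nodes:
        for out in n.outs:
            producers[out] = n
    seen = {}
    stack = [producers[t] for t in targets if t in producers]
    while stack:
        n = stack.pop()
        if n.node_id in seen:
            continue
        seen[n.node_id] = n
        for inp in n.ins:
            if inp in producers:
                stack.append(producers[inp])
    return list(seen.values())


def sim_success(graph_nodes, fs, targets):
    """Targets exist and every *existing* file produced by an ancestor of a
    target is at least as new as the effective time of its producer's
    inputs (deleted intermediates are tolerated)."""
    if not all(t in fs for t in targets):
        return False
    for n in ancestor_nodes(graph_nodes, targets):
        in_time = max((sim_effective_time(graph_nodes, fs, p) for p in n.ins),
                      default=float("-inf"))
        for out in n.outs:
            if out in fs and fs[out] < in_time:
                return False
    return True


def oracle_min_plan(graph_nodes, fs, targets, topo_ids):
    """Smallest subset whose simulated execution satisfies sim_success."""
    ids = [n.node_id for n in graph_nodes
           if n.node_id in {a.node_id for a in
                            ancestor_nodes(graph_nodes, targets)}]
    for r in range(len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            subset = set(combo)
            end_fs = simulate(graph_nodes, fs, subset, topo_ids)
            if end_fs is None:
                continue
            if sim_success(graph_nodes, end_fs, targets):
                return subset
    return set()


def build_chain(tmp_path, present, times):
    """src -> mid -> final chain; `present` lists which files exist."""
    base = str(tmp_path)
    tree = {name: {"size": 3, "mtime_offset": times[name]}
            for name in present}
    make_file_tree(tree, base)
    g = DependencyGraph(base_dir=base)
    g.register(node("mk_mid", ["mid"], ["src"]))
    g.register(node("mk_final", ["final"], ["mid"]))
    return g


def test_deleted_intermediate_with_fresh_final_plans_nothing(tmp_path):
    g = build_chain(tmp_path, ["src", "final"], {"src": 0, "final": 100})
    assert g.resolve_goal(["final"]) == []


def test_deleted_final_regenerates_minimally(tmp_path):
    # mid still on disk: only the final producer runs
    g = build_chain(tmp_path, ["src", "mid"], {"src": 0, "mid": 50})
    plan = [n.node_id for n in g.resolve_goal(["final"])]
    assert plan == ["mk_final"]


def test_deleted_mid_and_final_regenerates_chain_in_order(tmp_path):
    g = build_chain(tmp_path, ["src"], {"src": 0})
    plan = [n.node_id for n in g.resolve_goal(["final"])]
    assert plan == ["mk_mid", "mk_final"]


def test_existing_target_without_producer_is_trivially_satisfied(tmp_path):
    base = str(tmp_path)
    make_file_tree({"free.txt": {"size": 1, "mtime_offset": 0}}, base)
    g = DependencyGraph(base_dir=base)
    assert g.resolve_goal([os.path.join(base, "free.txt")]) == []


def test_unproducible_target_raises(tmp_path):
    g = DependencyGraph(base_dir=str(tmp_path))
    with pytest.raises(UnproducibleTargetError):
        g.resolve_goal(["ghost.txt"])


def test_stale_source_forces_full_downstream_plan(tmp_path):
    g = build_chain(tmp_path, ["src", "mid", "final"],
                    {"src": 300, "mid": 100, "final": 200})
    plan = [n.node_id for n in g.resolve_goal(["final"])]
    assert plan == ["mk_mid", "mk_final"]


def test_idempotence_after_running_plan(tmp_path):
    base = str(tmp_path)
    make_file_tree({"src": {"size": 3, "mtime_offset": 0}}, base)
    g = build_chain(tmp_path, [], {})  # registers nodes; files via line above
    for dnode in g.resolve_goal(["final"]):
        for out in dnode.outs:
            with open(os.path.join(base, out), "w") as fh:
                fh.write("x")
    assert g.resolve_goal(["final"]) == []


def random_dag_case(rng, base):
    """Random linear-ish DAG of <= 6 nodes with random file states."""
    n = rng.randint(2, 6)
    nodes = []
    files = ["f0"]  # f0 is the source
    for i in range(1, n + 1):
        ins = rng.sample(files, k=min(len(files), rng.randint(1, 2)))
        out = f"f{i}"
        nodes.append(node(f"n{i}", [out], ins))
        files.append(out)
    tree = {"f0": {"size": 3, "mtime_offset": rng.randint(0, 50)}}
    for i in range(1, n + 1):
        if rng.random() < 0.7:
            tree[f"f{i}"] = {"size": 3, "mtime_offset": rng.randint(0, 400)}
    make_file_tree(tree, base)
    target = files[-1]
    return nodes, tree, target


def test_goal_plan_matches_bruteforce_oracle_on_random_dags(tmp_path):
    rng = random.Random(11)
    for case in range(40):
        base = str(tmp_path / f"dag{case}")
        os.makedirs(base)
        nodes, tree, target = random_dag_case(rng, base)
        g = DependencyGraph(base_dir=base)
        for n in nodes:
            g.register(n)
        plan = {n.node_id for n in g.resolve_goal([target])}
        fs = {name: stamp(os.path.join(base, name)).mtime
              for name in tree}
        topo = [n.node_id for n in nodes]
        expected = oracle_min_plan(nodes, fs, [target], topo)
        assert plan == expected, (case, tree, plan, expected)
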