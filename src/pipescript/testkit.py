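"""Synthetic pipeline fixtures.

Generates the study workloads every module is exercised against, without
any external data: fan-out/fan-in pipelines shaped like the canonical
two-step example (N per-file tasks, each declaring a CPU requirement and
sleeping for a controlled duration, then a single task consuming all N
outputs), deferred dep/goal chains, flaky commands that fail a controlled
number of times before succeeding (for retry and resume semantics), and
file trees with exact sizes and mtimes (for the lazy out-of-date rule).

Everything is deterministic given the FixtureSpec: identical specs yield
byte-identical scripts and file trees (mtimes are fixed offsets from a
caller-supplied base time).
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field
from typing import Optional, Union


@dataclass(frozen=True)
class FixtureSpec:
    n_tasks: int = 100
    cpus_per_task: int = 2
    task_duration: float = 1.0  # seconds each fan-out task sleeps
    flaky_failures: Union[int, dict, None] = None  # initial failures per task
    retry: Optional[int] = None  # per-task retry option; None = engine default
    seed: int = 0


def _fmt_duration(seconds: float) -> str:
    if float(seconds) == int(seconds):
        return str(int(seconds))
    return f"{seconds:g}"


def _flaky_for(spec: FixtureSpec, index: int) -> int:
    if spec.flaky_failures is None:
        return 0
    if isinstance(spec.flaky_failures, dict):
        return int(spec.flaky_failures.get(index, 0))
    return int(spec.flaky_failures)


def flaky_command(fail_times: int, counter_path: str) -> str:
    """A POSIX shell line that counts its own invocations in
    `counter_path` and exits nonzero for the first `fail_times` calls.

    Shell variables are ``\\$``-escaped so the engine's ``$name``
    interpolation leaves them for the shell.
    """
    c = counter_path
    return (f"n=$(cat {c} 2>/dev/null || echo 0); n=$((n+1)); "
            f"printf '%s\\n' \\$n > {c}; test \\$n -gt {fail_times}")


def gen_fanout_pipeline(spec: FixtureSpec) -> str:
    """Two-step fan-out/fan-in pipeline.

    Step one declares `n_tasks` tasks, each requiring `cpus_per_task`
    CPUs, reading ``in_<i>.txt`` and writing ``out_<i>.txt`` after a
    sleep; a wait barrier separates step two, a single task that combines
    every step-one output into ``main.out``.
    """
    assert spec.n_tasks >= 1
    dur = _fmt_duration(spec.task_duration)
    lines = [
        f"n := {spec.n_tasks}",
        "string[] outs",
        "for( int i = 0 ; i < n ; i++ ) {",
        '    inFile := "in_" + i + ".txt"',
        '    outFile := "out_" + i + ".txt"',
    ]
    flaky_uniform = spec.flaky_failures is not None \
        and not isinstance(spec.flaky_failures, dict)
    retry_opt = f", retry := {spec.retry}" if spec.retry is not None else ""
    if flaky_uniform or spec.flaky_failures is None:
        body = []
        if flaky_uniform and int(spec.flaky_failures) > 0:
            body.append("        " +
                        flaky_command(int(spec.flaky_failures), "cnt_$i.txt"))
        body.append(f"        sleep {dur}")
        body.append("        echo done > $outFile")
        lines.append(f'    task( outFile <- inFile, '
                     f'cpus := {spec.cpus_per_task}, '
                     f'taskName := "fan_" + i{retry_opt} ) {{')
        lines.extend(body)
        lines.append("    }")
    else:
        # per-task flaky counts: emit an if-chain selecting the fail count
        lines.append("    failTimes := 0")
        for idx, times in sorted(spec.flaky_failures.items()):
            lines.append(f"    if( i == {idx} ) {{")
            lines.append(f"        failTimes = {int(times)}")
            lines.append("    }")
        lines.append(f'    task( outFile <- inFile, '
                     f'cpus := {spec.cpus_per_task}, '
                     f'taskName := "fan_" + i{retry_opt} ) {{')
        lines.append("        " +
                     flaky_command(0, "cnt_$i.txt").replace(
                         "test \\$n -gt 0", "test \\$n -gt $failTimes"))
        lines.append(f"        sleep {dur}")
        lines.append("        echo done > $outFile")
        lines.append("    }")
    lines += [
        "    outs += outFile",
        "}",
        "wait",
        'mainOut := "main.out"',
        f'task( mainOut <- outs, cpus := {spec.cpus_per_task}, '
        'taskName := "fanin" ) {',
        "    cat $outs > $mainOut",
        "}",
        "",
    ]
    return "\n".join(lines)


def fanout_inputs(spec: FixtureSpec) -> dict:
    """File-tree description of the fan-out pipeline's input files."""
    return {f"in_{i}.txt": {"size": 8, "mtime_offset": 0}
            for i in range(spec.n_tasks)}


def gen_goal_chain(n_stages: int = 3, final_name: str = "final.txt") -> str:
    """Deferred dep/goal chain: src -> stage_1 -> ... -> final.

    Every stage is a `dep` (not evaluated immediately); the trailing
    `goal` asks only for the final file, so the engine plans the minimal
    set of stages needed to bring it up to date.
    """
    assert n_stages >= 1
    lines = ['src := "src.txt"']
    prev = "src"
    for i in range(1, n_stages + 1):
        var = f"s{i}"
        path = final_name if i == n_stages else f"stage_{i}.txt"
        lines.append(f'{var} := "{path}"')
        lines.append(f"dep( {var} <- {prev} ) {{")
        lines.append(f"    cat ${prev} > ${var}")
        lines.append(f"    echo stage{i} >> ${var}")
        lines.append("}")
        prev = var
    lines.append(f"goal s{n_stages}")
    lines.append("")
    return "\n".join(lines)


def gen_flaky_chain(n_tasks: int, flaky: dict, retry: int = 1,
                    checkpoints: tuple = ()) -> str:
    """Linear chain of tasks, some of which fail a controlled number of
    times before succeeding; optional explicit checkpoint statements after
    the listed stage indices.  Used for retry and resume-equivalence
    fixtures."""
    lines = ['prev := "src.txt"']
    for i in range(1, n_tasks + 1):
        fail = int(flaky.get(i, 0))
        lines.append(f'out{i} := "chain_{i}.txt"')
        lines.append(f"task( out{i} <- prev, retry := {retry}, "
                     f'taskName := "stage{i}" ) {{')
        if fail > 0:
            lines.append("    " + flaky_command(fail, f"cnt_{i}.txt"))
        lines.append(f"    cat $prev > $out{i}")
        lines.append(f"    echo stage{i} >> $out{i}")
        lines.append("}")
        lines.append("wait")
        if i in checkpoints:
            lines.append(f'checkpoint "after_{i}.chp"')
        lines.append(f"prev = out{i}")
    lines.append("")
    return "\n".join(lines)


def gen_flaky_pipeline(n_tasks: int = 1, fail_times: int = 1,
                       retry: int = 2) -> str:
    """Independent flaky tasks; each fails `fail_times` times, then writes
    its output."""
    lines = []
    for i in range(1, n_tasks + 1):
        lines.append(f'out{i} := "flaky_{i}.txt"')
        lines.append(f"task( out{i} <- \"src.txt\", retry := {retry}, "
                     f'taskName := "flaky{i}" ) {{')
        lines.append("    " + flaky_command(fail_times, f"cnt_{i}.txt"))
        lines.append(f"    echo ok > $out{i}")
        lines.append("}")
    lines.append("wait")
    lines.append("")
    return "\n".join(lines)


def make_file_tree(tree: dict, base_dir: str,
                   base_time: Optional[float] = None) -> dict:
    """Materialize files and directories with exact sizes and mtimes.

    `tree` maps relative paths to descriptors with keys ``size`` (bytes,
    files only), ``mtime_offset`` (seconds relative to `base_time`), and
    ``is_dir``.  Zero-size files and empty directories are created as
    such, for exercising the out-of-date clauses.  Returns a map of
    absolute paths.
    """
    if base_time is None:
        base_time = time.time() - 3600
    created = {}
    for rel, desc in sorted(tree.items()):
        path = os.path.join(base_dir, rel)
        if desc.get("is_dir"):
            os.makedirs(path, exist_ok=True)
        else:
            os.makedirs(os.path.dirname(path) or base_dir, exist_ok=True)
            size = int(desc.get("size", 0))
            with open(path, "wb") as fh:
                fh.write(b"x" * size)
        mtime = base_time + float(desc.get("mtime_offset", 0))
        os.utime(path, (mtime, mtime))
        created[rel] = path
    # directory mtimes must be set after their contents
    for rel, desc in sorted(tree.items()):
        if desc.get("is_dir"):
            mtime = base_time + float(desc.get("mtime_offset", 0))
            os.utime(os.path.join(base_dir, rel), (mtime, mtime))
    return created
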