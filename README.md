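# pipescript

A strongly typed scripting language and execution engine for
data-processing pipelines, aimed at the kind of long-running,
multi-tool analyses common in genomics (read mapping, variant calling,
annotation) but useful for any workload that chains external programs
over files.

Shell scripts make pipeline logic easy to write but leave the hard parts
— scheduling against limited CPUs, surviving task failures, not redoing
days of finished work — to the author. `pipescript` moves those concerns
into the language runtime:

* **Architecture abstraction.** Work is declared with `task` statements
  carrying optional resource requirements (`cpus`, `mem`, `timeout`,
  `retry`). The same script runs unchanged on a resource-budgeted local
  executor or a (mock) cluster executor that accepts everything and lets
  the queue decide. A pipeline of one hundred 2-CPU tasks runs 32-wide
  on a 64-core pool, one at a time on a dual-core box, and fails fast
  with a resource error on a single core — without the script changing.
* **Lazy processing.** The dependency operator `outs <- ins` is true iff
  an output *needs* to be rebuilt: it does not exist, has zero length,
  is an empty directory, or is older than an input. Rerunning a finished
  pipeline executes nothing. `dep`/`goal` give the same rule a
  declarative, make-like form over an inferred dependency DAG, and goal
  resolution tolerates deleted intermediate files: if the final targets
  are up to date with respect to the transitive sources, the plan is
  empty.
* **Absolute serialization.** The engine can snapshot its complete state
  — program, variables, scopes, program counter, task table — into a
  checkpoint file. On a failed `wait` barrier this happens
  automatically; `checkpoint` statements do it explicitly. `resume`
  re-executes from exactly where the run stopped: finished tasks are
  never rerun, failed ones are resubmitted.
* **Robust supervision.** Every task runs as its own process group with
  stdout/stderr redirected to per-task log files and its exit status
  written to a file; timeouts and interrupts kill the whole group
  (grandchildren included); failed attempts delete the task's declared
  outputs so a rerun can never consume half-written files; a task is
  only FAILED after `retry + 1` attempts.

## A worked example

`align.bds` — a two-step fan-out/fan-in pipeline:

```text
ref := "reference.txt"
string[] outs

for( int i = 0 ; i < 3 ; i++ ) {
    sample := "sample_" + i + ".txt"
    out := "aligned_" + i + ".txt"
    task( out <- [sample, ref], cpus := 2, taskName := "align_" + i ) {
        cat $sample $ref > $out
    }
    outs += out
}
wait

report := "report.txt"
task( report <- outs ) {
    wc -l $outs > $report
}
```

`:=` declares with inferred types (`ref` is a `string`, `outs` a
`string[]`); the whole script is typechecked before anything runs, so
`cpus := "two"` is rejected up front rather than hours in. Each loop
iteration declares one task; `wait` is a barrier; the final task's
clause `report <- outs` makes it depend on every fan-out output.

```sh
$ pipescript run align.bds --cpus 4 --run-dir . --no-report
$ cat report.txt
 2 aligned_0.txt
 2 aligned_1.txt
 2 aligned_2.txt
 6 total
```

With `--cpus 4` the three 2-CPU alignment tasks run two at a time. Run
it again and nothing executes: every task is reported SKIPPED because
its outputs are newer than its inputs. Touch `sample_1.txt` and only
`align_1` and the report task rerun.

Task stdout is tagged and echoed to the console, and kept per task in
the run directory (`task.1.stdout`, `task.1.stderr`, `task.1.exitCode`):

```sh
$ pipescript run hello.bds --run-dir rd --no-report
starting
all tasks finished
[task.1] hello world
```

Global variables are assignable from the command line without any
argument-parsing code — `pipescript run hello.bds -name pipeline`
replaces `name := "world"` with `"pipeline"`, converting the text to the
variable's declared type.

Other entry points: `pipescript resume run/script.wait-failure.chp`
continues a failed run from its checkpoint; `pipescript inspect
<file.chp>` dumps its variables, program counter and task table;
`pipescript fixtures fanout --n-tasks 100` prints the synthetic
pipelines used by the test suite; `--dry-run` prints a goal's resolved
plan without executing; `--check-only` just parses and typechecks.

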