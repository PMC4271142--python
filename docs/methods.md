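# Methods

This note documents the execution model behind `pipescript`: the
language, the scheduling and supervision machinery, the lazy-processing
and checkpoint semantics, and the design decisions taken where the
behaviour was genuinely open. It also states what the synthetic fixtures
do and do not emulate.

## The language

The language is a small, strongly typed imperative scripting language:
`bool`, `int`, `real`, `string`, and homogeneous lists `T[]`; `if/else`,
`while`, C-style `for` and `for (x in list)`, functions with typed
parameters, `include`, `print`/`println`, `exit`. Pipeline control is
first-class: `task`, `dep`, `goal`, `sys`, `wait`, `par`, `checkpoint`.
There are no maps, objects, or generics beyond lists — pipelines are
overwhelmingly glue code, and a closed type system is what makes
checkpoint serialization total (every value is serializable by
construction).

Typing notes:

* `:=` infers the declared type from the initializer; `int` widens
  implicitly to `real`; everything else converts explicitly via
  `toInt` / `toReal` / `toStr`. `int / int` truncates toward zero and
  `%` follows the same convention (C-like); this is a documented choice,
  not an inevitability.
* `+` concatenates when either operand is a string (rendering the other
  scalar), and appends/concatenates lists.
* `second`, `minute`, `hour`, `day` are predefined `int` constants on
  the seconds scale, so `timeout := 6*hour` reads naturally.
* Typechecking happens entirely before execution ("pseudo-compilation")
  and reports *all* diagnostics with positions, not just the first.
  Variables interpolated into command bodies (`$x`, `${expr}`) are
  checked for declaration at this stage too; `\$` escapes a literal
  dollar for the shell.

Concrete grammar conventions chosen for the command-flavoured parts:
`sys` captures the rest of its line verbatim; a task body is raw text in
braces, either single-line (`{ cmd }`, up to the last `}` on the line)
or multi-line (until a line containing only `}`), with the opening brace
on the header's last line. The dependency operator `<-` is also an
ordinary boolean expression with the lowest precedence, so
`if( out <- in )` works.

The parser assigns every node a dense pre-order integer id after include
splicing. Identical source therefore always yields identical ids, and a
subtree is an interval `[nid, max_nid]` — the two facts checkpoint
program counters rely on.

## Tasks, scheduling, resources

`task` evaluates its resource options and dependency clause, then
returns an id immediately (execution is asynchronous). With a clause
`outs <- ins`, the out-of-date rule is evaluated first; an up-to-date
task is recorded SKIPPED and never spawns a process.

The **out-of-date rule** is timestamp-based, with four clauses: an
output triggers regeneration if it (1) does not exist, (2) has zero
length, (3) is an empty directory, or (4) is older than the newest
input. A directory's effective mtime is the max over its immediate
entries, so directories are first-class dependencies. A missing input
with no producer triggers the task with a warning (the step may
regenerate it); content hashing is deliberately out of scope. An
`mtime_slack` option (default 0) exists for coarse filesystem clocks;
the fixtures set mtimes explicitly so the default is exact.

The **scheduler** drives tasks through
CREATED → SCHEDULED → RUNNING → {DONE, FAILED, TIMEOUT, KILLED}
(plus SKIPPED for lazy no-ops) against a CPU/memory pool. Dispatch is
strict FIFO with head-of-line blocking on *resources* — no backfilling —
which makes peak concurrency deterministic: ⌊pool/c⌋ for uniform c-CPU
tasks. A head whose DAG predecessors are still pending parks at the back
of the queue instead of blocking, since its predecessor may sit behind
it (e.g. after a retry re-enqueue); resource-blocked heads never yield.
Tasks with inferred producer/consumer edges never start before their
producers are DONE.

Two executors implement one submit/poll/kill contract:

* `local` — rejects a submission outright if it can never fit
  (`cpus > pool`), otherwise debits the pool at start and credits at
  termination. The default pool is the machine's CPU count. Memory is
  bookkeeping only (no ulimit/cgroup enforcement): the engine *checks*
  budgets, it does not police processes.
* `mock-cluster` — accepts every submission immediately without
  accounting, emulating a cluster whose own resource manager decides
  placement. Options: `queue_delay` (submission latency) and
  `fail_rate` with a seeded RNG (induced per-attempt failures, for
  unattended-robustness testing). Real cluster/cloud/ssh backends are
  out of scope by design; the executor interface is where they would
  plug in.

**Failure handling.** A task gets up to `retry + 1` attempts and is only
FAILED after the last one. Every failed attempt (including the final
one, and timeouts and kills) deletes the task's declared outputs, so no
downstream step can consume a half-written file. A failed `wait` barrier
lets the remaining joined tasks finish, then checkpoints and stops the
program with exit code 1.

## Process supervision

Each attempt materializes its command lines into `<id>.sh` (with a
`set -e` prologue) and launches it as the leader of a fresh POSIX
session/process group, stdout and stderr redirected to `<id>.stdout` /
`<id>.stderr`. Supervision writes the numeric exit status to
`<id>.exitCode` exactly once; a deadline breach signals the whole group
(TERM, a configurable 5 s grace period, then KILL) and writes the
literal sentinel `timeout` instead of a fake exit code, so downstream
code can distinguish the two. Because signals go to the group, detached
grandchildren die with the task; process-tree scans (via `/proc`) are
used in the tests to verify zero survivors. Interrupts (Ctrl-C) kill
every group, dequeue scheduled work, clean non-DONE outputs, and write
an `interrupt` checkpoint.

Console echoing of task output polls log file *sizes* and opens only
files that grew since the last tick, one at a time — thousands of
concurrent tasks therefore cost O(1) file descriptors, at the price of
up to one poll interval (default 250 ms) of latency.

## dep / goal

`dep` declares a task whose condition is *not* evaluated at declaration;
`goal targets` plans the minimal set of deferred nodes needed to bring
the target files up to date, then submits the plan in topological order
with predecessor constraints. A producer enters the plan iff

1. a demanded output (a target, or an input a planned consumer must
   read) is missing or unusable,
2. one of its *existing* outputs is older than the effective time of its
   inputs, or
3. the producer of one of its inputs is itself planned (a rebuilt input
   invalidates everything downstream).

"Effective time" looks through deleted or empty intermediates to their
producer's inputs, so a deleted intermediate between fresh sources and a
fresh final target yields an empty plan, while touching a source forces
the full downstream chain. The plan is computed statically per `goal`
invocation (timestamps are not re-read between plan steps), and its
minimality is checked in the test suite against a brute-force oracle
that enumerates all subsets of nodes on graphs of ≤ 6 nodes.

## par threads and wait

`par { block }` / `par f(args)` runs on a separate interpreter thread
over a *snapshot* of the enclosing variables; writes inside the thread
do not propagate back. This is a deliberate choice where shared mutation
would have been possible: snapshots avoid data races and make the
checkpoint contents well-defined. `wait` with no ids joins the units
spawned by the current thread; `wait [ids]` joins exactly those (ids are
global, so joining another thread's unit is allowed); an implicit global
wait at the end of the main thread guarantees the program never exits
with live tasks or threads.

## Checkpoints and resume

A checkpoint is a canonical JSON document (sorted keys, fixed encoding —
loading and re-saving is byte-identical) with a format-version gate. It
embeds the full source bundle (main script plus includes) and its hash,
the main thread's program counter (a node id) and scope chain, the task
table with failure reasons, deferred dependency nodes, par-thread
snapshots, and the id counters — everything needed to resume with no
access to the original files, on any machine. It is not compatible with
any external checkpoint format.

Serialization points are statement boundaries; a mid-task crash loses
only that attempt (RUNNING tasks are recorded for re-execution, since OS
processes cannot be serialized). Checkpoints are written automatically
on wait failures, runtime errors, failed `sys` commands (uniform failure
path — a silent glue failure would undermine the robustness goals), and
interrupts; `checkpoint [name]` writes one explicitly and continues.

`resume` re-parses the embedded source (deterministic node ids),
restores the global scope, adopts DONE/SKIPPED task records verbatim,
resubmits everything else with a fresh retry budget, and then traverses
the tree in **recovery mode**: statements are skipped without side
effects, descending only into the subtree containing the recorded
program counter, with block scopes restored from the checkpoint rather
than re-executed. On reaching the program counter the engine switches to
run mode — an explicit checkpoint statement resumes at its successor,
every other reason re-executes the pc statement (a failed wait waits
again, now for the resubmitted tasks). Loop positions survive because
loop variables live in restored scopes; `for-in` additionally carries a
hidden iteration index binding. Passing `--script` at resume time only
*validates* that the on-disk file still hashes to the embedded source —
a checkpoint is not valid against modified code.

Granularity decisions, documented as such: if a checkpoint event occurs
inside a function call, the whole calling top-level statement is
re-executed on resume (the function is re-invoked); a `checkpoint`
statement inside a `par` thread is ignored with a warning; unfinished
par threads re-run their block from the start with their snapshot scope
(their tasks' own lazy clauses and output cleanup make that safe).
Recorded DONE tasks are trusted without re-checking their outputs'
timestamps; re-validation would be a defensible alternative.

## Fixtures: what they emulate, and what they do not

The `testkit` module generates every workload the suite runs: the
two-step fan-out/fan-in pipeline (N per-file tasks with declared CPU
requirements and a controlled sleep, a barrier, one fan-in task),
deferred dep/goal chains, flaky commands that fail a set number of times
before succeeding (the failure count persists in a counter file, which
is also how resume tests verify exactly how often a command really ran),
and file trees with exact sizes and mtimes covering the zero-length and
empty-directory clauses. Generation is deterministic: identical fixture
specifications yield byte-identical scripts and trees.

Default study conditions follow the two-step example the engine is
benchmarked against: 100 fan-out tasks, 2 CPUs each, ~1 s of work,
measured on a 64-CPU local pool and an unconstrained mock cluster. The
serialized-execution check (2-CPU pool) and the lazy/retry/resume
fixtures use shorter sleeps and smaller task counts — they assert
counting properties (peak concurrency, attempt counts, which task ids
ran) that are independent of task duration; the problem sizes used are
stated in each test.

What passing these tests does *not* show: behaviour against real cluster
schedulers (queue semantics here are idealized FIFO), workloads whose
commands are CPU-bound rather than sleeping (fixture tasks cost no
compute), NFS-style coarse or skewed timestamps (fixtures set mtimes
explicitly; `mtime_slack` exists but defaults to 0), and any
content-level notion of "up to date" (the engine is timestamp-only by
design).

## Numerical and degenerate-input choices

* mtime comparison is strict `<` with configurable slack (default 0).
* `cpus` must be ≥ 1; `retry` ≥ 0; `timeout` 0 means none; `mem` 0 means
  unaccounted.
* Empty list literals have no type; declare `string[] xs` instead.
* Division or modulo by zero, and out-of-range indexing, are runtime
  faults that checkpoint and exit 1.
* Duplicate producers of the same output path, and dependency cycles,
  are rejected at declaration.
* Task ids are deterministic (`task.<seq>`, `dep.<seq>`, `par.<seq>`) so
  logs and event-order assertions are reproducible.
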