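"""pipescript — a strongly typed scripting language and execution engine
for data-processing pipelines.

The library surface mirrors the pipeline lifecycle:

* :func:`parse` / :func:`check_program` — frontend and pseudo-compilation
* :class:`Engine` / :func:`run_script` — execution
* :func:`resume` / :func:`inspect_checkpoint` — absolute serialization
* :mod:`pipescript.testkit` — synthetic pipeline fixtures
"""

from .ast_nodes import SourcePos, SyntaxTree
from .checkpoint import inspect as inspect_checkpoint
from .checkpoint import resume
from .config import EngineOptions
from .depgraph import DependencyGraph, DepNode, FileStamp, needs_update, stamp
from .errors import (CycleError, DuplicateProducerError, LexError, ParseError,
                     PipeScriptError, ResourceError, RuntimeFault,
                     StaleSourceError, SysFailure, TypecheckError,
                     UnproducibleTargetError)
from .interpreter import Engine, ExitStatus
from .lexer import Token, tokenize
from .parser import parse, parse_file, unparse
from .scheduler import ResourcePool, Scheduler, TaskRecord, TaskSpec
from .typecheck import TypedTree, check_program

__version__ = "0.1.0"


def run_script(source: str, options: EngineOptions | None = None,
               overrides: dict | None = None, origin: str = "<script>",
               stdout=None):
    """Parse, typecheck and execute a pipeline script given as text.

    Returns ``(ExitStatus, Engine)``; the engine exposes the event log,
    task records and run directory for inspection.
    """
    typed = check_program(parse(source, origin=origin))
    engine = Engine(typed, options=options, overrides=overrides,
                    script_path=origin, stdout=stdout)
    return engine.run(), engine


__all__ = [
    "Engine", "EngineOptions", "ExitStatus", "run_script", "resume",
    "inspect_checkpoint", "parse", "parse_file", "unparse", "tokenize",
    "Token", "SourcePos", "SyntaxTree", "check_program", "TypedTree",
    "needs_update", "stamp", "FileStamp", "DependencyGraph", "DepNode",
    "Scheduler", "TaskSpec", "TaskRecord", "ResourcePool",
    "PipeScriptError", "LexError", "ParseError", "TypecheckError",
    "RuntimeFault", "SysFailure", "ResourceError", "DuplicateProducerError",
    "CycleError", "UnproducibleTargetError", "StaleSourceError",
]
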