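"""Exception hierarchy for the pipeline language and engine."""

from __future__ import annotations


class PipeScriptError(Exception):
    """Base class for all errors raised by this package."""


# ---------------------------------------------------------------- frontend

class LexError(PipeScriptError):
    def __init__(self, message, pos):
        super().__init__(f"{pos}: {message}")
        self.pos = pos
        self.message = message


class ParseError(PipeScriptError):
    def __init__(self, message, pos=None):
        super().__init__(f"{pos}: {message}" if pos else message)
        self.pos = pos
        self.message = message


class IncludeCycleError(ParseError):
    pass


class IncludeNotFoundError(ParseError):
    pass


# ---------------------------------------------------------------- typecheck

class TypecheckError(PipeScriptError):
    """Carries the full list of diagnostics; all errors are reported at once."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        lines = "\n".join(f"{pos}: {msg}" for msg, pos in self.diagnostics)
        super().__init__(f"{len(self.diagnostics)} type error(s):\n{lines}")


# ---------------------------------------------------------------- runtime

class RuntimeFault(PipeScriptError):
    """A runtime error inside a script (index out of range, division by zero...)."""

    def __init__(self, message, pos=None):
        super().__init__(f"{pos}: {message}" if pos else message)
        self.pos = pos
        self.message = message


class SysFailure(RuntimeFault):
    def __init__(self, exit_code, command, pos=None):
        super().__init__(f"sys command failed with exit code {exit_code}: {command}", pos)
        self.exit_code = exit_code
        self.command = command


class UnknownIdError(RuntimeFault):
    pass


# ---------------------------------------------------------------- depgraph

class DuplicateProducerError(PipeScriptError):
    pass


class CycleError(PipeScriptError):
    pass


class UnproducibleTargetError(PipeScriptError):
    pass


# ---------------------------------------------------------------- scheduler / runner

class ResourceError(PipeScriptError):
    """Task requirements exceed the executor's total budget; unrecoverable."""


class SpawnError(PipeScriptError):
    pass


# ---------------------------------------------------------------- checkpoint

class CheckpointError(PipeScriptError):
    pass


class VersionMismatchError(CheckpointError):
    pass


class StaleSourceError(CheckpointError):
    """The checkpoint no longer matches the (overridden) source file."""


class CorruptCheckpointError(CheckpointError):
    pass


# ---------------------------------------------------------------- cli

class UsageError(PipeScriptError):
    pass


class UnknownVariableError(UsageError):
    pass


class ConversionError(UsageError):
    pass
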