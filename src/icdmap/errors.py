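"""Exception hierarchy for icdmap.

Every error raised by the library derives from :class:`IcdMapError`, so
callers can catch one type at a pipeline boundary.  Subclasses are grouped
by the stage that raises them.
"""


class IcdMapError(Exception):
    """Base class for all icdmap errors."""


class FormatError(IcdMapError):
    """A tabular input file violates the documented dialect."""


class ReferentialError(IcdMapError):
    """A parent_id or mapped id refers to a code that does not exist."""


class StructureError(IcdMapError):
    """Parent links do not form a forest (cycle or chapter inconsistency)."""


class CodeLookupError(IcdMapError, KeyError):
    """An unknown code_id or chapter_id was requested."""


class CompositionError(IcdMapError):
    """Two mapping tables cannot be composed (system-id mismatch)."""


class ArgumentError(IcdMapError, ValueError):
    """An operation received an invalid argument."""


class DegenerateVectorError(IcdMapError):
    """A zero-norm vector reached a cosine computation."""


class BackendError(IcdMapError):
    """A generation or encoding backend failed.

    Carries the prompt (when one exists) so failures are reproducible.
    """

    def __init__(self, message: str, prompt: str | None = None):
        super().__init__(message)
        self.prompt = prompt


class GenerationError(IcdMapError):
    """A text-generation backend returned an unusable completion."""


class ChoiceParseError(IcdMapError):
    """A multiple-choice response contained no parsable option label."""


class ConsistencyError(IcdMapError):
    """Resolution outcomes and candidates disagree."""


class EvaluationError(IcdMapError):
    """An evaluation frame is degenerate (e.g. no evaluable sources)."""


class SimulationError(IcdMapError):
    """A synthetic-data configuration is infeasible."""


class ConfigError(IcdMapError):
    """A run configuration is invalid or incomplete."""
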