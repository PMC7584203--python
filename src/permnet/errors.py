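"""Exception hierarchy.

All package errors derive from :class:`PermnetError` so callers (and the CLI)
can distinguish validation problems from assembly non-convergence.
"""


class PermnetError(Exception):
    """Base class for all permnet errors."""


class ValidationError(PermnetError, ValueError):
    """Malformed input: bad degree sequence, file, or configuration."""


class GraphicalityError(ValidationError):
    """A bi-degree sequence cannot realise a network under the requested mode."""


class AssemblyFailure(PermnetError, RuntimeError):
    """Assembly terminated without matching the target out-degree sequence.

    Carries the :class:`~permnet.assembly.AssemblyTrace` of the failed run.
    """

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
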