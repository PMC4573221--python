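"""Exception hierarchy shared across the pipeline.

Every error raised on a user-facing path derives from :class:`KonetError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""

from __future__ import annotations


class KonetError(Exception):
    """Base class for all pipeline errors."""


class ParseError(KonetError):
    """A line of an input file could not be parsed.

    Carries the offending path and 1-based line number so the message can
    point at the exact row.
    """

    def __init__(self, path: str, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{self.path}:{line}: {message}")


class ValidationError(KonetError):
    """Input violated a structural invariant (duplicate ids, bad labels...)."""


class FormatError(KonetError):
    """A structured file (BIOM JSON, GraphML) violated its schema."""


class NumericError(KonetError):
    """A numeric procedure failed (division by empty state, non-convergence)."""
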