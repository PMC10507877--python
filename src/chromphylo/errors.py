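"""Exception hierarchy shared across the package.

The distinction matters for the CLI: configuration problems (a bad column
name, an unknown cell) exit with a usage-style message, parse/input problems
point at the offending data, and capability errors direct the user to a
supported alternative (e.g. heuristic instead of exhaustive search).
"""


class ChromphyloError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChromphyloError, ValueError):
    """A request references something that does not exist or is inconsistent
    (unknown column, unknown cell, invalid class proportions...)."""


class ParseError(ChromphyloError, ValueError):
    """Malformed input data; the message names the offending row/column."""


class InputError(ChromphyloError, ValueError):
    """Structurally valid but unusable input (empty matrix, too few taxa)."""


class ContractError(ChromphyloError, ValueError):
    """An argument violates a documented precondition (length mismatch,
    non-binary state, negative branch length)."""


class CapabilityError(ChromphyloError, NotImplementedError):
    """The exact algorithm cannot handle this instance size/shape; the
    message points at the supported alternative."""
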