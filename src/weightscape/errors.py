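"""Exception hierarchy with CLI exit codes.

Exit-code convention: validation problems (bad inputs, malformed config)
exit 2, numerical/computation failures exit 3, degenerate data exits 4.
"""


class WeightscapeError(Exception):
    """Base class for all toolkit errors."""

    exit_code = 1


class ValidationError(WeightscapeError):
    """Structurally invalid input (matrix shape, reciprocity, ranges...)."""

    exit_code = 2


class ConfigurationError(WeightscapeError):
    """Invalid or incomplete configuration (missing table entries, paths)."""

    exit_code = 2


class ComputationError(WeightscapeError):
    """A numerical procedure failed (non-convergence, out-of-range result)."""

    exit_code = 3


class DegenerateDataError(WeightscapeError):
    """Input data carry no usable information (e.g. all-constant columns)."""

    exit_code = 4
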