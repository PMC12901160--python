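"""Structured error hierarchy shared by every pipeline stage.

All errors carry enough context (row, column, offending value) to point a
user at the exact spot in an input table, and map onto distinct CLI exit
codes: validation problems exit 2, data/format problems exit 3.
"""


class SSCPhenoError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(SSCPhenoError):
    """An input file is structurally wrong (missing columns, bad header)."""

    exit_code = 3


class ValidationError(SSCPhenoError):
    """An input violates a data-model invariant (duplicate id, negative
    intensity, out-of-square centroid)."""

    exit_code = 2


class ConfigurationError(SSCPhenoError):
    """The run configuration is inconsistent with the data (unknown gate
    marker, missing isotype channel, unknown exclusion name)."""

    exit_code = 2


class UsageError(SSCPhenoError):
    """An operation was called in a state it does not support (e.g. raw
    positivity on an already background-subtracted table)."""

    exit_code = 2
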