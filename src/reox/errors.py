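"""Exception hierarchy.

The CLI maps these onto distinct exit codes (schema 2, validation 3,
statistics 4) so shell pipelines can tell malformed files apart from
physiologically impossible sessions or degenerate statistics.
"""


class ReoxError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(ReoxError):
    """A CSV file does not match the documented schema (missing column,
    unknown enum value, unparsable field)."""

    exit_code = 2


class SessionValidationError(ReoxError):
    """A session bundle violates a physical or structural precondition
    (no veins, zero venous flow, missing physiology)."""

    exit_code = 3


class StatisticsError(ReoxError):
    """A statistical estimator is undefined on the given input
    (zero variance, unpaired data, too few subjects)."""

    exit_code = 4
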