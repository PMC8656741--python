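"""Exception hierarchy shared across the package.

Error semantics follow the three-way CLI exit contract: input/parsing
problems (exit 2), statistical precondition failures (exit 3), and
everything else (unexpected, exit 1).
"""


class NephriskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NephriskError, ValueError):
    """A value violates a physical or mathematical precondition."""


class InputFormatError(NephriskError):
    """A file or table could not be parsed / has an incompatible schema."""


class EvidenceError(NephriskError):
    """Evidence names an unknown variable or an out-of-range level."""


class TrainingError(NephriskError):
    """Model fitting precondition failed (e.g. single-class cohort)."""


class NotComputableError(NephriskError):
    """A complete-case score cannot be computed because inputs are missing.

    Distinct from :class:`InvalidInputError`: the record is valid, the
    score simply does not apply to it.
    """


class ConfigError(NephriskError):
    """A configuration document is internally inconsistent or infeasible."""


class PairingError(NephriskError):
    """Paired comparison received score vectors of mismatched length."""
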