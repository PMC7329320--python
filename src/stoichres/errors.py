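"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`StoichresError`
so callers (and the CLI) can distinguish domain errors from bugs.
"""


class StoichresError(Exception):
    """Base class for all stoichres errors."""


class InvalidArgumentError(StoichresError, ValueError):
    """A scalar argument violates a precondition (e.g. n_sites < 2)."""


class InvalidConfigError(StoichresError, ValueError):
    """A configuration document is malformed, non-finite, or has unknown keys."""


class InvalidInputError(StoichresError, ValueError):
    """Input data violate a precondition (negative abundances, bad shapes...)."""


class InsufficientDataError(StoichresError, ValueError):
    """Too few observations for the requested fit."""


class DegenerateInputError(StoichresError, ValueError):
    """Input is degenerate (zero variance, all-zero row/gene...)."""


class UndefinedControlError(StoichresError, ValueError):
    """Resistance is undefined because the control value is not positive."""


class MissingCurveError(StoichresError, KeyError):
    """No standard curve supplied for a gene that needs one."""


class DuplicateKeyError(StoichresError, ValueError):
    """A table contains a duplicated (site, gene, treatment) key."""


class TableParseError(StoichresError, ValueError):
    """A tabular file could not be parsed; carries the offending row."""


class AlignmentError(StoichresError, ValueError):
    """Two tables that must share keys do not; carries the missing keys."""

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class CollinearityError(StoichresError, ValueError):
    """A predictor matrix is rank deficient; names the dependent columns."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class InvalidModelError(StoichresError, ValueError):
    """A path model is structurally invalid (cycle, undeclared variable...)."""
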