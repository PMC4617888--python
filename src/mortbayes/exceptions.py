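"""Exception hierarchy.

Everything raised on bad user input derives from :class:`MortBayesError`
so callers (and the CLI) can catch one base class.
"""


class MortBayesError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MortBayesError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleSpecError(MortBayesError, ValueError):
    """Prior elicitation constraints contradict each other."""


class BracketExhaustedError(MortBayesError, RuntimeError):
    """Root search found no sign change within its bracket."""

    def __init__(self, message: str, bracket: tuple[float, float]):
        super().__init__(f"{message} (search bracket for alpha: "
                         f"[{bracket[0]:.3g}, {bracket[1]:.3g}])")
        self.bracket = bracket


class MethodNotApplicableError(MortBayesError, ValueError):
    """The requested estimator cannot handle this input."""


class UndefinedPrecisionError(MortBayesError, ValueError):
    """Precision adequacy is undefined (zero point estimate)."""


class UnknownRegionError(MortBayesError, KeyError):
    """Region code not found in the baseline table."""


class SchemaError(MortBayesError, ValueError):
    """An input file does not match the declared schema."""
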