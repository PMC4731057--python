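"""Exception hierarchy shared across the package."""


class MaldimixError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MaldimixError, ValueError):
    """A file exists but does not parse in the declared format."""


class SchemaError(MaldimixError, ValueError):
    """A table is missing required columns."""


class ValidationError(MaldimixError, ValueError):
    """Input values violate a documented precondition."""


class ParameterError(MaldimixError, ValueError):
    """An algorithm parameter is outside its valid range."""


class DegenerateInputError(MaldimixError, ValueError):
    """Input is formally valid but degenerate (all-zero spectrum, single row...)."""


class EmptyResultError(MaldimixError, ValueError):
    """An operation produced an empty result where a nonempty one is required."""


class LinkageError(MaldimixError, KeyError):
    """A spectrum cannot be matched to a manifest row (or vice versa)."""


class FoldError(MaldimixError, RuntimeError):
    """A cross-validation fold failed; the message names the left-out row."""


class DivergenceError(MaldimixError, ArithmeticError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"training diverged (non-finite loss) at epoch {epoch} "
            f"with learning_rate={learning_rate}"
        )
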