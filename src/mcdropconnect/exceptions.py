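"""Exception hierarchy used across the package."""


class MCDropConnectError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MCDropConnectError, ValueError):
    """A configuration parameter is outside its admissible range."""


class InvalidInputError(MCDropConnectError, ValueError):
    """A data input violates a precondition (bad probabilities, empty set, ...)."""


class ShapeMismatchError(MCDropConnectError, ValueError):
    """Structurally incompatible array shapes."""


class TrainingDivergenceError(MCDropConnectError, RuntimeError):
    """Training loss became non-finite; carries the loss trace up to failure."""

    def __init__(self, message: str, loss_trace=None):
        super().__init__(message)
        self.loss_trace = list(loss_trace) if loss_trace is not None else []
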