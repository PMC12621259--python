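"""Exception hierarchy shared across the package."""


class FqdropError(Exception):
    """Base class for all package errors."""


class ContractError(FqdropError, ValueError):
    """An argument violates a documented precondition (shape, emptiness, range)."""


class ParameterError(FqdropError, KeyError):
    """A force-field parameter lookup failed; the message names the type_key."""


class GeometryError(FqdropError, ValueError):
    """Coincident or otherwise degenerate coordinates."""


class TopologyError(FqdropError, ValueError):
    """A molecule definition is inconsistent (e.g. a water without oxygen)."""


class ConditioningError(FqdropError, RuntimeError):
    """A linear system is singular or numerically unusable."""

    def __init__(self, message, condition_estimate=None):
        super().__init__(message)
        self.condition_estimate = condition_estimate


class ConvergenceError(FqdropError, RuntimeError):
    """An iterative procedure failed to converge; carries its trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []


class UnitError(FqdropError, ValueError):
    """Unsupported or mismatched axis/physical units."""


class ParseError(FqdropError, ValueError):
    """A file could not be parsed; the message carries the line number."""


class FormatError(FqdropError, ValueError):
    """A file is structurally inconsistent (e.g. varying atom counts)."""


class PackingError(FqdropError, RuntimeError):
    """Random placement could not satisfy the separation constraints."""
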