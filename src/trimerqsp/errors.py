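"""Exception hierarchy for trimerqsp."""


class TrimerQSPError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TrimerQSPError, ValueError):
    """A parameter value violates its physical constraints."""


class SchemaError(TrimerQSPError, ValueError):
    """A dataset or configuration file violates the expected schema."""


class NumericalError(TrimerQSPError, RuntimeError):
    """An ODE integration or root-finding step failed to converge."""


class IntegrityError(TrimerQSPError, RuntimeError):
    """A model invariant (nonnegativity, receptor cap) was violated beyond
    solver tolerance — indicates a solver-accuracy problem, not bad input."""


class EstimationError(TrimerQSPError, RuntimeError):
    """A fit is under-determined or failed to converge."""


class StasisUnreachableError(TrimerQSPError, ValueError):
    """kmax <= kg0: no trimer concentration can hold the tumor static."""
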