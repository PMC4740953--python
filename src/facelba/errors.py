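"""Exception taxonomy shared across the pipeline.

The CLI maps these onto distinct exit codes; library code raises them
directly so callers can tell a bad parameter vector from a malformed
table or a sampler-logic bug.
"""


class FaceLBAError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(FaceLBAError, ValueError):
    """A model parameter is outside its mathematical domain (A <= 0, sigma <= 0, b < A, ...)."""


class DataError(FaceLBAError, ValueError):
    """Input data violate a contract (empty table, negative RT, length mismatch, constant ranks)."""


class ConfigError(FaceLBAError, ValueError):
    """A run configuration is unparseable or infeasible."""


class ConsistencyError(FaceLBAError, ValueError):
    """Two inputs that must agree do not (e.g. subjects present in one table but not another)."""


class SamplerLogicError(FaceLBAError, RuntimeError):
    """Internal misuse of the sampler machinery (identical partner chains, degenerate init)."""


class NumericalError(FaceLBAError, ArithmeticError):
    """A computation produced NaN where a finite or -inf value was required."""
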