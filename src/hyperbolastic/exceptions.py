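"""Exception hierarchy for the hyperbolastic package."""


class HyperbolasticError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HyperbolasticError, ValueError):
    """A model parameter violates its constraint (named in the message)."""


class DomainError(HyperbolasticError, ValueError):
    """Evaluation requested outside the model's time domain."""


class IntegrationError(HyperbolasticError, RuntimeError):
    """The ODE solver failed; the message carries solver diagnostics."""


class InitializationError(HyperbolasticError, ValueError):
    """No usable starting values could be derived from the data."""


class InputError(HyperbolasticError, ValueError):
    """Malformed or inconsistent user input (files, series, configs)."""


class ConvergenceError(HyperbolasticError, RuntimeError):
    """All optimizer starts failed to converge."""
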