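"""Typed exceptions raised across the package."""


class IdcsimError(Exception):
    """Base class for all idcsim errors."""


class InvalidParameterError(IdcsimError, ValueError):
    """A kinetic constant, fraction or range is outside its valid domain."""


class UnknownNutrientError(IdcsimError, KeyError):
    """A nutrient identifier is not one of Leu/Trp/Ura/His (or glucose)."""


class InvalidStateError(IdcsimError, ValueError):
    """A coculture state contains NaN or negative components beyond tolerance."""


class SolverError(IdcsimError, RuntimeError):
    """The ODE integrator failed; carries the last good state when known."""

    def __init__(self, message, final_state=None, day=None):
        super().__init__(message)
        self.final_state = final_state
        self.day = day


class ConfigError(IdcsimError, ValueError):
    """A configuration file violated the schema."""


class DataError(IdcsimError, ValueError):
    """An input table is malformed or insufficient for the requested statistic."""
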