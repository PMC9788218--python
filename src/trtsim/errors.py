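"""Exception types shared across the package."""


class TrtSimError(Exception):
    """Base class for all trtsim errors."""


class InvalidInputError(TrtSimError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateModelError(TrtSimError, ValueError):
    """The parameter set makes the requested closed form undefined
    (e.g. no transfer out of blood, or a divergent dose integral)."""


class InsufficientDataError(TrtSimError, ValueError):
    """Too few usable observations for the requested fit."""


class ConfigError(TrtSimError, ValueError):
    """A configuration file is malformed or violates a parameter invariant."""
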