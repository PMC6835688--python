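"""Exception hierarchy shared across the package."""


class OcusearchError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OcusearchError, ValueError):
    """A value violates a documented precondition (e.g. a zero-sum
    contrast pair, which would describe an invisible item)."""


class ConfigurationError(OcusearchError, ValueError):
    """A configuration object is internally inconsistent or used with
    the wrong operation (e.g. a decrement mapping on an increment display,
    or a target-placement constraint with an empty feasible set)."""


class GenerationError(OcusearchError, RuntimeError):
    """Stimulus generation failed, e.g. a rejection-sampling cap was hit."""
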