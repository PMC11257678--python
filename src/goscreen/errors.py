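"""Exception hierarchy used across the package."""


class GoScreenError(Exception):
    """Base class for all goscreen errors."""


class ValidationError(GoScreenError, ValueError):
    """Input data violates an invariant (duplicate ids, bad alphabet, ...)."""


class ConfigurationError(GoScreenError, ValueError):
    """Options or file formats are inconsistent with the requested operation."""
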