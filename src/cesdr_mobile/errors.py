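"""Exception hierarchy shared across the package."""


class CesdrMobileError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CesdrMobileError):
    """A generative or pipeline configuration field is invalid.

    The message always names the offending field.
    """


class DataIntegrityError(CesdrMobileError):
    """Input session records violate a structural invariant
    (e.g. duplicate (participant, day, item) triples)."""


class MissingItemError(CesdrMobileError):
    """An item id has no responses, or no centering mean is available for it."""
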