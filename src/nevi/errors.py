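"""Exception types shared across the package."""


class NeviError(Exception):
    """Base class for all package-specific errors."""


class RegistryError(NeviError):
    """Malformed registry or unknown domain/subdomain/feature identifier."""


class SchemaError(NeviError):
    """Input table is missing a required column or has the wrong shape."""


class IntegrityError(NeviError):
    """Input table violates a uniqueness or alignment constraint."""


class InsufficientDataError(NeviError):
    """Too few observations for the requested computation."""


class DegenerateInputError(NeviError):
    """An input variable is constant (or otherwise degenerate) where variation is required."""


class ParameterError(NeviError):
    """A numeric parameter is outside its valid range."""
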