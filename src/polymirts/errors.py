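"""Exception hierarchy shared across the package."""


class PolymirtsError(Exception):
    """Base class for all package errors."""


class ValidationError(PolymirtsError, ValueError):
    """Malformed or inconsistent input data."""


class ReferenceMismatchError(ValidationError):
    """A SNP's declared reference allele disagrees with the genome sequence."""


class ConfigurationError(PolymirtsError):
    """Invalid or incomplete parameter/configuration data (e.g. a missing stack entry)."""


class GenerationError(PolymirtsError):
    """The synthetic-data generator could not satisfy its constraints."""
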