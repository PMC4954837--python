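"""Exception types shared across the pipeline."""


class NigraError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(NigraError):
    """Invalid simulation or run configuration."""


class DataError(NigraError):
    """Malformed or inconsistent input data (offending rows are listed)."""


class ContaminationError(DataError):
    """More than two alleles confirmed at one individual x locus."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""
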