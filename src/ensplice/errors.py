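"""Exception hierarchy shared across the package."""


class EnspliceError(Exception):
    """Base class for all package-specific errors."""


class DatasetIntegrityError(EnspliceError):
    """A record violates a dataset-level invariant (e.g. wrong window length)."""


class EmptyInputError(EnspliceError):
    """An input file or collection was empty where content is required."""


class InsufficientDataError(EnspliceError):
    """Not enough records in a class to satisfy a sampling/fold request."""


class EncodingCorruptionError(EnspliceError):
    """A one-hot row is neither a valid indicator vector nor all-zero."""


class ConfigError(EnspliceError):
    """Inconsistent or unresolvable run/simulation configuration."""


class ArchitectureError(EnspliceError):
    """A layer stack is incompatible with the requested input shape."""


class DegenerateDataError(EnspliceError):
    """Training labels contain a single class."""


class InputShapeError(EnspliceError):
    """Array arguments disagree in length or dimension."""
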