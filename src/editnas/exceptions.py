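"""Exception hierarchy for editnas."""


class EditNasError(Exception):
    """Base class for all editnas errors."""


class CoordinateError(EditNasError):
    """A genomic coordinate falls outside the sequence it addresses."""


class EncodingError(EditNasError):
    """A sequence contains characters outside the {A,C,G,T,N} alphabet."""


class CigarError(EditNasError):
    """A CIGAR string is malformed or uses an unsupported operation."""


class UndefinedProfileError(EditNasError):
    """No indel-bearing reads: the six outcome statistics are undefined."""


class InputError(EditNasError):
    """Structurally invalid input (duplicate groups, bad profile, ...)."""


class ArchitectureError(EditNasError):
    """Architecture tokens violate the search-space contract."""


class DimensionError(EditNasError):
    """Array geometry does not match what an operation expects."""


class TrainingError(EditNasError):
    """Optimisation diverged (non-finite loss)."""


class StalenessError(EditNasError):
    """Reward records were sampled under parameters that no longer match."""


class ConfigError(EditNasError):
    """A run configuration is invalid."""


class UndefinedMetricError(EditNasError):
    """A correlation or AUC is undefined (constant input or one class)."""


class ReferenceError_(EditNasError):
    """A chromosome or interval is absent from the reference."""


class RefMismatchError(EditNasError):
    """A variant's REF allele disagrees with the window sequence."""
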