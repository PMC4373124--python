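"""Exception hierarchy shared across the package."""


class HaplotraceError(Exception):
    """Base class for all package-specific errors."""


class InputError(HaplotraceError, ValueError):
    """Malformed or insufficient input data."""


class ConflictError(HaplotraceError):
    """Derived alleles observed on incompatible branches of the tree."""

    def __init__(self, message, markers=()):
        super().__init__(message)
        self.markers = tuple(markers)


class QualityError(HaplotraceError):
    """Alignment identity below the configured floor (wrong region suspected)."""


class ReconstructionError(HaplotraceError, ValueError):
    """Printed frequencies cannot be turned back into integer counts."""


class ConfigurationError(HaplotraceError, ValueError):
    """Inconsistent run configuration (e.g. diagnostic site outside the window)."""
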