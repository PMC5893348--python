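"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class RegiodistError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RegiodistError):
    """Invalid or inconsistent run configuration."""


class DataError(RegiodistError):
    """Malformed or inconsistent input data."""


class ShapeMismatchError(DataError):
    """Paired grids do not have identical dimensions."""


class UnknownLabelError(DataError):
    """Atlas grid contains a label absent from the label table."""


class EmptyRegionError(DataError):
    """A region has no voxels; propagated as a missing feature, not a crash."""


class MassMismatchError(DataError):
    """Histograms compared by EMD must carry equal total mass."""
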