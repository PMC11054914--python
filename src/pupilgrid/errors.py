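"""Exception hierarchy for pupilgrid.

Error families map to distinct CLI exit codes (see :mod:`pupilgrid.cli`).
"""


class PupilgridError(Exception):
    """Base class for all pupilgrid errors."""


class ConfigError(PupilgridError):
    """Invalid configuration (fractions, schedule, window parity, ...)."""


class SizeError(PupilgridError):
    """Invalid image/target geometry (non-positive, crop larger than source)."""


class CountError(PupilgridError):
    """Invalid or empty counts (n <= 0, empty distance list, empty batch)."""


class RangeError(PupilgridError):
    """Index or coordinate out of its legal range."""


class FormatError(PupilgridError):
    """Malformed input data (wrong channel count, bad CSV)."""


class ConsistencyError(PupilgridError):
    """Dataset labels and image files disagree."""


class ShapeError(PupilgridError):
    """Array shape incompatible with a network specification."""


class SpecError(PupilgridError):
    """Malformed network specification."""
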