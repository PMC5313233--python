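"""Exception types shared across the package."""


class PathCVError(Exception):
    """Base class for all package-specific errors."""


class SpecError(PathCVError):
    """A system, CV, restraint or schedule specification is invalid."""


class DimensionalityError(SpecError):
    """Input coordinates do not match the specification's dimensionality."""


class ConvergenceError(PathCVError):
    """An iterative computation diverged or failed to converge."""


class FileFormatError(PathCVError):
    """An input file could not be parsed."""
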