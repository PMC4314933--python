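"""Exception hierarchy shared across the toolbox."""


class AFMetricsError(Exception):
    """Base class for all afmetrics errors."""


class UnsupportedFormatError(AFMetricsError):
    """The file is not in (or not a supported version of) the claimed dialect."""


class CalibrationError(AFMetricsError):
    """Required calibration metadata (scan size, Z scale, tags, pixel size) is missing."""


class GridError(AFMetricsError):
    """Scattered x-y-z points do not form a complete rectangular grid."""


class BoundsError(AFMetricsError):
    """A selection, path or index lies outside the image grid."""


class ParameterError(AFMetricsError):
    """A numeric parameter is outside its documented domain."""


class NoParticleError(AFMetricsError):
    """Detection produced an empty mask where a particle was required."""


class FitError(AFMetricsError):
    """No cross-section Gaussian fit converged."""


class EmptyInputError(AFMetricsError):
    """A batch folder contained no readable image."""
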