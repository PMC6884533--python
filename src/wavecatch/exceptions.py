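"""Exception hierarchy shared across the pipeline stages."""


class WavecatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WavecatchError):
    """A file does not conform to the expected on-disk layout."""


class AxisError(WavecatchError):
    """A coordinate axis violates an invariant (monotonicity, monthly step)."""


class DomainError(WavecatchError):
    """A requested coordinate lies outside the grid domain."""


class DegenerateRegionError(WavecatchError):
    """A spatial reduction has no unmasked cells to average over."""


class AlignmentError(WavecatchError):
    """Two fields expected on identical grids do not match."""


class ValidationError(WavecatchError):
    """Tabular input records violate an invariant."""


class TrackingError(WavecatchError):
    """The anomaly-extremum track could not be followed across lags."""


class ResolutionError(WavecatchError):
    """A vertical profile has too few levels for the requested diagnostic."""


class ConfigError(WavecatchError):
    """A scenario or run configuration is inconsistent."""
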