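"""Typed errors raised across the pipeline.

Degenerate inputs raise rather than returning 0/NaN so that a poisoned
sub-band is visible in logs and the offending record can be dropped with
a recorded reason instead of silently contaminating the feature matrix.
"""


class EcgSubbandError(Exception):
    """Base class for all package errors."""


class MissingFileError(EcgSubbandError, FileNotFoundError):
    """Input file does not exist."""


class ParseError(EcgSubbandError, ValueError):
    """Input file exists but does not parse in the declared dialect."""


class EmptySignalError(EcgSubbandError, ValueError):
    """A parsed record contains no samples."""


class DegenerateSignalError(EcgSubbandError, ValueError):
    """Zero-variance (constant) signal: normalization and mobility are undefined."""


class DegenerateSlopeError(EcgSubbandError, ValueError):
    """Zero-variance first difference (linear ramp): complexity is undefined."""


class UndefinedDistributionError(EcgSubbandError, ValueError):
    """All-zero sequence: the energy probability distribution is undefined."""


class UndefinedEntropyError(EcgSubbandError, ValueError):
    """Entropy undefined for this input (e.g. no template matches in sample entropy)."""


class SignalTooShortError(EcgSubbandError, ValueError):
    """Signal shorter than an operation's minimum length."""


class UnknownWaveletError(EcgSubbandError, ValueError):
    """Mother-wavelet identifier not recognised."""


class FeatureExtractionError(EcgSubbandError, ValueError):
    """A per-band feature failed; carries the band and feature name."""

    def __init__(self, band: str, feature: str, cause: Exception):
        self.band = band
        self.feature = feature
        self.cause = cause
        super().__init__(f"feature {feature!r} failed on band {band!r}: {cause}")


class ConfigError(EcgSubbandError, ValueError):
    """Invalid or unknown configuration key/value."""


class ArtifactMismatchError(EcgSubbandError, ValueError):
    """Artifact config hash does not match the current run's configuration."""


class WFDBFormatError(EcgSubbandError, ValueError):
    """Unsupported or inconsistent WFDB header/signal file."""
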