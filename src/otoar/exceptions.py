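"""Exception hierarchy for otoar."""


class OtoARError(Exception):
    """Base class for all otoar errors."""


class DegenerateGeometryError(OtoARError):
    """Geometric configuration does not admit a solution (behind-camera
    point, point mapped to the line at infinity, coincident rays, ...)."""


class EstimationError(OtoARError):
    """Model estimation failed (too few correspondences, all RANSAC
    samples degenerate, singular fit)."""


class RegistrationError(OtoARError):
    """CT-to-video registration could not be computed."""


class TrackingLostError(OtoARError):
    """Operation requires an actively tracking state."""


class InstrumentModelError(OtoARError):
    """Instrument geometry file is inconsistent (collinearity violated,
    non-positive distance)."""


class AmbiguousLabelingError(OtoARError):
    """Marker labels cannot be assigned unambiguously."""


class ConfigError(OtoARError):
    """Invalid configuration value or file."""
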