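"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`PlasmascapeError`
so callers can distinguish pipeline data problems from programming errors.
"""


class PlasmascapeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PlasmascapeError):
    """A generator or field specification contains non-finite or bad values."""


class EmptyTrackError(PlasmascapeError):
    """A simulated or observed track has no usable fixes."""


class NoDataError(PlasmascapeError):
    """No fixes fall inside the requested window or field extent."""


class InvalidContaminationError(PlasmascapeError):
    """Lipid contamination parameters are out of range (delta C:N < 0)."""


class InvalidPointError(PlasmascapeError):
    """A coordinate is non-finite or outside valid lon/lat ranges."""


class DegenerateTripError(PlasmascapeError):
    """Filtering removed every fix except the anchor."""


class ConfigError(PlasmascapeError):
    """Unknown method or inconsistent configuration."""


class InvalidTripError(PlasmascapeError):
    """Trip violates its invariants (e.g. duplicate timestamps)."""


class InsufficientDataError(PlasmascapeError):
    """Not enough observations to fit the requested model."""


class SingularFitError(PlasmascapeError):
    """Zero predictor variance makes the regression singular."""


class ModelMissingError(PlasmascapeError):
    """No normalization model was fitted for this species."""


class AlreadyDelipidatedError(PlasmascapeError):
    """Sample has a measured delipidated value; correction refused."""


class NoForagingError(PlasmascapeError):
    """An individual has no foraging-labelled fixes in the window."""


class UnsupportedExtentError(PlasmascapeError):
    """Longitudes span the antimeridian, which gridding does not support."""


class UndefinedCorrelationError(PlasmascapeError):
    """Zero variance in predictor or response."""


class VariogramUndersampledError(PlasmascapeError):
    """Too few lag bins to fit a variogram model."""


class SingularKrigingError(PlasmascapeError):
    """Kriging matrix is singular even after jitter retry."""


class DegenerateHullError(PlasmascapeError):
    """Hull of the sample locations has no area and no extent."""


class NoOverlapError(PlasmascapeError):
    """Two surfaces share no defined cells."""


class InsufficientIndividualsError(PlasmascapeError):
    """A species has fewer individuals than the bootstrap draw size."""


class FrontNotPresentError(PlasmascapeError):
    """Requested SSH level lies outside the field's value range."""


class AmbiguousZoneError(PlasmascapeError):
    """Front ordering is violated at the queried longitude."""


class EmptyFeatureError(PlasmascapeError):
    """No defined surface cells overlap the requested feature."""


class WrongPredictorError(PlasmascapeError):
    """Back-calculation needs a latitude regression."""


class InvalidFieldError(PlasmascapeError):
    """SSH construction parameters are not monotone."""
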