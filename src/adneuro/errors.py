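"""Exception hierarchy shared by all stages of the pipeline."""


class AdneuroError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AdneuroError):
    """Invalid parameter, band edge, montage label or grid setting."""


class DegenerateInputError(AdneuroError):
    """Input is formally valid but carries no usable variation
    (flat channel, zero-variance baseline, zero-power series)."""


class InsufficientDataError(AdneuroError):
    """Too few samples/beats/rows for the requested computation."""


class GenerationError(AdneuroError):
    """Synthetic-data parameters produce physically impossible streams."""


class QualityError(AdneuroError):
    """Signal failed a screening stage (e.g. too many ectopic beats)."""


class DetectionError(AdneuroError):
    """A detector found nothing where its contract requires a result."""


class EmptyResultError(AdneuroError):
    """Every epoch/record was rejected; nothing left to aggregate."""
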