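"""Exception hierarchy for pedphewas.

All package errors derive from :class:`PhewasError` so callers can catch
one base class at pipeline level while stages raise specific subclasses.
"""


class PhewasError(Exception):
    """Base class for all pedphewas errors."""


class ParameterError(PhewasError, ValueError):
    """An argument is outside its documented range."""


class DefinitionError(PhewasError, KeyError):
    """A phecode or variant referenced by id does not exist."""


class ConfigurationError(PhewasError):
    """A run configuration is internally inconsistent."""


class StructuralError(PhewasError):
    """Input files are mutually inconsistent (e.g. bed/bim/fam counts)."""


class DegenerateFitError(PhewasError):
    """A regression cannot be fit on the supplied data."""


class DegeneratePredictorError(DegenerateFitError):
    """Constant or collinear predictor column."""


class DegenerateResponseError(DegenerateFitError):
    """Response vector is all-case or all-control."""


class UndefinedLdError(PhewasError):
    """LD statistics requested for a monomorphic locus."""


class NoSolutionError(PhewasError):
    """A design query has no attainable solution (e.g. power at OR = 1)."""
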