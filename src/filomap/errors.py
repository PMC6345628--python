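"""Exception hierarchy shared across the pipeline stages."""


class FilomapError(Exception):
    """Base class for all package errors."""


class ParameterError(FilomapError, ValueError):
    """A parameter value violates its documented constraints."""


class GeometryError(FilomapError, ValueError):
    """A trace or coordinate falls outside the image bounds."""


class FormatError(FilomapError, ValueError):
    """An input file is not in a supported format."""


class NormalizationError(FilomapError, ValueError):
    """A channel cannot be contrast-normalized (e.g. constant intensity)."""


class IntegrityError(FilomapError, ValueError):
    """Tabular data violates a schema or uniqueness constraint."""


class ShortProfileError(FilomapError, ValueError):
    """A line profile has fewer samples than the number of bins."""


class InsufficientDataError(FilomapError, ValueError):
    """Too few observations to compute a summary statistic."""


class PipelineConfigError(FilomapError, ValueError):
    """A pipeline configuration is missing or inconsistent."""
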