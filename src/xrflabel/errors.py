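"""Exception hierarchy shared across the package."""


class XrfLabelError(Exception):
    """Base class for all package errors."""


class CatalogueError(XrfLabelError, KeyError):
    """Unknown element, series or transition requested from the line catalogue."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class CoverageError(XrfLabelError, ValueError):
    """An energy grid does not cover a contributing emission line."""


class ConfigurationError(XrfLabelError, ValueError):
    """Inconsistent panels, parameters or pipeline configuration."""


class InsufficientDataError(XrfLabelError, ValueError):
    """Too few observations for the requested estimate."""


class DegenerateDataError(XrfLabelError, ValueError):
    """Input carries no usable signal (zero spread, uniform image, ...)."""


class PackingError(XrfLabelError, RuntimeError):
    """Phantom objects could not be placed without overlap."""


class GeometryError(XrfLabelError, ValueError):
    """A geometric transform would leave the image domain."""


class MaskError(XrfLabelError, ValueError):
    """A pixel mask is empty or inconsistent with the image."""


class FormatError(XrfLabelError, ValueError):
    """A file on disk does not match the documented layout."""
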