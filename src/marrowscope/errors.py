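"""Exception hierarchy shared by all analysis stages."""


class MarrowscopeError(Exception):
    """Base class for every error raised by this package."""


class SpecValidationError(MarrowscopeError, ValueError):
    """A phantom spec or run config field violates an invariant.

    The offending field name is stored in ``field`` and included in the
    message so callers can surface it directly.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FitError(MarrowscopeError, RuntimeError):
    """A model fit failed or was handed degenerate data."""


class SegmentationError(MarrowscopeError, RuntimeError):
    """Vessel segmentation could not be performed."""


class VelocimetryError(MarrowscopeError, RuntimeError):
    """Velocity estimation failed."""


class UnresolvableVelocityError(VelocimetryError):
    """Streak orientation sits at the pixels-per-line asymptote.

    The cell moved faster than the line scan can resolve; the velocity is
    unbounded along the scan line.
    """
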