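"""Exception types shared across the package."""


class NmjquantError(Exception):
    """Base class for all package errors."""


class FormatError(NmjquantError):
    """Input file has an unsupported layout (e.g. multi-page TIFF without a page selector)."""


class DimensionError(NmjquantError, ValueError):
    """Arrays that must share a shape do not."""


class ParameterError(NmjquantError, ValueError):
    """A parameter violates its precondition."""


class CapacityError(NmjquantError):
    """Requested object density cannot be placed; carries the feasible count."""

    def __init__(self, requested: int, placed: int, what: str = "objects"):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"could only place {placed} of {requested} requested {what}; "
            f"reduce density or enlarge the frame"
        )


class DenominatorError(NmjquantError, ZeroDivisionError):
    """A normalization denominator is zero or negative."""


class ConfigError(NmjquantError):
    """Pipeline configuration is inconsistent or incomplete."""
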