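"""Exception hierarchy shared across the package."""


class RiceSISTError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RiceSISTError, ValueError):
    """An argument violates a documented precondition."""


class MissingForcingError(RiceSISTError):
    """The daily weather record does not cover the requested simulation window."""

    def __init__(self, missing_doys):
        self.missing_doys = sorted(missing_doys)
        super().__init__(
            f"weather forcing is missing {len(self.missing_doys)} day(s): "
            f"{self.missing_doys}"
        )


class InfeasibleBandError(RiceSISTError):
    """The Sakoe-Chiba band excludes every complete warping path."""


class DegenerateRangeError(RiceSISTError):
    """Min-max normalization requested on an empty mask."""


class UndefinedCorrelationError(RiceSISTError):
    """Pearson correlation requested on data with zero variance."""
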