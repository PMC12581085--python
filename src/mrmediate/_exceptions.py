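"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package errors."""


class FormatError(MRError, ValueError):
    """A summary-statistics file does not match the declared dialect."""


class InputError(MRError, ValueError):
    """An operation received input violating its preconditions."""


class UndefinedRatioError(InputError):
    """Wald ratio requested for a variant with zero exposure effect."""


class UnderIdentifiedError(InputError):
    """Multivariable MR dataset has no more SNPs than exposures."""


class CollinearityError(InputError):
    """Exposure-beta matrix is rank deficient."""

    def __init__(self, message, exposures=()):
        super().__init__(message)
        self.exposures = tuple(exposures)


class DegenerateCorrectionError(InputError):
    """Outlier correction would remove every instrument."""
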