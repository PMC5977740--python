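"""Exception hierarchy shared across the package."""


class FoodMATSError(Exception):
    """Base class for all package-specific errors."""


class AuditValidationError(FoodMATSError):
    """An audit file or record violates the documented schema.

    The message names the offending row and field whenever possible.
    """


class UnclassifiedError(FoodMATSError):
    """A product, brand, or retailer could not be assigned a healthfulness
    class by any rule; manual assignment is required."""


class DomainError(FoodMATSError):
    """An argument is outside the domain a rule or statistic is defined on."""


class UndefinedStatisticError(FoodMATSError):
    """The requested statistic is undefined for the supplied data
    (e.g. chance agreement of 1 with imperfect agreement, or zero
    between-subject variance for an intraclass correlation)."""
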