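"""Exception and warning types shared across the package."""


class BoronPHError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BoronPHError, ValueError):
    """Non-finite or out-of-range input."""


class NoSolutionError(BoronPHError):
    """The carbonate-system root finder found no sign change in pH [2, 12],
    which signals an unphysical ALK/DIC pair."""


class UninvertibleError(BoronPHError):
    """A d11B value so low that the borate equation has no pH solution."""


class InsufficientDataError(BoronPHError):
    """Fewer records than required for a robust fit."""


class InsufficientSignalError(BoronPHError):
    """Fewer than two seasonal cycles detected in a Mg/Ca transect."""


class InvalidScenarioError(BoronPHError, ValueError):
    """Mixing fractions invalid (outside [0, 1] or not summing to 1)."""


class SchemaError(BoronPHError, ValueError):
    """A CSV table is missing required columns or contains bad values."""


class LowSalinityWarning(UserWarning):
    """Emitted when carbonate-system constants are evaluated below S = 19 psu,
    the stated validity limit of the Lueker et al. formulation."""
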