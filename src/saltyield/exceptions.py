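"""Exception hierarchy for saltyield."""


class SaltYieldError(Exception):
    """Base class for all saltyield errors."""


class MissingInputError(SaltYieldError):
    """A required model regressor is absent from the edaphic profile."""

    def __init__(self, field_name: str):
        self.field_name = field_name
        super().__init__(f"required model input is missing: {field_name!r}")


class NoInteriorMaximumError(SaltYieldError):
    """Quadratic coefficient is non-negative; the parabola has no interior maximum."""


class NoDeclineDetectedError(SaltYieldError):
    """No candidate breakpoint yields a positive decline slope."""


class SegmentUnderdeterminedError(SaltYieldError):
    """Too few points off the plateau to fit a three-piece tolerance curve."""


class UnderdeterminedError(SaltYieldError):
    """Not enough distinct abscissae to fit the requested curve."""


class SingularDesignError(SaltYieldError):
    """The regression design matrix is rank deficient."""


class MethodInapplicableError(SaltYieldError):
    """The requested fitting method cannot be applied to these samples."""


class DegenerateInputError(SaltYieldError):
    """Samples carry no variation; no distribution can be fitted."""


class EmptyRegionError(SaltYieldError):
    """The simulation was asked to run over zero fields."""


class SchemaError(SaltYieldError):
    """An input file does not conform to the expected tabular schema."""


class ValidationError(SaltYieldError):
    """Values in an input file violate a physical or logical constraint."""
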