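"""Shared exception types."""


class CavekitError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CavekitError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InsufficientDataError(CavekitError, ValueError):
    """Too few usable observations to attempt an estimate."""


class DegenerateDesignError(CavekitError, ValueError):
    """The experimental design cannot identify the requested parameters."""


class UndefinedRatioError(CavekitError, ZeroDivisionError):
    """A ratio with a zero denominator was requested."""


class ExtinctionError(CavekitError, RuntimeError):
    """A simulated population went extinct."""

    def __init__(self, round_index: int):
        self.round_index = round_index
        super().__init__(f"population extinct at round {round_index}")
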