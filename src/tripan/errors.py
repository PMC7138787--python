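"""Exception hierarchy for the tripan pipeline."""


class TripanError(Exception):
    """Base class for all tripan errors."""


class CoordinateError(TripanError):
    """Invalid genomic coordinates (negative, empty, or reversed)."""


class ParseError(TripanError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ParameterError(TripanError):
    """Parameter outside its documented domain."""


class UndefinedFractionError(TripanError):
    """A ratio was requested with an empty or zero denominator."""


class ConsistencyError(TripanError):
    """Inputs contradict each other (unknown chromosome, out-of-range block)."""


class SimulationError(TripanError):
    """The simulator could not satisfy its constraints (event collision)."""


class PlacementError(SimulationError):
    """Not enough free sequence to place the requested features."""


class OrderingError(TripanError):
    """Input records violate a required sort order."""


class InputError(TripanError):
    """Empty or unusable input to an operation."""


class OrchestrationError(TripanError):
    """A pipeline stage is missing a required upstream artifact."""
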