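"""Exception taxonomy shared across the pipeline."""


class KneeStsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KneeStsError, ValueError):
    """A physically or statistically meaningless input parameter."""


class FormatError(KneeStsError, IOError):
    """Malformed or incomplete trial file."""


class MissingMarkerError(KneeStsError, KeyError):
    """A required marker label is absent from a trial."""

    def __init__(self, label: str, context: str = ""):
        self.label = label
        msg = f"required marker {label!r} missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


class DegenerateGeometryError(KneeStsError, ValueError):
    """Collinear or coincident landmarks that do not define a frame."""


class EventDetectionError(KneeStsError, RuntimeError):
    """A sit-to-stand event rule could not be satisfied."""

    def __init__(self, event: str, detail: str = ""):
        self.event = event
        msg = f"event {event!r} not found"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class ConvergenceError(KneeStsError, RuntimeError):
    """An iterative solver failed to converge."""
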