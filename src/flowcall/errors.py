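"""Exception hierarchy shared across the package."""


class FlowcallError(Exception):
    """Base class for all package errors."""


class MarkupError(FlowcallError):
    """Malformed command markup (unclosed ``<``/``[`` or unmatched ``#``).

    Carries the character offset where the problem was detected.
    """

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (offset {offset})")
        self.offset = offset


class ValidationError(FlowcallError):
    """A workflow document or specification violates an invariant."""


class CycleError(ValidationError):
    """The step graph contains a cycle; ``cycle`` lists one offending cycle."""

    def __init__(self, cycle: list[str]):
        super().__init__("workflow graph contains a cycle: " + " -> ".join(cycle + cycle[:1]))
        self.cycle = cycle


class UnboundMacroError(FlowcallError):
    """A macro has no bound value and no default."""


class UnboundInputError(FlowcallError):
    """An unlinked input port has no binding to resolve it."""


class StaleStateError(FlowcallError):
    """A resume was attempted against a run directory from a different workflow."""


class EngineInterrupted(FlowcallError):
    """Raised by an ``on_step_end`` callback to stop a run at a step boundary."""


class SetupError(FlowcallError):
    """The run directory could not be prepared before any step ran."""


class RegistryError(FlowcallError):
    """A caller was used without being registered."""


class NormalizationError(FlowcallError):
    """A variant could not be reduced to its minimal anchored representation."""


class ConfigError(FlowcallError):
    """Invalid or incomplete configuration (e.g. TMB without a target size)."""
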