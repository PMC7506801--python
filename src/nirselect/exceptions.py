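"""Package-specific exception types."""


class NirselectError(Exception):
    """Base class for errors raised by nirselect."""


class DegenerateComponentError(NirselectError, ValueError):
    """A latent component could not be extracted (zero-norm weight vector)."""

    def __init__(self, component_index: int, message: str | None = None):
        self.component_index = component_index
        super().__init__(
            message
            or f"degenerate component at index {component_index}: "
            "weight vector has zero norm (constant column after deflation?)"
        )


class UndefinedScoreError(NirselectError, ValueError):
    """A variable-importance score is undefined (zero explained variance)."""


class InvalidConfigurationError(NirselectError, ValueError):
    """A configuration object violates its invariants."""


class DimensionError(NirselectError, ValueError):
    """Mismatched array dimensions."""
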