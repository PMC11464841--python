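"""Exception hierarchy used across the pipeline."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ChannelMismatchError(ValidationError):
    """Channel names of two objects cannot be reconciled."""


class UnmixingError(RuntimeError):
    """Spillover compensation failed (singular or ill-conditioned matrix)."""


class PlacementError(RuntimeError):
    """Synthetic cell placement could not satisfy the spacing constraint."""
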