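"""Exception types shared across the pipeline."""


class SpykitError(Exception):
    """Base class for all spykit errors."""


class ValidationError(SpykitError, ValueError):
    """A parameter or input violates a documented precondition."""


class DegenerateInputError(SpykitError, ValueError):
    """An input is structurally valid but collapses under the operation
    (e.g. a mask that vanishes after blurring or erosion)."""


class PlacementError(SpykitError, RuntimeError):
    """Spikes could not be placed disjointly within the retry budget."""
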