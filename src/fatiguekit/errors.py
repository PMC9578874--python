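"""Exception hierarchy shared across the toolkit."""


class FatigueKitError(Exception):
    """Base class for all fatiguekit errors."""


class InvalidArgumentError(FatigueKitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDataError(FatigueKitError, ValueError):
    """Input data is structurally valid but unusable (e.g. single-class labels)."""


class InvalidSpecError(FatigueKitError, ValueError):
    """A model/architecture spec violates its invariants."""


class DegenerateGeometryError(FatigueKitError, ValueError):
    """Landmark geometry collapses to zero extent."""


class OutOfBoundsError(FatigueKitError, ValueError):
    """A region of interest lies entirely outside the image."""
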