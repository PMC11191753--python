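"""Exception types used across the package."""


class SpineFEMError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpineFEMError, ValueError):
    """A geometry/material parameter violates its invariants."""


class InvalidPlanError(SpineFEMError, ValueError):
    """A cement plan cannot be realised inside the vertebra."""


class MeshingError(SpineFEMError, RuntimeError):
    """A region could not be meshed at the requested density."""


class AssemblyError(SpineFEMError, RuntimeError):
    """Element-level assembly failed (e.g. inverted element)."""


class UnknownRegionError(SpineFEMError, LookupError):
    """A region tag has no material or no elements."""


class NonConvergenceError(SpineFEMError, RuntimeError):
    """The tension-only active-set iteration did not settle."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []
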