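"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class OutsideMaskError(InvalidInputError):
    """Raised when a voxel with no analyzable tissue is passed to an estimator."""


class DegenerateModelError(RuntimeError):
    """Raised when the Gaussian model collapses (zero total variance)."""


class InitFailureError(RuntimeError):
    """Raised when an initialization region is empty."""


class NotCoregisteredError(InvalidInputError):
    """Raised when volumes that must share a grid/affine do not."""
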