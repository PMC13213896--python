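"""Exception hierarchy.

Validation failures map onto the protocol's preconditions: sites must share
an identical model structure, grids must align exactly, and degenerate data
(single-class outcomes, separation) must fail loudly rather than produce a
silently unusable local fit.
"""


class FedlikError(Exception):
    """Base class for all package errors."""


class DimensionMismatchError(FedlikError, ValueError):
    """A coefficient vector does not match the model's parameter count."""

    def __init__(self, expected: int, received: int):
        super().__init__(
            f"coefficient vector has length {received}, model requires {expected}"
        )
        self.expected = expected
        self.received = received


class SingleClassOutcomeError(FedlikError, ValueError):
    """The outcome takes a single value, so the model is not estimable.

    Mirrors the exclusion of a jurisdiction that recorded no patients with
    the outcome of interest: such a site cannot contribute a local fit.
    """


class SeparationError(FedlikError, RuntimeError):
    """Complete or quasi-complete separation: the MLE is not finite."""


class NonConvergenceError(FedlikError, RuntimeError):
    """The optimiser exhausted its iteration budget without converging."""


class ModelMismatchError(FedlikError, ValueError):
    """Sites disagree on model structure (parameter names or order).

    A valid joint likelihood requires every site to use an identical model
    specification: same outcome, same covariates, same order.
    """


class GridAlignmentError(FedlikError, ValueError):
    """Tensors were evaluated on different grids (fingerprint mismatch)."""


class DuplicateSiteError(FedlikError, ValueError):
    """The same site appears twice; summing its tensor would double-count
    records and bias the combined likelihood."""


class MemoryLimitError(FedlikError, MemoryError):
    """Materialising the requested tensor would exceed the memory ceiling.

    Use the streaming scan in :mod:`fedlik.federation` or a coarser
    increment.
    """
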