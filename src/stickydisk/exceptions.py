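"""Exception hierarchy for physically meaningful failure modes."""


class StickyDiskError(Exception):
    """Base class for all package errors."""


class CoverageError(StickyDiskError, ValueError):
    """Monolayer coverage eta = alpha*Gamma outside the hard-disk bound [0, 1)."""


class ValidityError(StickyDiskError, ValueError):
    """Parameters outside the model's domain of validity (e.g. beta >= 38)."""


class NoSolutionError(StickyDiskError, ValueError):
    """A requested inversion has no solution on the physical branch."""


class AmbiguityError(StickyDiskError, ValueError):
    """A root search detected a non-monotone residual; refusing to pick a root."""


class DesignError(StickyDiskError, ValueError):
    """A synthetic experiment design produces unphysical conditions."""
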