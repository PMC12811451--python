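"""Exception types shared across the pipeline."""


class FluidTrajError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FluidTrajError, ValueError):
    """A caller-supplied argument violates an operation's contract."""


class DegenerateInputError(FluidTrajError, ValueError):
    """Input is structurally valid but cannot support the computation.

    Examples: an ROC requested on single-class labels, or a cohort in
    which every trajectory falls below the minimum-tests exclusion rule.
    """
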