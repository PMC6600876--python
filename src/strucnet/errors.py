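"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


class DegenerateDataError(ValueError):
    """Raised when data are too degenerate for a statistic to be defined.

    Examples: a paired t-test on all-zero differences, a Shapiro-Wilk
    test on a constant sample, a regression on a constant predictor.
    """
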