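"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a domain precondition (non-positive duration, bad bound, ...)."""


class FeasibilityError(ValueError):
    """An overlap configuration violates the well-definedness constraint c_lower < 1/s."""


class NoRealSolutionError(ValueError):
    """The intersection identity has no real root for the requested parameters."""


class FitError(RuntimeError):
    """Mixture estimation cannot proceed (degenerate data, too few points)."""
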