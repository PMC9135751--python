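"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input violated a documented precondition or invariant."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""
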