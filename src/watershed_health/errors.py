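"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Invalid configuration value (dimensions, probabilities, ranges)."""


class RoutingError(RuntimeError):
    """Flow-network defect: pit, cycle, or inconsistent topological order."""


class ConvergenceError(RuntimeError):
    """Model fit failed to converge; carries optimizer diagnostics."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation detected in the outcome."""
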