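"""Exception types shared across the package."""


class LedthermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LedthermError):
    """Invalid model, scenario, or override configuration."""


class SolverError(LedthermError):
    """Numerical failure during time integration (divergence, NaN, non-convergence)."""


class FitError(LedthermError):
    """Beam-profile fitting failed to converge."""
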