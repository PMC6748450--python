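"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid parameter combination or grid specification."""


class FormatError(ValueError):
    """Malformed input table (ragged grid, missing columns, NaNs)."""


class ConsistencyError(ValueError):
    """Input force field violates the zero net force/torque requirement."""


class ConvergenceError(RuntimeError):
    """Iterative procedure failed to reach its residual tolerance."""
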